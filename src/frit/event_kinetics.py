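"""Release-event kinetics: filtering, occupancy, rates, persistence modes.

After lipoplex uptake, siRNA is released from endosomes into the cytosol in
discrete events whose onsets follow a biphasic schedule: a short burst phase
(~30 min) with a high per-cell release rate, followed by a sustained phase
with a much lower rate.  Cytosolic fluorescence from one release persists
for tens of minutes before fading (depletion).  This module turns an event
table into the standard summaries: the occupancy curve (fraction of cells
currently fluorescent), a continuous two-segment piecewise-linear fit of the
cumulative onset curve whose slopes are the per-cell release rates, and a
decomposition of the persistence-time histogram into Gaussian modes fitted
at its local maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "ReleaseEvent",
    "ReleaseRateFit",
    "GaussianMode",
    "PersistenceModes",
    "OccupancyCurve",
    "KineticsWarning",
    "events_to_frame",
    "events_from_frame",
    "read_events_csv",
    "write_events_csv",
    "filter_events",
    "occupancy_curve",
    "fit_release_rates",
    "persistence_modes",
    "detect_events_from_trace",
]

EVENT_CLASSES = ("A", "B", "C", "D", "E", "F", "G")


class KineticsWarning(UserWarning):
    """Raised (as a warning) for degenerate kinetics inputs."""


@dataclass
class ReleaseEvent:
    """One cytosolic release event.

    Times are minutes after transfection.  ``persistence`` is the time
    cytosolic fluorescence stays visible; ``depletion_duration`` is the
    length of the subsequent fading phase.  ``full_length`` marks events
    whose depletion completed before the end of observation (uncensored);
    ``single`` marks cells with no repeated release; ``event_class`` is a
    free annotation (the A–G taxonomy), never computed automatically.
    """

    cell_id: int
    onset: float
    persistence: float
    depletion_duration: float = float("nan")
    full_length: bool = True
    single: bool = True
    event_class: str = "B"
    repeat_index: int = 1

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError("onset must be non-negative")
        if self.full_length and not self.persistence > 0:
            raise ValueError("full-length events must have positive persistence")
        if self.repeat_index < 1:
            raise ValueError("repeat_index is 1-based")


_EVENT_COLUMNS = [
    "cell_id", "onset_min", "persistence_min", "depletion_min",
    "full_length", "single", "event_class", "repeat_index",
]


def events_to_frame(events) -> pd.DataFrame:
    rows = [
        (e.cell_id, e.onset, e.persistence, e.depletion_duration,
         e.full_length, e.single, e.event_class, e.repeat_index)
        for e in events
    ]
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def events_from_frame(frame: pd.DataFrame) -> list[ReleaseEvent]:
    return [
        ReleaseEvent(
            cell_id=int(r.cell_id),
            onset=float(r.onset_min),
            persistence=float(r.persistence_min),
            depletion_duration=float(r.depletion_min),
            full_length=bool(r.full_length),
            single=bool(r.single),
            event_class=str(r.event_class),
            repeat_index=int(r.repeat_index),
        )
        for r in frame.itertuples(index=False)
    ]


def write_events_csv(events, path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path) -> list[ReleaseEvent]:
    return events_from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Filtering and occupancy
# ---------------------------------------------------------------------------


def filter_events(events, purpose: str) -> list[ReleaseEvent]:
    """Select the event subset appropriate for each analysis.

    ``rates``: all events, sorted by onset (the cumulative onset curve uses
    every observed release).  ``histogram``: single, full-length, first
    releases only — repeated or censored events would bias the persistence
    distribution.  ``occupancy``: full-length events only.
    """
    events = list(events)
    if purpose == "rates":
        out = sorted(events, key=lambda e: e.onset)
    elif purpose == "histogram":
        out = [e for e in events if e.single and e.full_length and e.repeat_index == 1]
    elif purpose == "occupancy":
        out = [e for e in events if e.full_length]
    else:
        raise ValueError(f"unknown filtering purpose {purpose!r}")
    if events and not out:
        warnings.warn(f"no events left after {purpose!r} filtering", KineticsWarning)
    return out


@dataclass
class OccupancyCurve:
    """Fraction of observed cells with a fluorescent cytosol over time."""

    times: np.ndarray
    fraction_fluorescent: np.ndarray

    def __post_init__(self) -> None:
        f = self.fraction_fluorescent
        if np.any((f < 0) | (f > 1)):
            raise ValueError("occupancy fractions must lie in [0, 1]")

    @property
    def peak(self) -> tuple[float, float]:
        """(time, fraction) at the maximum occupancy."""
        i = int(np.argmax(self.fraction_fluorescent))
        return float(self.times[i]), float(self.fraction_fluorescent[i])


def occupancy_curve(events, n_cells: int, time_grid) -> OccupancyCurve:
    """Occupancy: a cell is fluorescent at t if some event has onset ≤ t < onset+persistence.

    Each cell counts at most once per time point even when its events
    overlap.
    """
    events = list(events)
    cell_ids = {e.cell_id for e in events}
    if n_cells < len(cell_ids):
        raise ValueError("n_cells must be at least the number of distinct cells")
    t = np.asarray(time_grid, dtype=float)
    active = np.zeros(t.shape, dtype=float)
    by_cell: dict[int, list[ReleaseEvent]] = {}
    for e in events:
        by_cell.setdefault(e.cell_id, []).append(e)
    for evs in by_cell.values():
        cell_active = np.zeros(t.shape, dtype=bool)
        for e in evs:
            cell_active |= (e.onset <= t) & (t < e.onset + e.persistence)
        active += cell_active
    return OccupancyCurve(times=t, fraction_fluorescent=active / n_cells)


# ---------------------------------------------------------------------------
# Biphasic release-rate fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReleaseRateFit:
    """Continuous two-segment piecewise-linear fit of cumulative onsets.

    ``rate1`` and ``rate2`` are per-cell release rates in permille per
    minute (segment slopes divided by the number of observed cells);
    ``breakpoint`` is where the segments meet.
    """

    breakpoint: float
    rate1: float
    rate2: float
    sse: float
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.rate1 < 0 or self.rate2 < 0:
            raise ValueError("release rates must be non-negative")


def _piecewise_lstsq(t: np.ndarray, y: np.ndarray, b: float):
    """LSQ fit of y = a + r1·min(t,b) + r2·max(t−b, 0); linear in (a, r1, r2)."""
    X = np.column_stack([np.ones_like(t), np.minimum(t, b), np.maximum(t - b, 0.0)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return coef, float(resid @ resid)


def fit_release_rates(
    events,
    n_cells: int,
    breakpoint: float | str = "free",
    *,
    grid_step: float = 1.0,
) -> ReleaseRateFit:
    """Fit the biphasic release model to the cumulative onset curve.

    Events are sorted by onset; the cumulative count at the i-th onset is i.
    A continuous two-segment piecewise-linear function is fitted by least
    squares, with the breakpoint either fixed or profiled over a 1-min grid.
    Slopes are divided by ``n_cells`` and reported in permille per minute.
    """
    events = filter_events(events, "rates")
    if len(events) < 10:
        raise ValueError("need at least 10 events to fit release rates")
    t = np.array([e.onset for e in events], dtype=float)
    y = np.arange(1, len(t) + 1, dtype=float)

    if isinstance(breakpoint, str):
        if breakpoint != "free":
            raise ValueError("breakpoint must be a number or 'free'")
        lo = np.floor(t.min()) + grid_step
        hi = np.ceil(t.max()) - grid_step
        grid = np.arange(lo, hi + grid_step / 2, grid_step)
        if grid.size == 0:
            grid = np.array([(t.min() + t.max()) / 2])
        best_b, best_coef, best_sse = None, None, np.inf
        for b in grid:
            coef, sse = _piecewise_lstsq(t, y, float(b))
            if sse < best_sse - 1e-12:
                best_b, best_coef, best_sse = float(b), coef, sse
        b, coef, sse = best_b, best_coef, best_sse
    else:
        b = float(breakpoint)
        coef, sse = _piecewise_lstsq(t, y, b)

    a, r1, r2 = coef
    return ReleaseRateFit(
        breakpoint=b,
        rate1=max(float(r1), 0.0) / n_cells * 1000.0,
        rate2=max(float(r2), 0.0) / n_cells * 1000.0,
        sse=sse,
        intercept=float(a),
    )


# ---------------------------------------------------------------------------
# Persistence-time histogram decomposition
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianMode:
    mean: float
    sd: float
    weight: float  # area under the mode, in event counts


@dataclass
class PersistenceModes:
    """Gaussian modes of the persistence-time histogram, sorted by weight."""

    bin_width: float
    modes: list[GaussianMode]
    bin_edges: np.ndarray = field(default_factory=lambda: np.array([]))
    counts: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def means(self) -> list[float]:
        return [m.mean for m in self.modes]


def _local_maxima(counts: np.ndarray) -> list[int]:
    """Indices of bins strictly greater than both neighbors.

    Ties between adjacent equal bins break toward the earlier bin: a plateau
    counts as one maximum at its left edge if it rises on the left and falls
    on the right.
    """
    n = len(counts)
    maxima = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and counts[j + 1] == counts[i]:
            j += 1
        left = counts[i - 1] if i > 0 else -np.inf
        right = counts[j + 1] if j + 1 < n else -np.inf
        if counts[i] > left and counts[i] > right and counts[i] > 0:
            maxima.append(i)
        i = j + 1
    return maxima


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def persistence_modes(
    events_or_durations,
    bin_width: float = 5.0,
    *,
    smooth: bool = False,
) -> PersistenceModes:
    """Decompose persistence times into Gaussian modes at histogram maxima.

    Durations are binned at ``bin_width`` minutes (bins from 0); local
    maxima of the histogram (optionally after a 1-bin moving-average
    smoothing) seed one Gaussian each, fitted per-peak on ±2 bins and then
    jointly refined as a sum of Gaussians over all bins.  Modes are returned
    sorted by weight (area), heaviest first.
    """
    durations = np.asarray(
        [e.persistence if isinstance(e, ReleaseEvent) else e for e in events_or_durations],
        dtype=float,
    )
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if durations.size < 30:
        raise ValueError("need at least 30 durations for mode decomposition")

    edges = np.arange(0.0, durations.max() + 2 * bin_width, bin_width)
    counts, edges = np.histogram(durations, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2
    work = counts.astype(float)
    if smooth:
        kernel = np.ones(3) / 3.0
        work = np.convolve(work, kernel, mode="same")

    maxima = _local_maxima(work)
    if not maxima:
        warnings.warn(
            "no local maxima in the persistence histogram; fitting a single mode",
            KineticsWarning,
        )
        maxima = [int(np.argmax(work))]

    occupied = np.nonzero(counts)[0]
    if occupied.size == 1:
        # degenerate: all durations in one bin
        warnings.warn("all durations fall in a single bin", KineticsWarning)
        i = occupied[0]
        mode = GaussianMode(mean=float(centers[i]), sd=bin_width / 2, weight=float(counts[i]))
        return PersistenceModes(bin_width=bin_width, modes=[mode], bin_edges=edges, counts=counts)

    # per-peak fits on +-2 bins around each maximum; widths are bounded to
    # about one bin's worth of spread so a single Gaussian cannot swallow two
    # neighboring subpopulations
    def fit_one_peak(i: int, y: np.ndarray) -> np.ndarray:
        lo, hi = max(0, i - 2), min(len(counts), i + 3)
        p0 = [max(y[i], 1.0), centers[i], bin_width]
        try:
            popt, _ = curve_fit(
                _gauss, centers[lo:hi], y[lo:hi], p0=p0,
                bounds=(
                    [0, centers[i] - bin_width, bin_width / 10],
                    [np.inf, centers[i] + bin_width, 1.5 * bin_width],
                ),
                maxfev=10000,
            )
        except RuntimeError:
            popt = np.asarray(p0, dtype=float)
        return np.asarray(popt, dtype=float)

    seeds = [fit_one_peak(i, counts.astype(float)) for i in maxima]

    def joint_fit(seeds: list[np.ndarray]):
        k = len(seeds)

        def model(x, *theta):
            out = np.zeros_like(x)
            for j in range(k):
                out += _gauss(x, *theta[3 * j: 3 * j + 3])
            return out

        p0 = np.concatenate(seeds)
        # means may move at most ~1 bin from their seed during refinement
        lower = np.concatenate(
            [[0.0, s[1] - bin_width, bin_width / 10] for s in seeds]
        )
        upper = np.concatenate(
            [[np.inf, s[1] + bin_width, 1.5 * bin_width] for s in seeds]
        )
        p0 = np.clip(p0, lower, upper)
        try:
            popt, _ = curve_fit(
                model, centers, counts.astype(float), p0=p0,
                bounds=(lower, upper), maxfev=20000,
            )
        except RuntimeError:
            popt = p0
        return popt, model(centers, *popt)

    popt, fitted = joint_fit(seeds)

    # residual augmentation: a subpopulation hidden on the flank of a larger
    # one shows up as a significant (Poisson ~ 2*sqrt) excess of counts over
    # the fitted sum; seed an extra mode there and refit
    for _ in range(3):
        residual = counts.astype(float) - fitted
        sig = residual > 2.5 * np.sqrt(np.maximum(fitted, 1.0))
        means_now = popt[1::3]
        candidates = [
            i
            for i in _local_maxima(np.where(sig, residual, 0.0))
            if sig[i] and np.all(np.abs(centers[i] - means_now) > 2.0 * bin_width)
        ]
        if not candidates:
            break
        i_new = max(candidates, key=lambda i: residual[i])
        seeds.append(fit_one_peak(i_new, np.maximum(residual, 0.0)))
        popt, fitted = joint_fit(seeds)

    # mode weight = empirical occupancy: each duration is assigned to the
    # mode with the nearest mean and counted.  Occupancy is far more stable
    # than the fitted Gaussian areas, which trade mass freely between
    # overlapping components
    mus = list(popt[1::3])
    sds = list(np.maximum(np.abs(popt[2::3]), 1e-9))

    def occupancy(mus_):
        return np.argmin(np.abs(durations[:, None] - np.asarray(mus_)[None, :]), axis=1)

    # modes whose means collapsed to within two bins describe one
    # subpopulation split in two; merge them (occupancy-weighted)
    while len(mus) > 1:
        order = np.argsort(mus)
        gaps = np.diff(np.asarray(mus)[order])
        if gaps.min() >= 2 * bin_width:
            break
        i, j = order[gaps.argmin()], order[gaps.argmin() + 1]
        assignment = occupancy(mus)
        wi = max(np.count_nonzero(assignment == i), 1)
        wj = max(np.count_nonzero(assignment == j), 1)
        mus[i] = (wi * mus[i] + wj * mus[j]) / (wi + wj)
        sds[i] = max(sds[i], sds[j])
        del mus[j], sds[j]

    assignment = occupancy(mus)
    modes = [
        GaussianMode(
            mean=float(mus[j]),
            sd=float(sds[j]),
            weight=float(np.count_nonzero(assignment == j)),
        )
        for j in range(len(mus))
    ]
    modes.sort(key=lambda m: m.weight, reverse=True)
    return PersistenceModes(bin_width=bin_width, modes=modes, bin_edges=edges, counts=counts)


# ---------------------------------------------------------------------------
# Trace-based event detection
# ---------------------------------------------------------------------------


def detect_events_from_trace(
    times,
    mfi,
    rise_factor: float = 2.0,
    fall_factor: float = 1.2,
    *,
    cell_id: int = 0,
    baseline_window: int = 3,
) -> list[ReleaseEvent]:
    """Threshold-crossing event detection on a cytosolic MFI trace.

    The baseline is the median of the pre-onset window.  An event starts
    when the MFI first exceeds ``baseline·rise_factor`` and ends when it
    next falls below ``baseline·fall_factor``; persistence is the
    difference.  Events still above threshold at the end of the trace are
    censored (``full_length=False``).
    """
    times = np.asarray(times, dtype=float)
    mfi = np.asarray(mfi, dtype=float)
    if times.shape != mfi.shape or times.size < 3:
        raise ValueError("trace needs matching times/MFI with at least 3 samples")

    events: list[ReleaseEvent] = []
    i = 0  # start of the current quiescent segment
    n = len(times)
    while i < n:
        # provisional baseline from the first samples of the segment, then
        # refined as the median of the whole pre-onset window
        baseline = float(np.median(mfi[i: i + baseline_window]))
        rise = np.nonzero(mfi[i:] > baseline * rise_factor)[0]
        if rise.size == 0:
            break
        onset_idx = i + int(rise[0])
        if onset_idx > i:
            baseline = float(np.median(mfi[i:onset_idx]))
        fall = np.nonzero(mfi[onset_idx:] < baseline * fall_factor)[0]
        if fall.size:
            end_idx = onset_idx + int(fall[0])
            events.append(
                ReleaseEvent(
                    cell_id=cell_id,
                    onset=float(times[onset_idx]),
                    persistence=float(times[end_idx] - times[onset_idx]),
                    full_length=True,
                    repeat_index=len(events) + 1,
                )
            )
            i = end_idx + 1
        else:
            events.append(
                ReleaseEvent(
                    cell_id=cell_id,
                    onset=float(times[onset_idx]),
                    persistence=float(times[-1] - times[onset_idx]),
                    full_length=False,
                    repeat_index=len(events) + 1,
                )
            )
            break
    for e in events:
        e.single = len(events) == 1
        e.event_class = "B" if e.repeat_index == 1 else "D"
    return events
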
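"""Ground-truthed synthetic data: event tables and rendered time-lapse stacks.

Two levels of simulation back the test suite and the acceptance checks:

* :func:`generate_event_table` draws release events directly from the
  kinetic model — per-cell onsets from an inhomogeneous Poisson process with
  a biphasic rate (a ~30-min burst phase followed by a low sustained rate),
  persistence times from a three-mode Gaussian mixture, and depletion
  (fading) durations from a truncated normal.

* :func:`generate_timeseries` renders those events into dual-gain
  two-channel confocal-like z-stacks: elliptical cells with nuclei, bright
  lipoplex particles of fully intact siRNA, cytosolic fluorescence that
  ramps up at each release, decays in integrity while dwelling, fades during
  depletion, and accumulates in partially degraded perinuclear dots.

Every random draw flows through one ``numpy.random.Generator`` seeded from
the config, so identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import PhotophysicsModel
from .event_kinetics import ReleaseEvent
from .roi_stats import RoiSet

__all__ = [
    "SimulationConfig",
    "generate_event_table",
    "generate_timeseries",
    "generate_calibration_table",
    "sample_persistence",
    "channel_emission_per_unit",
]

#: Default persistence-time mixture: (mean min, sd min, weight).
DEFAULT_PERSISTENCE_MIXTURE = ((24.0, 5.0, 0.60), (43.0, 5.0, 0.25), (58.0, 5.0, 0.15))


@dataclass
class SimulationConfig:
    """Full ground-truth parameterization of a synthetic transfection movie.

    Kinetic defaults are the fitted population values: biphasic release at
    1.9 ‰ then 0.2 ‰ cells/min with a 30-min breakpoint over a 360-min
    observation of 2,376 cells (54 areas × 44 cells); persistence modes at
    24/43/58 min; mean fading duration 46 min; release spreading through the
    cytosol within 4 min.  Imaging defaults mirror the acquisition geometry:
    512 × 512 px fields of ~44 cells, 5 z-slices, dual-gain channel pairs.
    """

    # kinetics
    n_cells: int = 54 * 44
    duration: float = 360.0
    rate1: float = 1.9            # permille cells/min, burst phase
    rate2: float = 0.2            # permille cells/min, sustained phase
    breakpoint: float = 30.0      # min
    persistence_mixture: tuple = DEFAULT_PERSISTENCE_MIXTURE
    depletion_mean: float = 46.0  # min, fading-phase duration
    depletion_sd: float = 10.0
    release_spread: float = 4.0   # min for cytosolic fluorescence to ramp up
    repeat_probability: float = 0.08
    integrity_decay_rate: float = 0.005  # per min, cytosolic dwell
    thinning_dt: float = 0.1      # min, Poisson thinning resolution

    # imaging
    image_size: tuple = (512, 512)
    z_slices: int = 5
    frame_interval: float = 1.0   # min
    cells_per_field: int = 44
    photophysics: PhotophysicsModel = field(default_factory=PhotophysicsModel)
    gain_ratio: float = 10.0
    saturation: float = 255.0
    shot_noise: bool = True
    read_noise_sd: float = 1.0
    seed: int | None = None

    # rendering brightness (a.u. at high gain, before saturation)
    cytosol_base_intensity: float = 2.0
    release_amplitude: float = 60.0
    lipoplex_intensity: float = 2000.0
    perinuclear_intensity: float = 80.0

    def __post_init__(self) -> None:
        if self.rate1 < 0 or self.rate2 < 0:
            raise ValueError("release rates must be non-negative")
        weights = [w for _, _, w in self.persistence_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("persistence mixture weights must sum to 1")
        if any(sd <= 0 for _, sd, _ in self.persistence_mixture) or self.depletion_sd <= 0:
            raise ValueError("all standard deviations must be positive")
        if not 0.0 <= self.repeat_probability <= 1.0:
            raise ValueError("repeat_probability must be a probability")


def sample_persistence(mixture, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw persistence times from a Gaussian mixture, truncated at > 0."""
    means = np.array([m for m, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    weights = np.array([w for _, _, w in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    out = rng.normal(means[comp], sds[comp])
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
        bad = out <= 0
    return out


def _sample_truncated_normal(mean, sd, n, rng) -> np.ndarray:
    out = rng.normal(mean, sd, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


# ---------------------------------------------------------------------------
# Event-table generation
# ---------------------------------------------------------------------------


def generate_event_table(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[ReleaseEvent], SimulationConfig]:
    """Draw a ground-truth release-event table from the kinetic model.

    Onsets come from per-cell Poisson thinning at ``thinning_dt`` resolution
    with the biphasic rate; each event gets a persistence time from the
    mixture and a fading duration from the truncated normal.  After the
    fading completes, the cell may release again (``repeat_probability``);
    events whose fading would not complete within the observation window are
    censored (``full_length=False``).  Returns the events plus an echo of
    the config (with the effective seed) as ground truth.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dt = config.thinning_dt
    n_steps = int(round(config.duration / dt))
    t_grid = (np.arange(n_steps) + 1) * dt  # onset at the end of each step
    rate = np.where(t_grid <= config.breakpoint, config.rate1, config.rate2) / 1000.0
    p_step = rate * dt

    events: list[ReleaseEvent] = []
    per_cell_counts: dict[int, int] = {}
    chunk = 2000
    for start in range(0, config.n_cells, chunk):
        rows = min(chunk, config.n_cells - start)
        hits = rng.random((rows, n_steps)) < p_step[None, :]
        hit_rows, hit_cols = np.nonzero(hits)
        for r in range(rows):
            cols = hit_cols[hit_rows == r]
            if cols.size == 0:
                continue
            cell_id = start + r
            cursor = -np.inf
            repeat_index = 0
            for c in cols:
                onset = float(t_grid[c])
                if onset < cursor:
                    continue
                if repeat_index >= 1 and rng.random() >= config.repeat_probability:
                    break
                persistence = float(sample_persistence(config.persistence_mixture, 1, rng)[0])
                depletion = float(_sample_truncated_normal(config.depletion_mean, config.depletion_sd, 1, rng)[0])
                end_of_fading = onset + persistence + depletion
                repeat_index += 1
                events.append(
                    ReleaseEvent(
                        cell_id=cell_id,
                        onset=onset,
                        persistence=persistence,
                        depletion_duration=depletion,
                        full_length=end_of_fading <= config.duration,
                        event_class="B" if repeat_index == 1 else "D",
                        repeat_index=repeat_index,
                    )
                )
                cursor = end_of_fading
            per_cell_counts[cell_id] = repeat_index
    for e in events:
        e.single = per_cell_counts[e.cell_id] == 1
    truth = replace(config, seed=seed)
    return events, truth


# ---------------------------------------------------------------------------
# Image rendering
# ---------------------------------------------------------------------------


def channel_emission_per_unit(integrity, model: PhotophysicsModel) -> tuple[np.ndarray, np.ndarray]:
    """Donor/FRET emission per unit of labeled material at a given integrity.

    A population of integrity ``f`` behaves like the cuvette mixture
    ``(f, (1−f)/2, (1−f)/2)``: unquenched donors emit green, FRET-sensitized
    acceptors plus bleed-through plus cross-excitation emit red.
    """
    f = np.asarray(integrity, dtype=float)
    u520 = model.qD * (f * (1 - model.E) + (1 - f) / 2)
    u625 = model.qA * model.E * f + model.beta * u520 + model.alpha * (f + (1 - f) / 2)
    return u520, u625


def _ellipse_polygon(cx, cy, ax, ay, n_vertices=32) -> np.ndarray:
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + ax * np.cos(theta), cy + ay * np.sin(theta)])


def _ellipse_mask(shape, cx, cy, ax, ay) -> np.ndarray:
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def _splat(donor, fret, x, y, sigma, intensity, integrity, model) -> None:
    """Add a small Gaussian blob with the given integrity to both channels."""
    h, w = donor.shape
    r = int(np.ceil(3 * sigma))
    x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
    y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    blob = intensity * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    u520, u625 = channel_emission_per_unit(integrity, model)
    donor[y0:y1, x0:x1] += blob * u520
    fret[y0:y1, x0:x1] += blob * u625


@dataclass
class _Cell:
    cell_id: int
    cx: float
    cy: float
    ax: float
    ay: float
    cytosol: np.ndarray
    nucleus: np.ndarray
    lipoplexes: list        # (x, y) static bright dots
    perinuclear: list       # (x, y, integrity) dots appearing at depletion
    events: list


def _place_cells(config: SimulationConfig, rng: np.random.Generator) -> list[_Cell]:
    h, w = config.image_size
    scale = np.sqrt(h * w / (512.0 * 512.0))
    ax_mean, ay_mean = 28.0 * scale, 20.0 * scale
    occupied = np.zeros((h, w), dtype=bool)
    cells = []
    attempts = 0
    max_attempts = 200 * config.cells_per_field
    while len(cells) < config.cells_per_field:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.cells_per_field} non-overlapping cells "
                f"in a {h}x{w} field after {max_attempts} attempts"
            )
        ax = ax_mean * rng.uniform(0.8, 1.2)
        ay = ay_mean * rng.uniform(0.8, 1.2)
        cx = rng.uniform(ax + 1, w - ax - 1)
        cy = rng.uniform(ay + 1, h - ay - 1)
        body = _ellipse_mask((h, w), cx, cy, ax, ay)
        if np.any(body & occupied):
            continue
        occupied |= body
        nucleus = _ellipse_mask((h, w), cx, cy, 0.4 * ax, 0.4 * ay)
        n_dots = 1 + rng.poisson(2)
        dots = []
        for _ in range(n_dots):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0.5, 0.9)
            dots.append((cx + rad * ax * np.cos(ang), cy + rad * ay * np.sin(ang)))
        cells.append(
            _Cell(
                cell_id=len(cells), cx=cx, cy=cy, ax=ax, ay=ay,
                cytosol=body & ~nucleus, nucleus=nucleus,
                lipoplexes=dots, perinuclear=[], events=[],
            )
        )
    return cells


def _event_envelope(t: float, e: ReleaseEvent, config: SimulationConfig) -> float:
    """Cytosolic intensity envelope of one event at time t, in [0, 1]."""
    rise_end = e.onset + config.release_spread
    fade_start = e.onset + e.persistence
    fade_end = fade_start + e.depletion_duration
    if t < e.onset or t >= fade_end:
        return 0.0
    if t < rise_end and config.release_spread > 0:
        return (t - e.onset) / config.release_spread
    if t < fade_start:
        return 1.0
    if e.depletion_duration <= 0:
        return 0.0
    return 1.0 - (t - fade_start) / e.depletion_duration


def generate_timeseries(
    config: SimulationConfig,
    seed: int | None = None,
    *,
    events: list[ReleaseEvent] | None = None,
    return_integrity: bool = False,
):
    """Render a dual-gain two-channel time-lapse z-stack with ground truth.

    Cells are static ellipses with concentric nuclei and a dim basal
    cytosolic signal; lipoplex particles are bright fully intact dots.  At
    each release onset the cytosol ramps up over ``release_spread`` minutes
    while its siRNA integrity decays exponentially; during the fading phase
    the cytosolic signal ramps back down and partially degraded
    (integrity 0.5–0.9) perinuclear dots accumulate.  Channels derive
    per-pixel from integrity via the photophysics model; the high-gain
    exposure saturates at ``config.saturation`` while the low-gain exposure
    is the same signal divided by ``gain_ratio``.

    Parameters
    ----------
    events:
        Scripted events to render instead of drawing from the kinetic model
        (cell_ids must index cells of this field).
    return_integrity:
        Also return the (T, Y, X) intensity-weighted ground-truth integrity
        maps (float32; memory-heavy for large fields).

    Returns
    -------
    stack:
        (T, Z, 4, Y, X) float32 array, channels ordered
        ``(donor_low, fret_low, donor_high, fret_high)``.
    truth:
        dict with ``events``, ``rois`` (one RoiSet per cell), ``times``,
        ``config``, and optionally ``integrity``.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    h, w = config.image_size
    cells = _place_cells(config, rng)

    if events is None:
        field_cfg = replace(config, n_cells=len(cells), seed=None)
        # child seed below 2**31 so reruns can reproduce it from the report
        events, _ = generate_event_table(field_cfg, seed=int(rng.integers(2**31)))
    for e in events:
        if not 0 <= e.cell_id < len(cells):
            raise ValueError(f"event cell_id {e.cell_id} does not index a rendered cell")
        cells[e.cell_id].events.append(e)

    # pre-draw perinuclear dots per event (appear during fading)
    for cell in cells:
        for e in cell.events:
            n_dots = 2 + rng.poisson(2)
            for _ in range(n_dots):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(1.05, 1.6)
                x = cell.cx + rad * 0.4 * cell.ax * np.cos(ang)
                y = cell.cy + rad * 0.4 * cell.ay * np.sin(ang)
                cell.perinuclear.append((x, y, rng.uniform(0.5, 0.9), e))

    n_frames = int(np.floor(config.duration / config.frame_interval)) + 1
    times = np.arange(n_frames) * config.frame_interval
    z_center = (config.z_slices - 1) / 2.0
    z_weight = np.exp(-((np.arange(config.z_slices) - z_center) ** 2) / (2 * max(config.z_slices / 2.0, 1.0) ** 2))

    model = config.photophysics
    stack = np.zeros((n_frames, config.z_slices, 4, h, w), dtype=np.float32)
    integrity_maps = (
        np.zeros((n_frames, h, w), dtype=np.float32) if return_integrity else None
    )

    base_u520, base_u625 = channel_emission_per_unit(1.0, model)
    for ti, t in enumerate(times):
        donor = np.zeros((h, w))
        fret = np.zeros((h, w))
        weighted_f = np.zeros((h, w))
        total_i = np.zeros((h, w))
        for cell in cells:
            # basal cytosolic signal, fully intact
            base = config.cytosol_base_intensity
            donor[cell.cytosol] += base * base_u520
            fret[cell.cytosol] += base * base_u625
            weighted_f[cell.cytosol] += base * 1.0
            total_i[cell.cytosol] += base
            for e in cell.events:
                env = _event_envelope(t, e, config)
                if env <= 0:
                    continue
                f = float(np.exp(-config.integrity_decay_rate * max(t - e.onset, 0.0)))
                u520, u625 = channel_emission_per_unit(f, model)
                amp = config.release_amplitude * env
                donor[cell.cytosol] += amp * u520
                fret[cell.cytosol] += amp * u625
                weighted_f[cell.cytosol] += amp * f
                total_i[cell.cytosol] += amp
            for x, y in cell.lipoplexes:
                _splat(donor, fret, x, y, 1.5, config.lipoplex_intensity, 1.0, model)
            for x, y, f_dot, e in cell.perinuclear:
                fade_start = e.onset + e.persistence
                if t < fade_start:
                    continue
                ramp = min((t - fade_start) / max(e.depletion_duration, 1e-9), 1.0)
                _splat(donor, fret, x, y, 1.2, config.perinuclear_intensity * ramp, f_dot, model)

        if return_integrity:
            with np.errstate(invalid="ignore"):
                integrity_maps[ti] = np.where(total_i > 0, weighted_f / np.maximum(total_i, 1e-30), 0.0)

        for z in range(config.z_slices):
            d = donor * z_weight[z]
            f_img = fret * z_weight[z]
            if config.shot_noise:
                d = rng.poisson(d).astype(np.float64)
                f_img = rng.poisson(f_img).astype(np.float64)
            if config.read_noise_sd > 0:
                d = d + rng.normal(0, config.read_noise_sd, size=d.shape)
                f_img = f_img + rng.normal(0, config.read_noise_sd, size=f_img.shape)
            d = np.maximum(d, 0.0)
            f_img = np.maximum(f_img, 0.0)
            stack[ti, z, 0] = d / config.gain_ratio
            stack[ti, z, 1] = f_img / config.gain_ratio
            stack[ti, z, 2] = np.minimum(d, config.saturation)
            stack[ti, z, 3] = np.minimum(f_img, config.saturation)

    rois = [
        RoiSet(
            cell=_ellipse_polygon(c.cx, c.cy, c.ax, c.ay),
            nucleus=_ellipse_polygon(c.cx, c.cy, 0.4 * c.ax, 0.4 * c.ay),
        )
        for c in cells
    ]
    truth = {"events": events, "rois": rois, "times": times, "config": replace(config, seed=seed)}
    if return_integrity:
        truth["integrity"] = integrity_maps
    return stack, truth


# ---------------------------------------------------------------------------
# Calibration tables
# ---------------------------------------------------------------------------


def generate_calibration_table(model: PhotophysicsModel, levels) -> list[tuple[float, float]]:
    """Simulated (degradation, normalized R/G) calibration points.

    Runs the cuvette workflow per integrity level — mixture composition,
    channel emission, R/G — and normalizes to the fully intact ratio.
    """
    from .calibration import compute_rg, mix_integrity_sample, simulate_channels

    levels = sorted(set(float(x) for x in levels), reverse=True)
    i520_ref, i625_ref = simulate_channels(mix_integrity_sample(1.0), model)
    rg_ref = compute_rg(i625_ref, i520_ref)
    out = []
    for lvl in levels:
        i520, i625 = simulate_channels(mix_integrity_sample(lvl), model)
        out.append((1.0 - lvl, compute_rg(i625, i520) / rg_ref))
    return out
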
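"""Pipeline tying the stages together: simulate → R/G image → ROI stats → events.

The pipeline consumes a multi-dimensional TIFF/OME-TIFF stack (axes
T, Z, C, Y, X) with a declared channel map, runs dual-gain fusion,
background correction and ratio imaging per frame, extracts per-cell
compartment traces from ROI polygons, detects release events on the cytosol
traces, fits the release-rate and persistence-mode summaries, and writes a
machine-readable JSON report plus all intermediate artifacts.  All
randomness funnels through the single seed recorded in the report, so a
rerun on the same inputs is byte-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from . import calibration as cal
from . import event_kinetics as ek
from . import rg_imaging as rgi
from . import roi_stats as rs

logger = logging.getLogger("frit")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "write_stack",
    "read_stack",
    "process_frame",
    "transfection_concentration_nm",
    "CHANNEL_NAMES",
]

CHANNEL_NAMES = ("donor_low", "fret_low", "donor_high", "fret_high")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (YAML-serializable)."""

    channel_map: dict = field(
        default_factory=lambda: {name: i for i, name in enumerate(CHANNEL_NAMES)}
    )
    theta_min: float = rgi.THETA_MIN
    theta_max: float = rgi.THETA_MAX
    intensity_floor: float | str = "auto"
    background: float | str = "auto"
    saturation_level: float = 255.0
    gain_ratio: float | None = None
    c_intact: float = cal.DEFAULT_C_INTACT
    calibration_anchors: tuple = cal.DEFAULT_ANCHORS
    calibration_params: dict | None = None  # y0/A1/t1/A2/t2 override
    rise_factor: float = 2.0
    fall_factor: float = 1.2
    n_cells: int | None = None  # denominator for rates/occupancy
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [n for n in CHANNEL_NAMES if n not in self.channel_map]
        if missing:
            raise ValueError(f"channel map lacks channels: {missing}")
        if not self.theta_min < self.theta_max:
            raise ValueError("theta_min must be below theta_max")

    def curve(self) -> cal.CalibrationCurve:
        if self.calibration_params:
            return cal.CalibrationCurve(c_intact=self.c_intact, **self.calibration_params)
        return cal.default_calibration(
            c_intact=self.c_intact, anchors=tuple(tuple(a) for a in self.calibration_anchors)
        )

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["calibration_anchors"] = [list(a) for a in self.calibration_anchors]
        Path(path).write_text(yaml.safe_dump(payload))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if "calibration_anchors" in payload:
            payload["calibration_anchors"] = tuple(tuple(a) for a in payload["calibration_anchors"])
        return cls(**payload)


# ---------------------------------------------------------------------------
# Stack I/O
# ---------------------------------------------------------------------------


def write_stack(stack: np.ndarray, path, *, frame_interval: float = 1.0) -> None:
    """Write a (T, Z, C, Y, X) stack as OME-TIFF with channel names."""
    stack = np.asarray(stack, dtype=np.float32)
    if stack.ndim != 5:
        raise ValueError("stack must be (T, Z, C, Y, X)")
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "TZCYX",
            "Channel": {"Name": list(CHANNEL_NAMES[: stack.shape[2]])},
            "TimeIncrement": frame_interval,
            "TimeIncrementUnit": "min",
        },
    )


def read_stack(path) -> np.ndarray:
    """Read a (T, Z, C, Y, X) stack written by :func:`write_stack`."""
    arr = tifffile.imread(path)
    if arr.ndim == 4:  # single time point
        arr = arr[None]
    if arr.ndim != 5:
        raise ValueError(f"expected a 5-D TZCYX stack, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# Per-frame processing
# ---------------------------------------------------------------------------


def process_frame(
    frame_czyx: np.ndarray, config: PipelineConfig
) -> tuple[rgi.RatioImage, np.ndarray, np.ndarray]:
    """One z-slice (C, Y, X) → masked RatioImage + corrected channels.

    Stages: dual-gain fusion per channel, background correction, donor
    intensity floor, ratio image, color rendering, cellmask.
    Returns (masked ratio, corrected donor, corrected fret).
    """
    cm = config.channel_map
    donor, _ = rgi.fuse_dual_gain(
        frame_czyx[cm["donor_low"]], frame_czyx[cm["donor_high"]],
        config.saturation_level, config.gain_ratio,
    )
    fret, _ = rgi.fuse_dual_gain(
        frame_czyx[cm["fret_low"]], frame_czyx[cm["fret_high"]],
        config.saturation_level, config.gain_ratio,
    )
    donor = rgi.background_correct(donor, config.background)
    fret = rgi.background_correct(fret, config.background)
    floor = (
        rgi.intensity_floor(donor)
        if isinstance(config.intensity_floor, str)
        else config.intensity_floor
    )
    ratio = rgi.compute_ratio_image(donor, fret, floor, config.theta_min, config.theta_max)
    color = rgi.render_color(ratio)
    masked = rgi.apply_cellmask(ratio.values, color,
                                theta_min=config.theta_min, theta_max=config.theta_max)
    return masked, donor, fret


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.setdefault("stage_seconds", {})[name] = round(dt, 3)
            if exc is None:
                logger.info("stage %s: done in %.2fs", name, dt)
            else:
                logger.error("stage %s: failed (%s)", name, exc)
            return False

    return _Timer()


def run_pipeline(
    config: PipelineConfig,
    stack_path,
    roi_paths,
    out_dir,
    *,
    times=None,
) -> dict:
    """Run the full analysis on a stack + ROI sets; write artifacts + report.

    Parameters
    ----------
    stack_path:
        TIFF/OME-TIFF with axes (T, Z, C, Y, X) and the config's channel map.
    roi_paths:
        ROI JSON files, one per analyzed cell.
    times:
        Frame times in minutes; defaults to the frame index.

    Writes raw ``.rg`` and color PNG files for the middle z-slice of each
    frame, tidy trace and event CSVs, the fit JSON, and ``report.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "artifacts": {}}
    curve = config.curve()

    with _stage(report, "load"):
        stack = read_stack(stack_path)
        T, Z, C, H, W = stack.shape
        if times is None:
            times = np.arange(T, dtype=float)
        times = np.asarray(times, dtype=float)
        rois = [rs.RoiSet.from_json(p) for p in roi_paths]

    with _stage(report, "rgimage"):
        ratio_values = np.empty((T, Z, H, W))
        donor_corr = np.empty((T, Z, H, W))
        fret_corr = np.empty((T, Z, H, W))
        mid_z = Z // 2
        for t in range(T):
            for z in range(Z):
                masked, donor, fret = process_frame(stack[t, z], config)
                ratio_values[t, z] = masked.values
                donor_corr[t, z] = donor
                fret_corr[t, z] = fret
            rgi.write_raw(rgi.RatioImage(ratio_values[t, mid_z],
                                         theta_min=config.theta_min, theta_max=config.theta_max),
                          out / f"frame_{t:04d}.rg")
            color = rgi.render_color(rgi.RatioImage(ratio_values[t, mid_z],
                                                    theta_min=config.theta_min,
                                                    theta_max=config.theta_max))
            iio.imwrite(out / f"frame_{t:04d}.png", color)
        report["artifacts"]["raw_rg"] = f"frame_*.rg ({T} files)"
        report["artifacts"]["color_png"] = f"frame_*.png ({T} files)"

    with _stage(report, "roistats"):
        all_traces = []
        roi_reports = []
        for i, roi in enumerate(rois):
            traces = rs.compartment_traces(times, donor_corr, fret_corr, ratio_values, roi)
            all_traces.append(traces)
            final = rgi.RatioImage(ratio_values[-1, mid_z],
                                   theta_min=config.theta_min, theta_max=config.theta_max)
            entry = {"roi": i}
            try:
                dist = rs.integrity_distribution(final, roi, "cell")
                entry["integrity_distribution"] = {
                    "green": dist.frac_green, "olive": dist.frac_olive, "red": dist.frac_red,
                }
                entry["fraction_intact_pct"] = rs.fraction_intact(final, roi, curve, "cell")
            except ValueError:
                entry["integrity_distribution"] = None
                entry["fraction_intact_pct"] = None
            roi_reports.append(entry)
            rs.traces_to_frame(traces).to_csv(out / f"traces_roi{i:03d}.csv", index=False)
        report["rois"] = roi_reports

    with _stage(report, "events"):
        events = []
        for i, traces in enumerate(all_traces):
            events.extend(
                ek.detect_events_from_trace(
                    times, traces["cytosol"].mfi_donor,
                    config.rise_factor, config.fall_factor, cell_id=i,
                )
            )
        ek.write_events_csv(events, out / "events.csv")
        n_cells = config.n_cells or max(len(rois), 1)
        report["n_events"] = len(events)
        report["n_cells"] = n_cells
        if len(events) >= 10:
            fit = ek.fit_release_rates(events, n_cells)
            report["release_rates_permille_per_min"] = {
                "rate1": fit.rate1, "rate2": fit.rate2, "breakpoint_min": fit.breakpoint,
            }
        else:
            report["release_rates_permille_per_min"] = None
        hist_events = ek.filter_events(events, "histogram")
        if len(hist_events) >= 30:
            modes = ek.persistence_modes(hist_events)
            report["persistence_modes_min"] = [
                {"mean": m.mean, "sd": m.sd, "weight": m.weight} for m in modes.modes
            ]
        else:
            report["persistence_modes_min"] = None
        occ = ek.occupancy_curve(ek.filter_events(events, "occupancy"), n_cells, times)
        peak_t, peak_f = occ.peak
        report["occupancy_peak"] = {"time_min": peak_t, "fraction": peak_f}
        np.savetxt(out / "occupancy.csv",
                   np.column_stack([occ.times, occ.fraction_fluorescent]),
                   delimiter=",", header="time_min,fraction", comments="")

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def transfection_concentration_nm(
    amount_pmol: float = 8.0,
    mix_volume_ul: float = 1.6 + 29.0 + 1.7 + 7.0,
    added_ul: float = 19.5,
    well_ul: float = 124.5,
) -> float:
    """Final siRNA concentration (nM) of a lipofection recipe.

    A stock amount is diluted into the transfection mix, of which an aliquot
    is added to the medium-filled well; defaults describe a typical
    Oligofectamine protocol (8 pmol in a 39.3-µl mix, 19.5 µl into 124.5 µl).
    """
    in_well_pmol = amount_pmol * added_ul / mix_volume_ul
    return in_well_pmol / (well_ul + added_ul) * 1000.0
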
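"""ROI-based integrity statistics and per-compartment time traces.

Cells are segmented manually into cell outline and nucleus (plus optional
speckle polygons); this module rasterizes those polygons, classifies ratio
pixels into degraded / intermediate / intact color bins, computes the
integrity-weighted fraction of intact siRNA, and extracts mean fluorescence
intensity (MFI) and mean-R/G time traces per compartment with z-averaging.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath

from .calibration import CalibrationCurve, integrity_from_rg
from .rg_imaging import SENTINEL, RatioImage

__all__ = [
    "RoiSet",
    "IntegrityDistribution",
    "CompartmentTrace",
    "rasterize_polygon",
    "integrity_distribution",
    "fraction_intact",
    "compartment_traces",
    "traces_to_frame",
]


def rasterize_polygon(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside a polygon.

    ``polygon`` is a sequence of (x, y) vertices in 0-based pixel
    coordinates; membership uses the even-odd rule on pixel centers, the
    convention of common ROI tooling.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("polygon must be an (N>=3, 2) array of (x, y) vertices")
    rows, cols = shape
    yy, xx = np.mgrid[0:rows, 0:cols]
    centers = np.column_stack([xx.ravel(), yy.ravel()])
    mask = MplPath(poly).contains_points(centers)
    return mask.reshape(rows, cols)


@dataclass
class RoiSet:
    """Named polygons of one cell: outline, nucleus, optional speckles.

    Vertices are (x, y) in 0-based pixel coordinates.  The nucleus must lie
    inside the cell outline after rasterization.
    """

    cell: np.ndarray
    nucleus: np.ndarray
    speckles: list = field(default_factory=list)
    frame: int | None = None

    def masks(self, shape: tuple[int, int]) -> dict[str, np.ndarray]:
        """Rasterize all regions; ``cytosol`` is cell minus nucleus."""
        cell = rasterize_polygon(self.cell, shape)
        nucleus = rasterize_polygon(self.nucleus, shape)
        if np.any(nucleus & ~cell):
            raise ValueError("nucleus polygon must lie inside the cell outline")
        out = {"cell": cell, "nucleus": nucleus, "cytosol": cell & ~nucleus}
        if self.speckles:
            sp = np.zeros(shape, dtype=bool)
            for poly in self.speckles:
                sp |= rasterize_polygon(poly, shape)
            out["speckles"] = sp
        return out

    def to_json(self, path) -> None:
        payload = {
            "cell": np.asarray(self.cell).tolist(),
            "nucleus": np.asarray(self.nucleus).tolist(),
            "speckles": [np.asarray(p).tolist() for p in self.speckles],
            "frame": self.frame,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "RoiSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            cell=np.asarray(payload["cell"], dtype=float),
            nucleus=np.asarray(payload["nucleus"], dtype=float),
            speckles=[np.asarray(p, dtype=float) for p in payload.get("speckles", [])],
            frame=payload.get("frame"),
        )


@dataclass(frozen=True)
class IntegrityDistribution:
    """Fractions of ROI pixels in the three color bins.

    green: R/G < theta_min (strongly degraded); olive: theta_min ≤ R/G ≤
    theta_max (intermediate; boundary values assigned inward for
    determinism); red: R/G > theta_max (intact).
    """

    frac_green: float
    frac_olive: float
    frac_red: float

    def __post_init__(self) -> None:
        total = self.frac_green + self.frac_olive + self.frac_red
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")


def _region_values(ratio: RatioImage, roi: RoiSet | np.ndarray, region: str) -> np.ndarray:
    if isinstance(roi, RoiSet):
        masks = roi.masks(ratio.values.shape)
        if region not in masks:
            raise ValueError(f"ROI set has no region {region!r}")
        mask = masks[region]
    else:
        mask = np.asarray(roi, dtype=bool)
    vals = ratio.values[mask & ratio.foreground]
    if vals.size == 0:
        raise ValueError(f"region {region!r} contains no non-background pixels")
    return vals


def integrity_distribution(
    ratio: RatioImage, roi: RoiSet | np.ndarray, region: str = "cell"
) -> IntegrityDistribution:
    """Green/olive/red pixel fractions inside an ROI region.

    Only non-background pixels count; fractions are of the non-background
    total within the region.
    """
    vals = _region_values(ratio, roi, region)
    n = vals.size
    green = np.count_nonzero(vals < ratio.theta_min)
    red = np.count_nonzero(vals > ratio.theta_max)
    return IntegrityDistribution(
        frac_green=green / n,
        frac_olive=(n - green - red) / n,
        frac_red=red / n,
    )


def fraction_intact(
    ratio: RatioImage, roi: RoiSet | np.ndarray, curve: CalibrationCurve, region: str = "cell"
) -> float:
    """Fraction of intact siRNA in a region, in percent.

    Each non-background pixel's R/G is converted to an integrity percentage
    through the calibration curve; the result is the pixel-fraction-weighted
    sum of those integrities (equivalently their mean), bounded [0, 100].
    """
    vals = _region_values(ratio, roi, region)
    return float(np.mean(integrity_from_rg(vals, curve)))


@dataclass
class CompartmentTrace:
    """Time traces of one compartment: MFI per channel and mean R/G."""

    times: np.ndarray
    mfi_donor: np.ndarray
    mfi_fret: np.ndarray
    mean_rg: np.ndarray
    n_pixels: int
    region: str = "cell"

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("mfi_donor", "mfi_fret", "mean_rg"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match times")


def compartment_traces(
    times,
    donor_stack: np.ndarray,
    fret_stack: np.ndarray,
    ratio_stack,
    roi: RoiSet,
    regions: tuple[str, ...] = ("cell", "nucleus", "cytosol"),
) -> dict[str, CompartmentTrace]:
    """Per-compartment MFI and mean-R/G traces from a (T, Z, Y, X) stack.

    For each time point the region mean is taken per z-slice and averaged
    across z.  The ROI is static across frames, matching the manual
    segmentation workflow (one outline per event).  ``ratio_stack`` is a
    (T, Z) nested sequence of RatioImages or a (T, Z, Y, X) array of ratio
    values with the background sentinel.

    Returns traces for cell (nucleus included), nucleus, and cytosol
    (cell minus nucleus).
    """
    donor_stack = np.asarray(donor_stack, dtype=float)
    fret_stack = np.asarray(fret_stack, dtype=float)
    if donor_stack.ndim != 4:
        raise ValueError("stacks must be (T, Z, Y, X)")
    T, Z, H, W = donor_stack.shape
    times = np.asarray(times, dtype=float)
    if len(times) != T:
        raise ValueError("times length must match the stack's T axis")

    masks = roi.masks((H, W))
    out: dict[str, CompartmentTrace] = {}
    ratio_values = _ratio_values_array(ratio_stack, (T, Z, H, W))
    sentinel_fg = ratio_values != SENTINEL
    for region in regions:
        mask = masks[region]
        if not np.any(mask):
            raise ValueError(f"region {region!r} rasterizes to zero pixels")
        mfi_d = donor_stack[..., mask].mean(axis=-1).mean(axis=1)
        mfi_f = fret_stack[..., mask].mean(axis=-1).mean(axis=1)
        rg_region = np.where(sentinel_fg[..., mask], ratio_values[..., mask], np.nan)
        with warnings.catch_warnings():
            # regions with no foreground pixels at some (t, z) produce NaN
            warnings.simplefilter("ignore", category=RuntimeWarning)
            per_z = np.nanmean(rg_region, axis=-1)
            mean_rg = np.nanmean(per_z, axis=1)
        out[region] = CompartmentTrace(
            times=times,
            mfi_donor=mfi_d,
            mfi_fret=mfi_f,
            mean_rg=mean_rg,
            n_pixels=int(mask.sum()),
            region=region,
        )
    return out


def _ratio_values_array(ratio_stack, shape) -> np.ndarray:
    if isinstance(ratio_stack, np.ndarray) and ratio_stack.shape == shape:
        return ratio_stack.astype(float)
    T, Z = shape[:2]
    values = np.empty(shape, dtype=float)
    for t in range(T):
        for z in range(Z):
            frame = ratio_stack[t][z]
            values[t, z] = frame.values if isinstance(frame, RatioImage) else frame
    return values


def traces_to_frame(traces: dict[str, CompartmentTrace]) -> pd.DataFrame:
    """Tidy CSV-ready table: time, region, mfi_donor, mfi_fret, mean_rg, n_pixels."""
    rows = []
    for region, tr in traces.items():
        for i, t in enumerate(tr.times):
            rows.append(
                {
                    "time": t,
                    "region": region,
                    "mfi_donor": tr.mfi_donor[i],
                    "mfi_fret": tr.mfi_fret[i],
                    "mean_rg": tr.mean_rg[i],
                    "n_pixels": tr.n_pixels,
                }
            )
    return pd.DataFrame(rows)
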
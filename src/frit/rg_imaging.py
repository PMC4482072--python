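"""Pixel-wise R/G ratio imaging on dual-gain two-channel confocal frames.

Each frame is acquired twice per channel: once at low detector gain (bright
lipoplex particles stay unsaturated) and once at high gain (dim cytosolic
signal is resolved).  The two exposures are fused into a single
high-dynamic-range intensity image, background corrected, and divided
(FRET / donor) into a per-pixel R/G ratio image.  Ratio images carry a
background sentinel for non-cell pixels, are color coded green → red for
display, and round-trip through a headerless little-endian raw float64 file
format compatible with ImageJ's "64-bit real" import.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "DualGainFrame",
    "RatioImage",
    "SENTINEL",
    "THETA_MIN",
    "THETA_MAX",
    "fuse_dual_gain",
    "background_correct",
    "estimate_background",
    "intensity_floor",
    "compute_ratio_image",
    "render_color",
    "apply_cellmask",
    "write_raw",
    "read_raw",
]

#: Stored value marking non-cell (background) pixels in ratio images and raw
#: files.  −1 is impossible as a true ratio, so 0 remains a legal R/G value.
SENTINEL = -1.0

#: Default color thresholds: R/G below THETA_MIN renders pure green
#: (degraded), above THETA_MAX pure red (intact), shading in between.
THETA_MIN = 0.5
THETA_MAX = 1.2

#: Pixels at or above this fraction of the saturation level count as
#: saturated during gain fusion.
_SATURATION_FRACTION = 0.95


@dataclass(frozen=True)
class DualGainFrame:
    """One two-channel acquisition at two detector gains."""

    donor_low: np.ndarray
    donor_high: np.ndarray
    fret_low: np.ndarray
    fret_high: np.ndarray
    saturation_level: float = 255.0
    gain_low_setting: float = 0.10
    gain_high_setting: float = 1.00

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.donor_low, self.donor_high, self.fret_low, self.fret_high)}
        if len(shapes) != 1:
            raise ValueError(f"channel images must share one shape, got {shapes}")


@dataclass
class RatioImage:
    """Per-pixel R/G floats with a background sentinel.

    ``values`` stores the unclamped ratio at cell pixels and ``SENTINEL`` at
    background pixels; clamping to the color thresholds happens only at
    render time.
    """

    values: np.ndarray
    theta_min: float = THETA_MIN
    theta_max: float = THETA_MAX
    background_sentinel: float = SENTINEL

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not self.theta_min < self.theta_max:
            raise ValueError("theta_min must be below theta_max")
        fg = self.values != self.background_sentinel
        if np.any(self.values[fg] < 0):
            raise ValueError("non-sentinel ratio values must be non-negative")

    @property
    def foreground(self) -> np.ndarray:
        """Boolean mask of non-background pixels."""
        return self.values != self.background_sentinel

    def foreground_values(self) -> np.ndarray:
        return self.values[self.foreground]


# ---------------------------------------------------------------------------
# Gain fusion and background correction
# ---------------------------------------------------------------------------


def fuse_dual_gain(
    low: np.ndarray,
    high: np.ndarray,
    saturation_level: float,
    gain_ratio: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse a low-/high-gain exposure pair into one HDR intensity image.

    Unsaturated pixels keep the high-gain value; pixels saturated at high
    gain are reconstructed as ``low * g`` where ``g`` is the supplied gain
    ratio or is estimated as the median ratio ``high/low`` over mutually
    unsaturated pixels with a usable high-gain signal (robust regression
    through the origin).

    Returns
    -------
    fused, invalid:
        ``fused`` is the HDR image (float64); ``invalid`` flags pixels
        saturated in both exposures, whose fused value is unreliable.
    """
    low = np.asarray(low, dtype=np.float64)
    high = np.asarray(high, dtype=np.float64)
    if low.shape != high.shape:
        raise ValueError("low and high gain images must have the same shape")
    sat = _SATURATION_FRACTION * saturation_level
    high_saturated = high >= sat
    low_saturated = low >= sat
    if gain_ratio is None:
        usable = ~high_saturated & ~low_saturated & (high > 0.10 * saturation_level) & (low > 0)
        if not np.any(usable):
            raise ValueError(
                "cannot estimate gain ratio: no mutually unsaturated pixels "
                "with usable signal; supply gain_ratio explicitly"
            )
        gain_ratio = float(np.median(high[usable] / low[usable]))
    fused = np.where(high_saturated, low * gain_ratio, high)
    return fused, high_saturated & low_saturated


def estimate_background(channel: np.ndarray, bins: int = 256) -> float:
    """Background level as the mode of the intensity histogram.

    Most pixels in a transfection field are extracellular, so the modal
    intensity is the background.  The mode is located on a histogram and
    refined as the median of the values inside the modal bin (exact for
    quantized data, robust for floats).
    """
    vals = np.asarray(channel, dtype=np.float64).ravel()
    lo, hi = vals.min(), vals.max()
    if lo == hi:
        return float(lo)
    counts, edges = np.histogram(vals, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    right = edges[i + 1] if i < bins - 1 else np.inf
    in_bin = (vals >= edges[i]) & (vals < right) if i < bins - 1 else (vals >= edges[i])
    return float(np.median(vals[in_bin]))


def background_correct(channel: np.ndarray, background) -> np.ndarray:
    """Subtract a background level (scalar, image, or ``"auto"``), clamping at 0."""
    channel = np.asarray(channel, dtype=np.float64)
    if isinstance(background, str):
        if background != "auto":
            raise ValueError(f"unknown background mode {background!r}")
        background = estimate_background(channel)
    background = np.asarray(background, dtype=np.float64)
    if background.ndim and background.shape != channel.shape:
        raise ValueError("background image shape does not match channel")
    if np.any(background < 0):
        raise ValueError("background must be non-negative")
    return np.maximum(channel - background, 0.0)


def intensity_floor(channel: np.ndarray) -> float:
    """Default donor-intensity floor: background + 3·robust σ of background.

    σ is estimated from the median absolute deviation of the sub-background
    residuals (scaled to Gaussian σ), so bright cell pixels do not inflate it.
    """
    bg = estimate_background(channel)
    vals = np.asarray(channel, dtype=np.float64).ravel()
    resid = np.abs(vals[vals <= bg] - bg)
    sigma = 1.4826 * float(np.median(resid)) if resid.size else 0.0
    return bg + 3.0 * sigma


# ---------------------------------------------------------------------------
# Ratio computation, color rendering, cellmask
# ---------------------------------------------------------------------------


def compute_ratio_image(
    donor: np.ndarray,
    fret: np.ndarray,
    intensity_floor: float = 0.0,
    theta_min: float = THETA_MIN,
    theta_max: float = THETA_MAX,
) -> RatioImage:
    """Per-pixel R/G = fret/donor with a donor-intensity floor.

    Pixels whose background-corrected donor signal falls below the floor are
    background (sentinel); everywhere else the unclamped ratio is stored.
    """
    donor = np.asarray(donor, dtype=np.float64)
    fret = np.asarray(fret, dtype=np.float64)
    if donor.shape != fret.shape:
        raise ValueError("donor and fret images must have the same shape")
    if intensity_floor < 0:
        raise ValueError("intensity floor must be non-negative")
    fg = donor >= np.maximum(intensity_floor, np.finfo(float).tiny)
    values = np.full(donor.shape, SENTINEL)
    values[fg] = fret[fg] / donor[fg]
    return RatioImage(values=values, theta_min=theta_min, theta_max=theta_max)


def render_color(ratio: RatioImage) -> np.ndarray:
    """Color-coded uint8 RGB rendering of a ratio image.

    R/G above ``theta_max`` renders pure red (intact siRNA), below
    ``theta_min`` pure green (degraded); ratios in between interpolate
    linearly from green to red, passing through olive at the midpoint.
    Background pixels are black.
    """
    v = ratio.values
    t = (v - ratio.theta_min) / (ratio.theta_max - ratio.theta_min)
    t = np.clip(t, 0.0, 1.0)
    rgb = np.zeros(v.shape + (3,), dtype=np.uint8)
    fg = ratio.foreground
    rgb[..., 0][fg] = np.rint(255 * t[fg]).astype(np.uint8)
    rgb[..., 1][fg] = np.rint(255 * (1.0 - t[fg])).astype(np.uint8)
    # fully green pixels would render (0,255,0); ensure no foreground pixel
    # is accidentally black (can only happen if both channels round to 0,
    # impossible since r+g >= 255 here)
    return rgb


def apply_cellmask(raw_values: np.ndarray, color: np.ndarray, **ratio_kwargs) -> RatioImage:
    """Mask raw R/G values with the cellmask derived from the color image.

    The cellmask is 1 where the color rendering is non-black.  To keep a
    legal ratio of exactly 0 distinguishable from background, masking uses
    the add-one trick: ``(raw + 1)·mask − 1``, so out-of-mask pixels land on
    the −1 sentinel while in-mask pixels keep their exact value.
    """
    raw_values = np.asarray(raw_values, dtype=np.float64)
    color = np.asarray(color)
    if color.shape[:-1] != raw_values.shape or color.shape[-1] != 3:
        raise ValueError("color image must be raw shape + (3,)")
    mask = np.any(color != 0, axis=-1)
    # the +1/-1 offset trick, applied exactly: in-mask pixels keep their
    # bit-exact value (including 0), out-of-mask pixels land on the sentinel
    masked = np.where(mask, raw_values, SENTINEL)
    return RatioImage(values=masked, **ratio_kwargs)


# ---------------------------------------------------------------------------
# Raw .rg file format
# ---------------------------------------------------------------------------


def write_raw(ratio: RatioImage | np.ndarray, path) -> None:
    """Write R/G values as headerless little-endian float64, row-major.

    The format matches ImageJ's raw import: "64-bit real", little-endian,
    no offset, no gap; background pixels carry the −1 sentinel.
    """
    values = ratio.values if isinstance(ratio, RatioImage) else np.asarray(ratio)
    if values.ndim != 2:
        raise ValueError("raw format stores a single 2-D image")
    Path(path).write_bytes(np.ascontiguousarray(values, dtype="<f8").tobytes())


def read_raw(path, shape: tuple[int, int] = (512, 512), **ratio_kwargs) -> RatioImage:
    """Read a raw .rg file back into a RatioImage (bit-exact round trip)."""
    data = Path(path).read_bytes()
    rows, cols = shape
    if len(data) != rows * cols * 8:
        raise ValueError(
            f"raw file holds {len(data)} bytes, expected {rows * cols * 8} for {rows}x{cols} float64"
        )
    values = np.frombuffer(data, dtype="<f8").reshape(rows, cols).copy()
    return RatioImage(values=values, **ratio_kwargs)
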
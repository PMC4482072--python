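# Methods

## The R/G integrity readout

A double-labeled siRNA duplex carries a donor fluorophore on one strand and
an acceptor on the other.  While the duplex is intact, donor excitation is
transferred to the acceptor with efficiency *E* and the sample emits mostly
in the red channel (605–635 nm band, summarized at 625 nm); once the
strands separate, transfer collapses and donor emission (510–540 nm band,
520 nm) recovers.  The ratio R/G = I625 / I520 upon donor excitation is a
population readout: it does not measure the dye–dye distance in a single
molecule but the fraction of molecules in a pixel or cuvette whose dye pair
is still in proximity.

### Cuvette mixture model

A sample of integrity *f* is modeled as the mixture
(f, (1−f)/2, (1−f)/2) of double-, donor-only- and acceptor-only-labeled
duplexes.  Channel intensities follow a four-parameter photophysics model:

    I520 = qD · [ f·(1−E) + (1−f)/2 ]
    I625 = qA·E·f + β·I520 + α · [ f + (1−f)/2 ]

with donor brightness qD, sensitized-acceptor brightness qA, bleed-through
β of donor emission into the red channel, and direct acceptor excitation α.
Defaults are E = 0.9, qD = 1, β = α = 0.05, and qA solved so that the
intact sample reads an image-scale R/G of 5 (the value used for
normalization in imaging).  The fully degraded sample then reads
β + α/qD = 0.1.

The per-duplex fractions halve the single-label amounts relative to the
constant-dye cuvette protocol; `simulate_channels(..., normalize_dye=True)`
rescales both channels by the total labeled strands per mixture, which
restores constant dye totals and leaves every R/G ratio unchanged — the
readout is insensitive to this bookkeeping choice.

### Calibration curve

Normalized R/G (1 at integrity 100 %) versus degradation level d is fitted
with a second-order exponential decay y0 + A1·e^(−d/t1) + A2·e^(−d/t2),
with the constraint y0 + A1 + A2 = 1 enforced exactly so every fitted curve
is normalized at d = 0.  Monotonicity on [0, 1] is checked on a dense grid
at construction; non-monotone fits are rejected with a warning.  Inversion
uses Brent bisection (tolerance 1e−9 in d) for scalars and linear
interpolation on a 20,001-point grid for whole images; the interpolation
error is orders of magnitude below the 0.5-percentage-point round-trip
budget.

The published fit parameters of the cell-calibration curve are not
available, so the **default curve** is fitted through the printed anchor
pairs — image R/G 5 ↔ 100 % intact, 1.2 ↔ 95 %, 0.5 ↔ 80 % — plus a floor
of normalized R/G 0.02 at full degradation (any small positive floor
consistent with the residual red emission of the degraded sample works; the
floor only affects the regime below R/G 0.5 where the method is known to
underestimate integrity and values clamp anyway).  Both the anchors and the
normalization constant c_intact = 5 are configuration parameters.

## Pixel-wise R/G imaging

Each channel is acquired at two detector gains.  Fusion keeps the high-gain
value where it is below 95 % of saturation and replaces saturated pixels by
the low-gain value scaled by the gain ratio, estimated (when not supplied)
as the median high/low ratio over mutually unsaturated pixels with at least
10 % of saturation signal — a robust regression through the origin.  Pixels
saturated in both exposures are flagged invalid.

Background is subtracted per channel; the `"auto"` estimate is the mode of
the intensity histogram (refined as the median within the modal bin), which
is appropriate because most pixels in a transfection field are
extracellular.  The donor intensity floor separating cell from background
pixels defaults to background + 3 robust σ (MAD of sub-background
residuals).  Ratio values are stored unclamped; color rendering clamps to
the thresholds θmin = 0.5 and θmax = 1.2 (green → red linear RGB
interpolation, the exact published lookup table being unstated) and paints
background black.  Raw ratio files are headerless little-endian float64,
row-major — ImageJ's "64-bit real" import — with −1 as the background
sentinel so that a legal ratio of exactly 0 survives the cellmask
(the add-one/subtract-one masking trick, applied exactly).

## ROI statistics

Polygons (0-based pixel coordinates) are rasterized by the even-odd rule on
pixel centers.  Color-bin boundaries are assigned inward: green strictly
below 0.5, red strictly above 1.2, olive closed on both ends — the
published inequalities leave the boundaries open, and inward assignment is
deterministic.  The fraction of intact siRNA in a region is the
pixel-fraction-weighted sum of per-pixel integrities through the
calibration curve.  Compartment traces average region means per z-slice and
then across z; the "cell" trace includes the nucleus, and a cytosol trace
(cell minus nucleus) is always computed alongside, since published
compartment traces are ambiguous about nuclear exclusion.

## Release-event kinetics

* **Filtering.**  Rate fits use all events sorted by onset; persistence
  histograms use single, full-length, first releases; occupancy uses
  full-length events.
* **Occupancy** counts each cell at most once per time point while any of
  its events spans the time (onset ≤ t < onset + persistence).
* **Release rates.**  A continuous two-segment piecewise-linear function is
  fitted to (onset, cumulative count) by least squares; for each candidate
  breakpoint on a 1-min grid the fit is linear in (intercept, slope1,
  slope2), and the breakpoint minimizing the SSE wins.  Slopes are divided
  by the number of observed cells and reported in permille per minute.  The
  fit is exact on exactly piecewise-linear data.
* **Persistence modes.**  Durations are binned at 5 min; local maxima
  (strict neighbor comparison, plateau ties broken toward the earlier bin)
  seed one Gaussian each, fitted per-peak on ±2 bins and refined jointly.
  Gaussian widths are bounded at 1.5 bins and means may move at most one
  bin from their seed, so one component cannot swallow two subpopulations.
  Because a subpopulation hidden on the flank of a larger one need not
  produce a strict histogram maximum, a residual pass seeds an extra mode
  wherever observed counts exceed the fitted sum by more than 2.5·√(fit)
  (a Poisson significance criterion) at least two bins from existing modes,
  and refits; modes whose means collapse to within two bins are merged.
  Mode weight is the empirical occupancy (durations assigned to the nearest
  mode mean), which is far more stable than fitted Gaussian areas when
  components overlap; modes are reported heaviest first.
* **Trace detection.**  Events on a cytosolic MFI trace start when the
  signal exceeds baseline·rise_factor (baseline = median of the pre-onset
  window) and end when it falls below baseline·fall_factor; a trace still
  above threshold at the end is censored.  The published analysis scored
  events manually; this detector exists to close the loop on synthetic
  movies.

## Synthetic data

The generator's defaults are the stated experimental world: 2,376 observed
cells (54 areas × 44 cells) over 360 min; biphasic release at 1.9 ‰ then
0.2 ‰ cells/min with a 30-min breakpoint; persistence times from the
three-mode mixture 0.6·N(24, 5²) + 0.25·N(43, 5²) + 0.15·N(58, 5²)
truncated positive; fading durations from N(46, 10²) truncated positive;
release spreading over 4 min; 512 × 512 px fields, 5 z-slices, 1-min
frames, dual-gain channel pairs (gain ratio 10, saturation 255).  Mode
weights, standard deviations, the repeat probability (0.08), the
integrity-decay rate (0.005 /min) and the fading-duration spread are not
published; the chosen values reproduce the printed aggregates (peak
occupancy ≈5 %, three resolvable modes) and are all config-exposed.  The
46-min figure is modeled as the duration of the fading phase following the
persistence window, which is the reading consistent with fading being
"slower than the release".

Onsets are drawn by per-cell Poisson thinning at 0.1-min resolution.  A
cell with an ongoing event cannot release again until its fading completes
(and then only with the repeat probability), so the observed event rate
sits ~3 % below the hazard rate — the same self-thinning present in the
real experiment, and well within the stochastic recovery tolerances.

Rendered movies contain static elliptical cells with concentric nuclei
(motility contributes nothing to the quantities analyzed), bright fully
intact lipoplex dots, a dim fully intact basal cytosolic signal (so traces
have a nonzero baseline), event-driven cytosolic ramps whose integrity
decays exponentially during dwell, and partially degraded (integrity
0.5–0.9) perinuclear dots accumulating during fading.  Channels derive
per pixel from integrity via the photophysics model; optional Poisson shot
noise and Gaussian read noise are applied per z-slice.  What a green test
on these movies establishes is the correctness of the measurement chain
(fusion → background → ratio → calibration → traces → detection) against
known ground truth; it does not establish robustness to optics the
generator omits (point-spread blur, drift, bleaching, cell motility,
segmentation error).

## Numerical choices and limitations

* All random draws flow through one `numpy.random.Generator`; identical
  seeds give bit-identical event tables and stacks.
* The breakpoint grid step (1 min), the saturation fraction (0.95), the
  usable-signal cut for gain estimation (10 % of saturation) and the
  residual-significance factor (2.5) are fixed design constants, documented
  where they are defined.
* Mode recovery at n = 1000 durations fails for roughly 3 % of random
  draws, when the smallest subpopulation's histogram peak lands more than
  3 min from its generating mean — a sampling limit, not a fitting one.
* The calibration inversion clamps outside [R/G_norm(1), 1]; integrity
  below the green threshold is systematically underestimated by
  construction, mirroring the method's stated dynamic range (80–100 %).
* ImageJ `.roi`/`.zip` ROI input is not supported (no reader available);
  ROI exchange uses JSON polygons.
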
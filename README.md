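# frit — FRET ratiometric integrity toolkit

`frit` quantifies the intracellular fate of FRET-labeled siRNA from
live-cell confocal imaging.  siRNA duplexes carrying a donor dye on one
strand and an acceptor on the other emit mostly red (FRET) light while
intact and mostly green (donor) light once degraded; the red-to-green
emission ratio upon donor excitation — the **R/G ratio** — is therefore a
population-level readout of the fraction of intact duplexes in a cuvette or
in a single image pixel.  The toolkit covers the full workflow:

* **calibration** — simulate cuvette mixtures of double- and single-labeled
  duplexes, predict their two-channel emission from a small photophysics
  model (FRET efficiency *E*, bleed-through β, cross-excitation α), fit the
  R/G-versus-degradation relation with a second-order exponential decay
  `R/G(d) = y0 + A1·e^(−d/t1) + A2·e^(−d/t2)`, and invert it to read
  integrity percentages from measured ratios;
* **rg_imaging** — pixel-wise R/G imaging of dual-gain two-channel frames:
  HDR gain fusion, background correction, thresholded color coding
  (R/G > 1.2 red = intact, < 0.5 green = degraded, shaded in between), and a
  bit-exact headerless raw float64 file format with cellmask logic;
* **roi_stats** — green/olive/red pixel distributions, the
  integrity-weighted fraction of intact siRNA, and per-compartment
  (cell/nucleus/cytosol) fluorescence and R/G time traces with z-averaging;
* **event_kinetics** — cytosolic release-event statistics: occupancy
  curves, a continuous two-segment piecewise-linear fit of the cumulative
  onset curve whose slopes are the per-cell release rates (an early burst
  phase of ≈30 min followed by a sustained low rate), and Gaussian-mode
  decomposition of the persistence-time histogram;
* **simulate** — ground-truthed synthetic data at both levels: event tables
  drawn from the kinetic model, and rendered dual-gain two-channel
  time-lapse z-stacks of cells undergoing release, integrity decay,
  depletion and perinuclear accumulation;
* **pipeline / CLI** — a `frit` command with `simulate`, `calibrate`,
  `rgimage`, `roistats`, `events` and `run` subcommands tying the stages
  together and emitting a machine-readable JSON report.

## Worked example

Simulate 10,000 cells at the default biphasic kinetics and recover the
generating parameters:

```python
import numpy as np
from frit import (SimulationConfig, generate_event_table, fit_release_rates,
                  filter_events, occupancy_curve, persistence_modes,
                  default_calibration, integrity_from_rg)

config = SimulationConfig(n_cells=10_000)
events, _ = generate_event_table(config, seed=17)          # 1206 events

fit = fit_release_rates(events, config.n_cells)
print(f"rate1 = {fit.rate1:.2f} permille/min, rate2 = {fit.rate2:.2f}, "
      f"breakpoint = {fit.breakpoint:.0f} min")
# rate1 = 1.89 permille/min, rate2 = 0.20, breakpoint = 31 min

modes = persistence_modes(filter_events(events, "histogram"))
print([(round(m.mean, 1), int(m.weight)) for m in modes.modes])
# [(23.4, 641), (42.9, 253), (57.5, 165)]

occ = occupancy_curve(filter_events(events, "occupancy"),
                      config.n_cells, np.arange(0.0, 361.0))
t, f = occ.peak
print(f"occupancy peak {100 * f:.1f}% at {t:.0f} min")
# occupancy peak 4.9% at 30 min

curve = default_calibration()
print(integrity_from_rg(0.5, curve), integrity_from_rg(1.2, curve))
# 80.0 95.0
```

The first fit recovers the two release rates (permille of cells releasing
per minute) and the phase breakpoint from the cumulative onset curve; the
mode decomposition finds the three persistence-time subpopulations (means in
minutes, weights in events); the occupancy curve gives the peak fraction of
cells simultaneously showing cytosolic fluorescence; and the calibration
curve maps the color thresholds 0.5 and 1.2 to 80 % and 95 % intact siRNA.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities from scratch by running the package at
its reference parameterization: the two release rates from a fresh
10,000-cell simulation, the three persistence-mode means from 1,000
simulated durations, the integrity percentages at the two color thresholds
under the default calibration curve, and the peak occupancy percentage.
The `--seed` argument drives every random draw; the result is a JSON map
from target id to the computed value and problem size.
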
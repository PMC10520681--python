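# cardiobeam

Contractility analysis for engineered cardiac tissue grown on
magnetically actuated hydrogel thin-film cantilevers.

A side-view camera films a soft cantilever whose tip is pulled down by a
stack of permanent magnets (setting the tissue *preload*) and bent upward
by electrically paced cell contractions. `cardiobeam` turns such videos —
or fully synthetic stand-ins — into cell-generated force traces,
normalized stress–strain loops, and force–length (FL) contractility
indices:

- **`cardiobeam.beam`** — constant-curvature cantilever mechanics.  The
  quasi-static power balance between bending strain energy, the
  distributed magnetic load, viscous drag and cell-layer tension is solved
  forward (deflection from forces, exact exponential integrator) and
  inverse (cell force from tracked tip deflection and velocity).  Two
  static-calibration conventions are shipped; they differ by a constant
  factor 2/3 (`energy_consistent`, the default, makes cell-free data
  invert to exactly zero force; `paper_eq4` is the classical
  uniformly-loaded-cantilever formula).
- **`cardiobeam.magnet`** — closed-form axial field of a cuboid magnet
  stack (dipole `d^-3` far field), a `B·dB/dd` force-density model with a
  single calibratable gain, and empirical calibration curves from
  cell-free deflection-vs-distance measurements (shape-preserving
  monotone interpolation).
- **`cardiobeam.synth`** — ground-truth experiment generator: preload
  hold/release schedules, paced double-exponential twitches whose peak
  force grows with preload strain (`s_FL`, the inotropy knob), forward
  simulated deflections, and anti-aliased grayscale silhouette videos
  with seeded noise.
- **`cardiobeam.tracking`** — frame binarization, beam midline extraction
  (with optional sub-pixel intensity refinement), per-frame quadratic
  fits giving curvature and tip position, and Savitzky–Golay velocity
  estimation.
- **`cardiobeam.analysis`** — per-twitch peak active forces, stress
  normalization to the no-preload baseline, phase-averaged stress–strain
  loops, FL relation fitting (% increase in peak active force vs relative
  preload) and bootstrap comparison of conditions
  ("steeper" / "not distinguishable").

## CLI

```sh
cardiobeam simulate --config config.yaml --seed 1 --out out/sim
cardiobeam track    --frames out/sim/level_00.tif --config config.yaml --out out/traces/level_00.csv
cardiobeam analyze  --traces out/traces --config config.yaml --out out/analysis
cardiobeam all      --config config.yaml --seed 1 --out out/run [--video]
```

`examples/config.yaml` is a complete starting point.  Config values accept
unit tags (`"200 um"`, `"12 kPa"`, `"1 mPa*s"`); everything is SI
internally.  With a `conditions:` list (e.g. baseline vs inotrope-like
`s_FL`), `all` analyzes each condition and reports the bootstrap slope
comparison in `fl_report.json`.

## Conventions

SI units throughout; `x` runs from the clamp to the tip; tip deflection
`W` and curvature are positive downward (image row 0 is the top row);
a magnet below the film pulls `W` positive; contraction of the
top-surface cell layer drives `W` negative; `F_cell > 0` is contractile
tension.
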
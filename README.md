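# patchtension

Quantitative analysis pipeline linking membrane-patch geometry to
mechanosensitive ion-channel activity, with synthetic ground-truth
generators so every stage is testable offline.

The pipeline covers:

- **imaging** — detection of the membrane dome inside a patch pipette by
  line scans parallel to the pipette walls (rolling-mean smoothing, subpixel
  minima) and least-squares circle fitting (algebraic initialisation +
  orthogonal-distance refinement) to obtain the radius of curvature.
- **mechanics** — Laplace's law `T = R·Δp/2` with explicit unit handling
  (µm, mmHg → mN/m; 1 mmHg = 133.322 Pa); tension is a magnitude, the sign
  lives in the curvature.
- **ephys** — sweep processing: baseline subtraction, on-/off-response peak
  magnitudes, optional decay-τ fits, and patch QC (seal ≥ 1 GΩ; ≥ 50 pA for
  cell-attached/inside-out under suction, ≥ 20 pA otherwise).
- **fitting** — per-cell Boltzmann pressure fits, plateau (or per-patch max)
  normalization, pooling into fixed-width bins (1 mN/m tension,
  0.05 µm⁻¹ inverse radius), per-bin-SD-weighted Boltzmann tension fits, and
  saturating-exponential recovery fits, all with standard errors and a
  seeded percentile bootstrap.
- **synthetic** — phantom pipette/membrane images with exact arc ground
  truth, per-response cohorts generated from a curvature–pressure membrane
  model plus a Boltzmann tension channel, and a two-variable gating model
  (instantaneous activation, slow availability) that reproduces
  inactivation during sustained steps, release currents that peak at the
  membrane-flattening pressure, and second-scale recovery from inactivation.
- **pipeline** — config-driven orchestration (simulate → tension →
  normalize → bin → fit) with config hashes, output checksums and a canned
  parameter-recovery reference suite.

## CLI

```sh
patchtension simulate responses --condition cell_attached --out r.csv --seed 1
patchtension simulate images --out imgs/ --radius 2.87
patchtension detect --image imgs/phantom.tif --out profile.csv
patchtension fit-circle --profile profile.csv --out circle.json
patchtension tension --circles circles.csv --pressures pressures.csv --out t.csv
patchtension analyze-sweeps --traces traces/ --manifest manifest.csv --out peaks.csv
patchtension fit-tension --responses r.csv --bin-width 1.0 --normalize plateau --out fits.json
patchtension fit-recovery --peaks recovery.csv --out recovery.json
patchtension run --config run.yaml
patchtension reproduce --out suite/ --seed 0
```

`patchtension reproduce` runs the full parameter-recovery suite (five
tension-curve cohorts at their standard sizes, the recovery time-course
fit, per-cell pressure midpoints and the phantom-imaging round trip) and
writes a table comparing recovered parameters with their generative values.

## Library example

```python
from patchtension import pipeline

res = pipeline.recover_condition("cell_attached", seed=1)
fit = res["fit"]            # SD-weighted Boltzmann fit of binned tensions
print(fit.X50, fit.k)       # half-activation tension (mN/m), slope factor
```
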
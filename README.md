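# mtarray

Quantification of **paraxial microtubule arrays**: how microtubules in
elongating muscle cells (and in reconstituted in vitro assays) become
aligned, bundled and mechanically stable.  The package is for cell
biologists and biophysicists who already have *derived* measurements —
manually traced filaments, plus-end (EB comet) tracks, photoactivated-mark
trajectories, TIRF encounter geometries, gliding-assay tracks, glycerol-
gradient fraction profiles — and need the downstream statistics, plus a
seeded synthetic-data generator so every stage is testable without any
external data.

## What it computes

- **Orientation** — angles of filament segments / growth tracks relative to
  the longitudinal cell axis; the **Kuiper alignment statistic**
  K = d1 + d2, the sum of the maximum deviations of the weighted empirical
  angle CDF above (d1) and below (d2) the uniform CDF (K = 0 disordered,
  K = 1 perfectly aligned); axial asymmetry index; band-occupancy
  fractions; growth speed and duration.
- **Sliding events** — segmentation of photoactivated-mark trajectories
  with the 0.5 μm scoring rule, mean event velocities with the 700 nm/s
  fast flag, and paraxial / off-axis / looping classification (45° and 90°
  rules).
- **Dissipation** — bleach-corrected single-exponential half-life fits,
  t½ = ln 2 / k, and decomposition of the decay rate into
  depolymerisation + transport + bleaching from taxol/azide drug panels.
- **In vitro assays** — encounter angle α between growth directions
  (antiparallel ⇔ α > 90°), zippered-vs-crossed classification with the
  2 μm co-alignment rule, angle-resolved zippering histograms, length
  controls, gliding speed histograms, bundle survival with censoring, and
  3×-intensity bundle scoring.
- **Hydrodynamics** — glycerol-gradient calibration (S linear in elution
  volume), sedimentation coefficients, and frictional ratios
  f/f_min = S_max/S with S_max = 0.00361·M^(2/3).
- **Morphology** — tip-to-tip cell length statistics, the ≥3-nuclei fusion
  index, and the orderliness-vs-length regression (K against mean cell
  length across conditions).

See `docs/methods.md` for the models, defaults and numerical conventions.

## Worked example

```python
import mtarray as mt

# a synthetic traced network inside an elongated cell (kappa = 4
# concentration around the axis), then its alignment statistics
cfg = mt.SynthConfig(seed=1)
geometry, filaments, truth = mt.synthetic.gen_filament_network(cfg)
sample = mt.filament_angles(filaments, geometry)
k = mt.kuiper_statistic(sample)
print(f"K = {k.K:.3f} (d1 = {k.d1:.3f}, d2 = {k.d2:.3f})")
print(f"within ±15° of axis: {100 * mt.fraction_within(sample, 15):.1f}%")

# frictional ratio of a 99 kDa protein sedimenting at 3.6 S
print(f"f/f_min = {mt.frictional_ratio(99_000, 3.6):.2f}")
```

prints

```
K = 0.605 (d1 = 0.299, d2 = 0.306)
within ±15° of axis: 64.2%
f/f_min = 2.15
```

A K of 0.6 on the (−90°, 90°] support reflects a strongly paraxial network
(a uniform network of this size scores ≈0.16); the frictional ratio of
2.1–2.2 is far above the compact-sphere value of 1, the signature of a
highly elongated monomer.

The full pipeline runs from one config:

```sh
mtarray run --config examples/demo.yaml
```

which writes per-stage CSVs, `summary.json` and a Markdown report (add
`plots: true` to the config for PNG figures).  `mtarray simulate` writes
every synthetic input class with ground truth, and per-stage subcommands
(`orient`, `motility`, `dissipation`, `zipper`, `gliding`, `sediment`,
`morph`, `orderliness`) analyse files in the documented CSV/JSON formats.

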
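# Methods

`mtarray` quantifies how microtubule arrays in elongating muscle cells (and
reconstituted in vitro systems) become ordered, bundled and mechanically
stable.  The package operates on *derived* data — filament polylines, point
tracks, intensity series, fraction profiles — never on raw images; trackers
and manual tracing sit upstream.

## Orientation statistics

Every filament segment (or plus-end growth track) is reduced to an angle θ
relative to the longitudinal cell axis.  Undirected (filament) angles are
folded to (−90°, 90°]; directed (growth) angles live on (−180°, 180°].
Filament angles are weighted by segment length, so a long aligned filament
contributes in proportion to the polymer it represents; comet tracks weigh
1 each.

**Kuiper statistic.**  Alignment is summarised by K = d1 + d2, where d1 and
d2 are the largest deviations of the weighted empirical CDF above and below
the uniform CDF on the sample's support.  Both extrema occur at jump points
of the ECDF — d1 on the right limit, d2 on the left — so a single pass over
the sorted distinct angles (ties merged to one jump) is exact.  K ∈ [0, 1]:
0 for a uniform (disordered) sample in the large-n limit, 1 for a point
mass (perfect alignment).  Unlike the classical rotation-invariant Kuiper
test, deviations are computed on the fixed axis-referenced support — the
cell axis is a canonical origin, and an array aligned 90° off-axis must not
score as aligned.

**Asymmetry index.**  A = f_axial − f_perp = 2·f_axial − 1, with f_axial the
weighted fraction of folded angles within ±45° of the axis.  This is a
package definition chosen to mirror the axial-vs-perpendicular colour
convention of directionality maps; it is 0 for uniform, ±1 for purely
axial/perpendicular samples, and invariant under mirroring θ → −θ.

**Growth statistics.**  Track speed is full path length over duration
(μm/min), robust to curved growth; net direction uses the first-to-last
displacement only.

## Sliding-event scoring

Photoactivated tubulin marks rest at their activation site unless motors
slide the underlying microtubule.  An event is scored when a mark moves
more than **0.5 μm** from its current rest reference.  The detector then

1. walks *back* from the threshold crossing to the motion onset (the last
   frame preceding an unbroken run of supra-noise steps), so the scored
   event covers the actual excursion, and
2. walks forward until the per-frame step stays below the noise floor
   (default 0.15 μm = 3 × a 50 nm centroiding precision) for 2 consecutive
   frames, trimming those quiet frames off the scored motion.

Mean event velocity is path length over event duration; events above
**700 nm/s** are flagged fast.  Direction classes are exclusive with
looping taking precedence: *looping* if any two instantaneous directions
within the event differ by more than 90°, else *paraxial* if the net
direction is within 45° of the axis (folded — motion toward either cell tip
counts), else *off-axis*.  Instantaneous directions are estimated over
sliding ≥0.4 μm displacement windows rather than raw frames, because a
frame-scale step at the noise floor carries an essentially random heading.
Frequencies are reported as events·region⁻¹·min⁻¹.

## Dissipation decomposition

Loss of photoactivated signal mixes three first-order channels:
depolymerisation (k_d), transport of marked polymer out of the region
(k_t), and photobleaching (k_b).  Intensities are normalised to t = 0;
bleaching measured in a taxol+azide control is restored additively,
corrected(t) = raw_n(t) + (1 − control_n(t)), which is exact at t = 0 and
first order in the rates.  Its closed-form bias against the true
bleach-free decay, (1 − e^(−k_b t))(1 − e^(−(k_d+k_t)t)), is ~3% RMS at the
default rates over 60 s and is asserted, not hidden, in the tests.

Half-lives come from a least-squares fit of I(t) = A·e^(−kt) on the linear
scale with free amplitude and no offset (log-transforms would inflate noise
at low intensities).  A non-decaying optimum is reported with t½ = ∞, never
raised.  With fits for the four drug conditions, the components follow by
subtraction: k_b from taxol+azide, k_t = k(taxol) − k_b, k_d = k(azide) −
k_b; the residual k(none) − (k_d + k_t + k_b) is reported as a consistency
check.

## Zippering-encounter classification

An encounter of two seed-anchored dynamic microtubules is characterised by
the incident angle α ∈ [0°, 180°] between the growth-direction tangents at
contact, each tangent averaged over 0.5 μm of arc approaching the contact
(damping tracing noise, and insensitive to the post-contact bend of a
zippered filament).  α > 90° ⇔ antiparallel.  The encounter is *zippered*
when post-contact co-alignment extends at least **2 μm** from the contact
along either filament; measuring the run along each filament's growth
direction enforces the polarity rule (both plus ends continue along the
partner lattice).  Co-alignment means the smoothed inter-filament distance
stays below 150 nm: distances are sampled every 50 nm of arc and averaged
over a forward 0.6 μm window.  The 150 nm gap (rather than a raw 100 nm
point threshold) is set by the measurement noise model — with 50 nm
independent tracing noise on both polylines the distance at a true overlap
has ≈70 nm spread, which a point threshold at 100 nm would break almost
surely, while a ≥5° crossing still separates well before 2 μm.  Histograms
use 10° bins by default; empty bins report an undefined (null) fraction.

Length controls measure the arc from the contact to the seed or the nearest
prior crossover, whichever is closer, with a companion filter selecting
unsuccessful encounters at shallow folded angles (10°–30°).

## Gliding assay and bundles

Instantaneous gliding speed is frame-to-frame displacement over the frame
interval, pooled per object type.  Bundle survival at a horizon is the
fraction intact among scoreable bundles; bundles that left the field or
dissociated as intact bundles are right-censored and excluded from both
numerator and denominator.  A region counts as a bundle when longer than
the length threshold **and** more than 3× the intensity of a single
microtubule; two length presets are kept (2.3 μm in-cell, 2.0 μm in vitro)
because the two assays are scored at different resolutions.

## Hydrodynamics

Peak elution volume (from the top of a glycerol gradient) is linear in the
sedimentation coefficient; standards of known S define the line by OLS.
Peak volume is the signal-weighted centroid of the contiguous ≥50%-of-max
region around the maximum — more stable than argmax given 250 μl fractions,
and exact for a symmetric peak centred on a fraction.  Shape then follows
from the frictional ratio f/f_min = S_max/S with S_max = 0.00361·M^(2/3)
(S in Svedbergs, M in Da): ≈1 for a compact sphere, ≫1 for elongated or
disordered proteins.  For a 99 kDa monomer at 3.6 S this gives 2.1 (two
significant figures), the signature of a highly elongated monomer.

## Morphology

Cell length is the straight-line tip-to-tip distance; condition summaries
report mean ± sample SD.  The fusion index is the fraction of scored cells
with ≥3 nuclei over all scored cells (mono- plus multi-nucleated).  The
orderliness-vs-length relationship is an unweighted OLS fit of per-condition
Kuiper K against mean cell length, reported with Pearson r and residuals.

## Synthetic data

Each generator emulates one measurement with ground-truth labels, under the
acquisition conditions of the corresponding experiment: plus-end imaging at
3 s intervals for 120 s; photoactivation marks at 1.6 s for 60 s; 7.5 min
gliding observation at 5 s; 250 μl fractions of a 5 ml gradient.  Key
choices:

- **Orientations** are axial von Mises: θ = φ/2 with φ ~ VM(0, κ), the
  standard doubled-angle construction (κ = 0 is uniform; circular SD of θ
  ≈ 1/(2√κ) rad).  Default κ = 4 gives a visibly paraxial array.
- **Localisation noise** is isotropic Gaussian, σ = 50 nm (typical
  widefield centroiding).  Tracing noise on in vitro polylines is iid per
  vertex and off by default.
- **Sliding events** arrive as a Poisson process (default 0.5 events·
  mark⁻¹·min⁻¹) with log-normal velocities (median 400 nm/s, σ_log = 0.4 —
  positive and right-skewed) and class-structured directions; event
  velocity is floored so every injected event clearly exceeds the 0.5 μm
  scoring rule and the detector noise floor, keeping injected and scoreable
  events identical by construction.
- **Intensity decay** uses rates k_d = 0.010, k_t = 0.005, k_b = 0.002 s⁻¹,
  with drug conditions zeroing the matching rate.
- **Encounters** draw α uniformly on [5°, 175°] (sub-5° grazes are not
  resolvable as encounters); zippering probability is a step model — 0.85
  for antiparallel α ≥ 150°, 0.25 for parallel α ≤ 25°, zero in between —
  reflecting a crosslinker that can bend filaments by at most ~30° and
  strongly prefers antiparallel geometry.  Zippered geometries co-align
  2.3–3.8 μm with a 30 nm lattice offset.
- **Gliding** singles run at 600 ± 50 nm/s; bundles are static until an
  exponential breakup time (default rate 5.5×10⁻⁴ s⁻¹, so ≈78% survive the
  7.5 min observation), with 10% censoring.
- **Gradient** map S = 0.002·v + 0.35 (v in μl); Gaussian peaks of σ =
  300 μl; standard set chymotrypsinogen 2.5 S, ovalbumin 3.5 S, BSA 4.3 S,
  aldolase 7.3 S, all eluting within the gradient.
- **Cells** are Normal in length (107 ± 40 μm control; 82 ± 39 and
  143 ± 58 μm for the shorter/longer conditions) with Bernoulli fusion.

Randomness uses one root seed with a fixed-spawn-key child stream per
generator, so identical configs are bit-identical and adding a generator
never perturbs the others.

**What the generators do not emulate** — and hence what passing tests do
not show about real data: no point-spread rendering or segmentation errors,
no filament curvature or crossing-induced tracing ambiguity, no pauses or
speed fluctuations within a sliding event, no photophysics beyond a single
bleaching exponential, no mechanical model of zippering forces or motor
stepping, and no correlated (systematic) tracing error.  Parameter-recovery
results bound algorithmic error under the stated noise model only.

## Problem sizes and numerical conventions

Test and verification runs use networks of 100 filaments (50 replicates per
concentration for monotonicity), ~500 injected sliding events for
precision/recall, 400–500 encounters per classification check, 200 bundles
for survival, and 50 Monte-Carlo replicates for the half-life,
decomposition and gradient recoveries — sizes at which the binomial and
sampling error bars quoted with each check are meaningful.  Ties in the
ECDF are merged at exact equality; angle folding maps −90° to +90°; all
degenerate inputs (empty samples, flat profiles, zero-length segments,
missing annotations) raise typed errors from `mtarray.errors`, while
non-decaying fits and all-censored survival return flagged values rather
than raising.

## Known limitations

- The Kuiper statistic is compared against a uniform reference only; no
  p-values are computed (the statistic is used as an alignment index, and
  its null distribution under weighting is not implemented).
- The asymmetry index is a declared package definition; other conventions
  (e.g. resultant-length-based) would order conditions similarly but are
  not interchangeable numerically.
- The additive bleach correction is first-order; for k_b·t ≳ 0.3 the
  multiplicative correction would be preferable, but the additive form is
  kept as the package's single documented reading of control subtraction.
- Event detection assumes marks are quasi-stationary between events; slow
  continuous drift would be segmented into spurious events.
- The co-alignment gap/smoothing constants are tuned to the 50 nm tracing
  noise model; data with heavier-tailed tracing error may need a wider gap.
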
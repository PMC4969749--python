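# Methods

## Strain projection onto neurite geometry

A neurite is an ordered space curve **x**(s) parameterised by arc length s
(µm). Curves are resampled to uniform arc-length spacing by linear
interpolation in the cumulative-length parameter (endpoints preserved
exactly; with the default spacing of 1 µm the total-length error on smooth
curves is well below 0.1%). Tangents use centred finite differences in s,
one-sided at the ends.

The classical Frenet normal is undefined on straight segments (curvature
→ 0), which real and synthetic neurites contain. We therefore complete
{**t**, **n**, **b**} by parallel transport: the previous normal is
projected onto the plane orthogonal to the current tangent and
renormalised, seeded by an arbitrary axis pick. The choice is immaterial
downstream: both strain components are functions of **t** alone, and a
test asserts bit-level agreement between differently seeded frames.

Local strain in the curve frame is **E**^(f) = Q **E**∞ Qᵀ, with Q the
row-stack (t, n, b). The axial component is E_c = **t**·**E**∞·**t**. The
axial shear magnitude is defined as

    E_s = ‖E∞ t − (t·E∞·t) t‖,

the transverse part of the strain traction on the neurite cross-section;
it equals √(E^(f)₁₂² + E^(f)₁₃²), is non-negative, vanishes exactly when
**t** is an eigenvector of **E**∞, and attains the familiar 45° maximum
(E_c = −0.15, E_s = 0.15 under 30% uniaxial compression). Under uniaxial
loading every definition of "axial shear" consistent with these three
properties coincides with this one up to normalisation.

Cell means ⟨E_c⟩ and ⟨E_s⟩ are trapezoidal arc-length averages pooled
over all neurites of a cell (length-weighted — equivalent to one long
quadrature over the whole skeleton). The axial mean is computed on the
signed E_c and reported as a compressive magnitude: x3 is the loading
axis, compression is negative internally, and summaries quote positive
compressive strain.

### Strain from a measured displacement field

When a gridded displacement field u(x) is supplied instead of a constant
tensor, the deformation gradient F = I + ∇u uses central differences
(second-order one-sided at boundaries; exact for affine fields to 1e-12)
and E = (FᵀF − I)/2 per node. Tensors are sampled onto curve points by
componentwise trilinear interpolation, which is exact on componentwise
linear fields; points outside the grid hull raise an error naming the
point index. Both the small-strain device convention (transverse ratio
configurable, default 0 per the measured near-uniaxial field) and the
finite Green–Lagrange measure are supported.

### Bleb-local extrema

The maxima of |E_c| and E_s near each bleb are taken over an arc-length
window of ±2 µm (default) centred on the annotated bleb position,
truncated at curve ends. The window width quantifies "immediate
proximity", which has no canonical value; results at these smooth
far-field projections are insensitive to it.

## Robust strain–death-time model

Dead cells contribute pairs (⟨E_c⟩, t_d), ordered (strain, hours)
internally. Survivors are excluded from the fit but retained in cohort
percentages.

### FAST-MCD

The minimum covariance determinant estimator finds the h-point subset
with the smallest covariance determinant. We implement FAST-MCD: 500
random (p+1)-point elemental starts, each refined by C-steps (keep the h
points of smallest Mahalanobis distance under the current estimate,
re-estimate) until the determinant changes by < 1e-9 relative, keeping
the best subset overall. Defaults: h = ⌈(n+3)/2⌉ (≈50% breakdown), seed
mandatory for determinism. The subset covariance is rescaled by the
standard Fisher-consistency factor (h/n) / P(χ²_{p+2} ≤ χ²_{p,h/n});
no outlier-reweighting step is applied, keeping the estimator exactly the
basic MCD. For n ≤ 10 the stochastic search provably lands on the global
optimum found by exhaustive subset enumeration (tested); an independent
cross-check against scikit-learn's raw MinCovDet estimates is included in
the test suite, but the shipped implementation is self-contained.

### Ellipse, eccentricity and the death-time law

The level-α ellipse of the fitted normal has half-axes
√(λ_i · χ²₂(α)) along the covariance eigenvectors (χ²₂(0.95) = 5.991).
Eccentricity √(1 − (|a2|/|a1|)²) is reported both on raw (strain, hours)
units (default) and after per-axis standardisation by the fitted SDs; the
two differ materially because the axes mix units, and neither is
privileged.

The major axis, expressed as t_d = s(c − ⟨E_c⟩), gives the death-time
law: s = |Δt/Δstrain| along a1 and c = μ_strain + μ_t/s. A major axis
parallel to the time axis carries no strain information and raises a
degenerate-relation error. Predictions at strains beyond c are clamped to
zero with a warning.

Known inconsistency of the published parameterisation this package
mirrors: the quoted slope/intercept pair (62.5, 0.265) and the quoted
centroid and major half-axis ((0.107, 9.67 hr), (0.065, 3.94 hr)) agree
only to ~2–3% (3.94/0.065 = 60.6; 62.5 × 0.158 = 9.88 ≠ 9.67). Recovery
tolerances are set accordingly, and tests of the generator's own
consistency use the generator's own line.

## Membrane-permeability traces

Traces are per-cell mean in-cell intensities over time. Smoothing is a
centred moving average, default 3 samples (edge-truncated); the window is
in samples because acquisition cadence varies between experiments.
Influx time (impermeant dye, AFH) is the smoothed-trace argmax; a maximum
on the final sample is censored. Death time (calcein) is the first drop
of the smoothed trace below 50% (configurable) of the baseline, the mean
of the first three samples; no crossing is censored. Censored detections
are excluded from group means with counts reported. The morphological
component of the experimental death criterion is not computable from
traces and is out of scope; the dye-only criterion is used. Group
comparison uses Welch's unequal-variance t-test (two-sided).

## Synthetic cohorts

The generators encode the study conditions as defaults:

| parameter | default | meaning |
|---|---|---|
| applied strain | 0.30 dynamic, 0.38 quasistatic | engineering strain of gel height |
| rate groups | 1e-4, 10, 75 s⁻¹ | labels; quasistatic cells never die |
| death probability | 0 / 0.59 / 0.67 | per group, before viability normalisation |
| bleb probability | 0 / 0.37 / 0.64 | among dead cells, per group |
| death model centroid | (⟨E_c⟩ = 0.107, t_d = 9.67 hr) | bivariate normal mean |
| major 95% half-axis | (0.065, 3.94 hr) | oriented (+strain, −time) |
| minor 95% half-width | 0.014 strain | perpendicular scatter about the line |
| bleb shear | lognormal, mean 0.14, SD 0.03 | per-bleb E_s samples |
| trace grid / noise | 24 h at 0.2 h, 5% | fluorescence sampling |

Neurites are persistent random walks with fixed step length (1 µm):
direction diffuses on the unit sphere with amplitude given by the
tortuosity parameter (0 → straight, uniformly random direction), so arc
length is exact by construction. Neurons carry 2–5 such neurites rooted
at a soma, isotropically oriented. Under 30% uniaxial compression the
isotropic expectation of a straight neurite's ⟨E_c⟩ magnitude is
0.30·E[cos²θ] = 0.10, matching the observed cohort centroid scale
without tuning.

Death times are sampled conditionally: each dead cell's ⟨E_c⟩ comes from
its actual geometry under the far-field tensor, and t_d | ⟨E_c⟩ is drawn
from the conditional of the configured bivariate normal (floored at
0.25 h), keeping geometry and statistics mutually consistent. Shrinking
the minor width to zero collapses deaths exactly onto the model's
major-axis line.

The covariance construction deserves a note. The quoted 95% half-axis
pairs mix units and are not orthogonal in raw (strain, hours) coordinates
— they are orthogonal only under a plot aspect — so they cannot both be
raw-unit principal axes. We take the major principal direction along
(+0.065 strain, −3.94 hr) with SD |a1|/√5.991, and the minor principal
direction as its raw-unit perpendicular with 95% half-width equal to the
minor axis' strain component (0.014), i.e. the strain scatter about the
death-time line. Treating the minor axis norm (≈1.65) as a raw-unit
length instead would imply a strain SD of ≈0.67 — larger than the whole
observed strain range — and destroy the strain–death-time correlation
entirely.

AFH traces are flat at baseline and rise as a sharp Gaussian peak (width
0.6 h) at the cell's death time — influx accompanies membrane
fragmentation; there is deliberately no gradual pre-death rise. Calcein
traces drop sigmoidally below half baseline at death. Survivors are flat
on both channels (censored by construction). A Triton-permeabilised
positive-control preset rises immediately and decays slowly
(photobleaching), so its detected influx is at the start of the
recording. Additive Gaussian noise (fraction of amplitude) is applied and
traces are clipped at zero.

What the generators do not emulate: matrix-fibril-scale strain
heterogeneity (bleb-local shear values are drawn from the configured
distribution rather than computed from microstructure), branching-tree
morphometrics, confocal PSF/noise structure, and any viscoelastic rate
dependence of the gel. Passing recovery tests therefore demonstrates
correctness of the analysis chain under the assumed statistical
structure, not validity of that structure for new experimental data.

## Numerical choices and problem sizes

- χ²₂(0.95) is taken from scipy at full precision (5.9915), not 5.991.
- Resampling spacing default 1 µm; quadrature error on smooth curves
  < 1e-4 at spacing L/1000 (tested on a semicircle against the analytic
  value 0.3/π).
- MCD C-step ties broken by stable argsort; all generators and fits are
  bit-reproducible per seed.
- Test and acceptance problem sizes — 1000-cell ellipse-recovery
  simulations, 10⁴ bleb-shear samples, 200 traces, 10⁵-draw coverage
  checks — were chosen so each estimate's Monte-Carlo error is several
  times smaller than the tolerance it is checked against, while the full
  suite runs in well under a minute.

## Known limitations

- The shear-strain formula is a reconstruction consistent with the
  stated behaviour (see above); alternative normalisations (e.g. maximum
  engineering shear) would scale E_s by a constant.
- Root-to-leaf SWC paths double-count shared branches of branching
  trees in the length-weighted average; the synthetic generator produces
  unbranched neurites, where the average is exact.
- The death-time law is a descriptive major-axis relation, not a causal
  or survival model; censoring of survivors is handled by exclusion, not
  by likelihood.
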
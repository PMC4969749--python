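# neurostrain

Strain-to-injury analysis for neurons compressed in 3D hydrogel culture.

When a collagen gel carrying embedded cortical neurons is uniaxially
compressed — as in an *in vitro* model of blunt-impact traumatic brain
injury — every neurite experiences the far-field strain tensor **E**∞
through its own 3D orientation. `neurostrain` implements the quantitative
chain from that far-field deformation to single-cell injury statistics:

1. **Geometry → local strain.** Neuron skeletons (SWC, or synthetic space
   curves) are resampled by arc length and equipped with local frames
   {**t**, **n**, **b**}. The local axial strain along a neurite is
   *E*_c = **t** · **E**∞ · **t** and the local axial shear strain is
   *E*_s = ‖**E**∞**t** − (**t**·**E**∞·**t**)**t**‖. Cell-level summaries
   ⟨*E*_c⟩ and ⟨*E*_s⟩ are arc-length averages over all neurites. A
   measured displacement field can replace the constant tensor: the
   Green–Lagrange strain E = (FᵀF − I)/2 with F = I + ∇u is computed on
   the grid and interpolated onto each curve.
2. **Bleb statistics.** Local strain extrema near neurite blebs (focal
   swellings, the hallmark injury morphology) are extracted in arc-length
   windows and summarised by a prevalence-scaled inverse CDF.
3. **Robust death-time law.** Per-cell pairs (⟨*E*_c⟩, *t*_d) — mean
   compressive axial strain versus hours to cell death — are fitted with a
   FAST-MCD (minimum covariance determinant) robust bivariate-normal
   estimator, implemented in-package. The 95% confidence ellipse of the
   fit yields a linear death-time law along its major axis,
   *t*_d = *s* (*c* − ⟨*E*_c⟩), with slope *s* in hours per unit strain
   and zero-death-time strain intercept *c*.
4. **Membrane permeability.** Mean in-cell fluorescence traces of an
   impermeant dye (AFH) and a live-cell dye (calcein AM) are analysed for
   influx time (smoothed-trace peak) and death time (drop below a baseline
   fraction), with Welch t-tests across groups.
5. **Synthetic cohorts.** Deterministic, seeded generators produce neurite
   geometries, cohorts, traces and displacement fields with the study's
   statistical structure, so the entire pipeline is testable without any
   imaging data.

The API follows the statsmodels convention: `StrainDeathModel` is built
from data and `fit()` returns a `StrainDeathResults` with estimates,
ellipse, death-time relation, `predict()`, `summary()` and `plot()`.

## Worked example

```python
import numpy as np
from neurostrain import (CohortConfig, StrainDeathModel, generate_cohort,
                         generate_neuron, mean_strains,
                         uniform_compression_tensor)

# one synthetic neuron under 30% uniaxial compression
neuron = generate_neuron(7, n_neurites=3, cell_id="demo")
tensor = uniform_compression_tensor(0.30)
s = mean_strains(neuron, tensor)
print(f"mean_Ec {s.mean_Ec:.4f}  mean_Es {s.mean_Es:.4f}")
# mean_Ec 0.1612  mean_Es 0.1151

# a cohort: geometry-derived strains, group-wise death and bleb outcomes
records = generate_cohort(CohortConfig(seed=7))
res = StrainDeathModel.from_records(records).fit(seed=7)
print(res.summary())
```

```
Strain–death-time robust bivariate fit (FAST-MCD)
====================================================
n obs                         58
h (subset size)               31
confidence level            0.95
----------------------------------------------------
centroid <Ec>             0.0772
centroid t_d [hr]         11.271
major half-axis a1    (-0.0466 strain, +3.554 hr)  |a1| = 3.554
minor half-axis a2    (-0.0135 strain, -0.000 hr)  |a2| = 0.014
...
death-time law: t_d = s (c − <Ec>)
  slope s [hr/strain]      76.30
  intercept c             0.2249
```

The cell above averaged a compressive axial strain of 0.16: with three
randomly oriented neurites under 30% compression, the cell-mean axial
strain lands between 0 (all neurites transverse) and 0.30 (all axial).
The fitted cohort law says a cell at ⟨*E*_c⟩ = 0.0772 (the robust
centroid) dies around 11.3 h post impact, and extrapolates to immediate
death at a strain of 0.22; on 58 dead cells the fit is noticeably looser
than on a 1000-cell simulation, where slope and intercept recover the
generating values closely.

A shell pipeline mirrors the library:

```bash
neurostrain simulate --seed 7 --out cohort.csv
neurostrain fit cohort.csv --seed 7 --out fit.json
neurostrain report --seed 7 --out run/        # full pipeline + run log
```

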
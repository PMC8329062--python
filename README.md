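# spinemorph

Statistical shape analysis of paraspinal muscle cross-sections on axial MRI
slices.

Unilateral lumbosacral disc herniation is expected to leave side- and
level-specific traces in the multifidus (MF) and erector spinae (ES)
muscles, but the conventional measures — cross-sectional area (CSA) and
fatty infiltration (fat%) — often show no side asymmetry.  `spinemorph`
implements the more sensitive alternative: a point-distribution statistical
shape model (SSM) of the muscle outlines.  Bilateral segmentations at two
spinal levels (L5-S1 and S1) are traced into arc-length-corresponded landmark
contours, mirrored into a canonical side, averaged into a bilaterally
symmetric template by generalized Procrustes analysis (GPA), and decomposed
by PCA into orthogonal shape modes.  Each sample's mode coefficients

&nbsp;&nbsp;&nbsp;&nbsp; **b** = Φᵀ(**x** − **x̄**),&nbsp;&nbsp;
**x** ≈ **x̄** + Φ**b**

(with Φ the orthonormal mode matrix retaining the smallest number of modes
whose cumulative variance reaches 90%) are then correlated with the side of
pathology, sex, and age by Spearman partial correlation — rank-transform all
columns, residualize the ranks of the tested pair on the covariate ranks,
and compute Pearson's r of the residuals, with p from
t = ρ·√((n−2−k)/(1−ρ²)) on n−2−k degrees of freedom.

Because clinical MRI cohorts of this kind are not publicly distributable,
the package ships a first-class synthetic-cohort generator that reproduces
the statistical structure such a study assumes: 24 adults (11 F / 13 M, age
41.5 ± 7.9 y, herniation on the left in 15), star-shaped Fourier muscle
outlines with sex/age-linked elongation and size effects, a localized medial
bulge on the affected-side multifidus at S1, and bimodal fat/lean T2-like
intensity texture with sex/age-linked fat fractions.  Every effect amplitude
is recorded in a ground-truth table so recovery can be tested exactly.

## Worked example

```python
import spinemorph as sm

cfg = sm.CohortConfig(seed=1)                      # 24 subjects, 2 levels
samples, subjects, truth = sm.generate_cohort(cfg)

# shape model for the multifidus at S1 (2 samples/subject: both sides,
# in the canonical right frame)
results, template, coeffs = sm.shape_analysis_for_group(samples, subjects, "S1", "MF")
print(results)

assoc = sm.analyze_modes(coeffs, sm.subjects_frame(subjects))
side = assoc[assoc.factor == "side_role"]
print(side[["response", "rho", "p_value", "significant"]].head(4).to_string(index=False))
```

prints

```
Point distribution model
  samples: 48, landmarks: 100
  modes retained: 7 (cumulative 91.2% >= 90% threshold)
  mode 1: 68.0% of variance
  mode 2: 8.9% of variance
  mode 3: 4.8% of variance
  mode 4: 4.0% of variance
  mode 5: 2.6% of variance
  mode 6: 1.5% of variance
  mode 7: 1.3% of variance
    response       rho  p_value  significant
S1-MF mode 1  0.334441 0.023104         True
S1-MF mode 2  0.220380 0.141097        False
S1-MF mode 3 -0.224263 0.134048        False
S1-MF mode 4  0.729478 0.000000         True
```

Mode 4 (4.0% of shape variance) is the injected medial-bulge direction: its
side_role p-value is 8.9 × 10⁻⁹ (printed 0.000000 at this precision), and
its ±3 SD variant `results.mode_variant(4, ±3)` moves most at the medial
sector near the spinous process.  Mode 1 — mediolateral elongation — also
correlates with sex and age, and k-means fat% recovers the generated fat
fractions to within 0.003.

The same analysis runs end-to-end from the shell:

```bash
spinemorph run --seed 1 --out runs/demo          # simulate ... report
spinemorph simulate --seed 1 --out runs/cohort   # cohort files only
```

writing the morphometry table, shape-model archives, mode-coefficient and
association CSVs, significant-mode summary, mode-variant figures
(mean in orange, +3 SD toward the factor in green, −3 SD in red), and a JSON
run manifest.  Reruns with the same config and seed are byte-identical.
`load_real_layout()` ingests user-supplied segmentations written in the same
file layout the generator produces.

## Package layout

| module | contents |
| --- | --- |
| `spinemorph.cohort` | synthetic cohort generator (contours, rasters, intensities, ground truth) |
| `spinemorph.preprocess` | percentile-landmark intensity standardization |
| `spinemorph.morphometry` | CSA, exact 1-D 2-means fat segmentation, fat%, Dice reliability |
| `spinemorph.shape` | contour extraction, mirroring, GPA template, `PointDistributionModel` → `ShapeModelResults` |
| `spinemorph.stats` | partial Spearman and the cohort-level association analyses |
| `spinemorph.pipeline`, `spinemorph.cli` | end-to-end orchestration, file IO, figures, `spinemorph` CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults, and
known limitations.
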
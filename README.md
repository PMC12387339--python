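# lenscurve

Quantifying anterior crystalline-lens curvature from multi-radial
Scheimpflug annotations.

During accommodation the ciliary muscle releases zonular tension and the
crystalline lens steepens; with age this response fades (presbyopia).
`lenscurve` implements an analysis pipeline for studying that response in
vivo from manually annotated Scheimpflug cross-sections: each of the 16
radial cuts of an eye carries five points on the anterior lens capsule plus
two anterior-chamber-depth (ACD) landmarks, and the package turns those
pixel coordinates into meridian-resolved curvature descriptors and a full
non-parametric statistical analysis. It is aimed at vision scientists
working with anterior-segment imaging who need a transparent, reproducible
alternative to device-embedded curvature software.

## Method

Each cut's five capsule points determine the general conic

    a x² + 2hxy + b y² + 2gx + 2fy + n = 0

exactly (null direction of the design matrix with rows
`(x², 2xy, y², 2x, 2y, 1)`; total least squares for >5 points). From the
fitted coefficients the package derives the eccentricity *e* (via the
canonical semi-axes, cross-checked against the invariant closed form), the
asphericity *Q = −e²* and the shape factor *SF = 1 − e²*. Because *e* is
invariant under similarity transforms, fitting in pixel space is valid
under the isotropic calibration (default 28 µm/px, derivable from apical
pachymetry); the same scale converts the apex–reflex landmark distance to
ACD in mm.

The 16 cuts are grouped into two 22.5° meridional sectors — horizontal
(core cuts 1, 13, 14) and vertical (core cuts 5, 6, 7), the rest
transitional — and each sector's eccentricity is the mean over its core
cuts (non-elliptical fits are flagged and excluded). Per subject and
sector, the response to accommodative demand (0, 1, 3, 5 D) is expressed
relative to the 0 D baseline: values below 1.0 mean a steeper lens. The
statistical battery mirrors the study design: Pearson correlations of age
with accommodative amplitude and facility, Wilcoxon signed-rank between
meridians (exact small-sample null distribution), Kruskal–Wallis across age
groups, and Friedman tests across demands with signed-rank post hocs at the
Bonferroni-corrected threshold 0.05/6 ≈ 0.0083.

Because the clinical images are not public, the package includes a phantom
generator (`lenscurve.phantom`) that emulates the full study design —
elliptical capsule arcs sampled within each subject's pupil aperture, with
accommodative miosis, chamber shallowing and age-group response profiles —
so every pipeline stage is testable against known ground truth.

## Worked example

```python
import lenscurve as lc

cohort = lc.generate_cohort(lc.PhantomConfig(seed=11), profile_override="TG")
results = lc.AccommodationStudy.from_cohort(cohort).fit()
print(results.summary())
```

prints (abridged):

```
Accommodation study results
==================================================
subjects: 104; rows: 832

Total-group mean relative eccentricity:
sector  horizontal  vertical
demand
0.0         1.0000    1.0000
1.0         0.8977    0.9149
3.0         0.7635    0.8244
5.0         0.5201    0.6052

Friedman across demands (p, * = significant at corrected threshold):
   horizontal vertical
TG    0.000 *  0.000 *

age_vs_AA: r = -0.819, p = 2.43e-26, y = -0.282 x + 19.30 (n = 104)
```

The relative-eccentricity table is the accommodation response: by 5 D the
horizontal meridian has dropped to ≈0.52 of its baseline eccentricity
(a markedly steeper surface), the vertical to ≈0.61, and the Friedman tests
confirm the within-subject change across demands. The age–AA line is the
expected presbyopic decline built into the phantom's aging model.

The same analysis runs from the shell:

```sh
lenscurve simulate --seed 11 --out sim/
lenscurve analyze sim/annotations.csv --metadata sim/metadata.csv --out results/
```

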
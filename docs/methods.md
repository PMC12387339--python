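# Methods

## Conic fitting

Each radial cut is analysed independently in its own 2-D image plane. The
five capsule landmarks determine the general conic
`a x² + 2hxy + b y² + 2gx + 2fy + n = 0` exactly: the coefficient vector is
the null direction of the 5×6 design matrix with rows
`(x², 2xy, y², 2x, 2y, 1)`. With more than five points the same
smallest-singular-direction solve is the total-least-squares fit. Points
are centred and isotropically rescaled before the solve (RMS radius √2) and
the coefficients mapped back, which keeps interpolation residuals near
machine precision even for pixel coordinates of order 10⁴. The homogeneous
scale/sign ambiguity is fixed by unit Euclidean norm with `a + b ≥ 0`
(first nonzero coefficient positive when `a + b = 0`).

Classification uses the discriminant `δ = h² − ab` and the full 3×3
determinant `Δ`, both with tolerance 1e−12 — but measured after rescaling
the coefficients by the norm of the quadratic part `(a, h, b)`. This is a
deliberate numerical choice: for a conic far from the coordinate origin the
unit-norm vector is dominated by the constant term and `Δ` shrinks like the
cube of the quadratic scale, so an absolute threshold would misclassify
exactly-fitted but translated ellipses as degenerate and break the
similarity invariance of the eccentricity, which is the property that makes
pixel-frame fitting legitimate under isotropic calibration.

Eccentricity is computed from the canonical semi-axes
(`e = √(1 − (b/a)²)`, axes from the eigen-decomposition of the quadratic
block) and cross-checked on every call against the invariant closed form
`e² = 2√((a−b)² + 4h²) / (η(a+b) + √((a−b)² + 4h²))`; disagreement beyond
1e−10 (or 1e−12 on `e²`, the formula's native scale near `e = 0`) raises
rather than silently reconciling. `Q = −e²` and `SF = 1 − e²`, the standard
ophthalmic-optics relations for a prolate section, so `Q + 1 = SF` holds as
an exact float identity. Parabolic fits return `e = 1`; hyperbolic or
degenerate fits raise a flagged-shape error — noisy shallow arcs can cross
the `δ = 0` boundary, and the sector aggregation must know rather than
receive a coerced number. Fits whose two smallest singular values are
within a factor of 10 of each other additionally emit an ill-conditioning
warning (short arcs barely constrain the conic).

## Calibration and ACD

A single isotropic scale (default 28 µm/px) converts pixels to mm; it can
be derived as apical pachymetry divided by its pixel span. ACD is the
Euclidean distance between the corneal-apex and lens-reflex landmarks times
the scale; an `axis_only` variant projects onto the vertical image axis
instead (the two coincide for an on-axis chamber, and the choice between
them is not determined by the study description — Euclidean is the
default). Anisotropic scales are deliberately not modelled: they would
break the similarity invariance of eccentricity.

## Sector reconstruction

Acquisition order is not angular order. Sector membership therefore follows
fixed lists — horizontal core {1, 13, 14}, vertical core {5, 6, 7},
transitional {8–12} and {2–4, 15–16} — and the cut-index → angle map is
configuration, defaulting to the three core cuts of each sector at −11.25°,
0°, +11.25° around its principal meridian (the 22.5° wedge at the
scanner's 180°/16 spacing). Sector eccentricity is the arithmetic mean of
per-cut eccentricities over the core cuts; transitional cuts are excluded
by default (a flag includes them) because the study design distinguishes
"included" from "transitional" cuts without stating that the latter enter
any number — exclusion is the conservative reading. Pooling points across
cuts into one fit is intentionally not offered: the cuts are sections of a
generally non-rotationally-symmetric surface in different planes, so a
pooled 2-D fit would be geometrically meaningless.

Relative response series divide each subject/sector trajectory by its own
0 D value (exactly 1.0 at baseline). Group curves average the per-subject
relative values; the alternative order (normalise the group-mean absolute
eccentricity) is available behind a flag for sensitivity analysis. Age
groups are closed-open decades [20, 30), …, [60, ∞); subjects younger than
20 are excluded with a warning.

## Statistics

All tests are rank-based, mirroring the study's analysis plan.

* Wilcoxon signed-rank (meridian comparisons, Friedman post hocs): zeros
  dropped, mid-ranks for tied absolute differences. For ≤25 retained pairs
  the two-sided p comes from the exact null distribution, computed by
  shift-convolution over doubled mid-ranks (exact even under ties); larger
  samples use the normal approximation with continuity and tie corrections.
  The exact route matters because the oldest groups have n ≤ 12, where the
  approximation is poor. Implemented in-package: no standard routine offers
  the exact-with-ties/zero-drop combination; it is cross-checked in the
  tests against full 2ⁿ sign enumeration and against the large-n
  approximation.
* Kruskal–Wallis (age-group comparisons) and Friedman (within-subject
  demand comparisons) use the tie-corrected chi-square forms; rows with any
  missing demand are dropped listwise, never imputed. Identical-data
  degenerate cases return statistic 0, p = 1, flagged.
* Pearson correlations (age vs AA, age vs MAF) report r, the two-sided
  t-test p and the least-squares line.
* Bonferroni correction for the C(4,2) = 6 demand contrasts sets the
  post-hoc threshold at 0.05/6 ≈ 0.0083, applied with strict inequality
  (a p exactly at the threshold is not significant). The post-hoc pairwise
  test after Friedman is the signed-rank test — the standard companion;
  the study design does not name one.

Cells whose group is too small for a test are reported `NA`, never filled.

## Phantom generator

The generator emulates the study conditions, not any particular patient:

* **Cohort design** — 104 subjects in five decade groups at four demands
  (0, 1, 3, 5 D), 16 cuts per eye, 5 points per cut. The published group
  sizes (58/20/12/10/6) sum to 106 while the study total — and the
  16 × 104 = 1664 dataset-size arithmetic — is 104; the generator resolves
  this internal inconsistency by defaulting the youngest group to 56.
* **Response profiles** — group-mean relative eccentricities are the
  published values where printed (all of G2–G5; the 5 D endpoints 0.531/
  0.606 for the total group and 0.414/0.491 for G1). The unprinted total-
  group and G1 values at 1 D and 3 D are smooth monotone interpolations
  chosen once. Baseline absolute eccentricities (0.78 horizontal, 0.80
  vertical — the vertical meridian sits slightly higher, as observed)
  are package choices; absolute baselines are not printed.
* **Forward model** — per cut, a prolate ellipse with apex radius R and
  the cut's target eccentricity (`a = R/p`, `b = R/√p`, `p = 1 − e²`),
  sampled at five lateral positions spread over the subject's pupil
  aperture with ±20%-of-spacing jitter and exact sag. R defaults to 7.0 mm
  at 0 D, steepening 0.3 mm/D (accommodation increases curvature).
  Transitional cuts interpolate their target e linearly in meridian angle
  between the two sector values, keeping the surface continuous.
* **Biometry** — pupil diameter starts at the published group baselines and
  shrinks per dioptre (stronger miosis in younger groups), which feeds back
  into the sampled arc span: higher demands genuinely sample shorter arcs,
  reproducing the clinical caveat that small pupils limit peripheral
  capsule access. ACD starts at the published unaccommodated group means
  and shallows per dioptre (G1's slope reproduces the published
  3.95 → 3.79 mm drop). AA and MAF are linear in age with negative slopes
  chosen to reproduce strong negative age correlations (r ≈ −0.8), noise
  floored at zero.
* **Noise** — between-subject (sd 0.04 on baseline e), within-subject
  (1% multiplicative per demand) and landmark placement noise (isotropic
  Gaussian, default 0.02 px). The landmark default was fixed by a
  pre-build Monte-Carlo calibration of the 5-point fit over pupil-limited
  arcs: 0.02 px is the level at which single-cut recovery is approximately
  unbiased (|bias| < 0.01, per-cut sd ≈ 0.05–0.08, no hyperbolic
  flagging), so that the configured group profiles are recoverable by the
  pipeline — the generator's stated purpose. This is far below manual
  annotation precision; see Limitations.

Everything derives from one seeded `numpy` generator, so identical configs
and seeds give byte-identical output files. A `null_config` +
`null_profiles` pair removes every demand effect (flat profiles, no miosis,
no shallowing) for type-I-error studies.

### What passing tests do and do not show

The phantom demonstrates that the pipeline is correct and calibrated: it
recovers known geometry exactly without noise, recovers configured group
means under the calibrated noise, and its statistical battery is quiet
under the null. It does not demonstrate performance on real Scheimpflug
annotations, whose landmark noise (of order a pixel) is ~50× the calibrated
default, and whose capsule deviates from a perfect conic. At realistic
annotation noise, a 5-point fit over a pupil-limited arc is severely
ill-conditioned — the sag difference between neighbouring eccentricities is
a fraction of a pixel — so per-cut estimates would scatter widely and
sector/cohort averaging would carry the inferential burden. Variance
parameters are therefore emulation devices, not estimates of the real
cohort's dispersion, and the battery's p-values on phantom data say nothing
about the clinical effect sizes.

## Problem sizes in the shipped runs

The test suite uses a 13-subject cohort for pipeline-level checks, the full
104-subject cohort for design arithmetic and total-group recovery, 10⁴
random ellipses for the fit-accuracy sweep and 2000-replicate null
simulations per statistical test. The acceptance script regenerates the
104-subject total-group cohort (6656 conic fits) per run. These sizes were
chosen so a complete run finishes in well under a minute per heavy test
while keeping Monte-Carlo error far below the decision tolerances
(seed-to-seed sd of the recovered 5 D group means ≈ 0.007; the recovery
tolerance is 0.035 ≈ 4 sd plus residual ratio bias, also fixed pre-build).

## Known limitations

* The calibrated landmark noise understates real annotation error by design
  (see above); the package quantifies, but cannot remove, the intrinsic
  ill-conditioning of 5-point conic fits on short arcs.
* Only the anterior capsule is modelled; no posterior surface, lens
  thickness, gradient index, or 3-D surface reconstruction across cuts.
* The ACD landmark convention (Euclidean vs axial) and the exact anatomical
  definition of the lens-reflex point are configurable assumptions.
* Age-group edges, sector membership lists and the angle map are fixed
  configuration mirroring one scanner's acquisition pattern.
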
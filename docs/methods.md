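# Methods

## Overview

`faceshape` reimplements, as a tested pipeline, the analysis chain of a
cross-cultural facial-attractiveness study design: 2-D facial landmark
configurations are superimposed, reduced to two shape statistics per face —
sexual shape dimorphism (SShD) and averageness — and related to 7-point
attractiveness ratings from several rater groups through interrater
agreement, linear mixed models with rater-group contrasts, Pearson
correlation screens, and recursive path models with permutation p-values.
A synthetic-data generator with fully known ground truth makes every stage
testable by parameter recovery.

## Geometric morphometrics

**Superimposition.** Generalized Procrustes analysis removes translation,
scale and rotation: configurations are centered, scaled to unit centroid
size, and iteratively rotated to the running consensus until the consensus
changes by less than `tol` (default 1e-8, `max_iter` 20). The distance
measure is the *partial* Procrustes distance (chord distance between
unit-size preshapes after optimal rotation); full-Procrustes and geodesic
variants are available but the partial variant drives all reported scores,
since averageness is used only as a comparable scalar. Reflections are never
permitted — faces have handedness. The final orientation is anchored by
optimally rotating the consensus onto the first specimen's preshape, which
makes the procedure idempotent on its own output; all reported statistics
are invariant to this (or any) global rotation convention.

**Tangent projection.** Aligned shapes are projected orthogonally onto the
tangent space at the consensus (`x_t = c + x − (x·c)c` on vectorized unit
preshapes). The projection is idempotent and preserves Procrustes distances
to first order; at chord distance 0.2 from the consensus the distortion is
of order d³/8 ≈ 1e-3, far below the shape variation in facial data.

**Semilandmark sliding.** Semilandmarks (curve/outline points without exact
homology) are slid along their local tangent direction — the unit vector
from the before-neighbor to the after-neighbor — to minimize the thin-plate
-spline bending energy of the deformation from the consensus to the
configuration. The TPS kernel is U(r) = r² log(r²) with the affine part in
the null space; the bending-energy matrix is the upper-left k×k block of the
inverse bordered TPS system, and the sliding amounts solve the standard
generalized-least-squares system in closed form. One sliding pass runs per
outer GPA iteration, against the current consensus, followed by re-centering,
re-scaling and re-alignment.

A property of this slide-then-realign loop worth documenting: the bending
energy objective has a near-neutral direction in which all semilandmarks
drift slowly along the outline while the consensus co-moves. The loop
therefore reduces bending energy monotonically but the consensus keeps
changing at a slowly decaying rate, and with sliding enabled the `converged`
flag is typically false at `max_iter`. This is a property of the sliding
formulation, not a defect of the implementation; results are deterministic,
the energy reduction is achieved within a few passes, and all downstream
scores are stable. The flag is reported honestly rather than suppressed.

**Shape scores.** SShD comes from a joint (both-sex) superimposition: with
female mean f, male mean m and grand mean g in tangent coordinates, each
face scores ((x−g)·v)/‖v‖ with v = f−m, so positive values are
female-typical and units are Procrustes units (an alternative ‖v‖²
normalization is exposed, under which the female-male mean gap is 1).
Averageness is the partial Procrustes distance of each face to its own-sex
consensus from a *separate per-sex* superimposition; the column is exported
as `avrg` ("distance from the average"). BMI is weight [kg] / height [m]².

## Synthetic data

The generator emulates a study with 50 faces per sex and 72 landmarks of
which 36 are outline semilandmarks (all configurable). Three orthonormal
displacement fields are drawn once from the seeded RNG in the 2k−4
dimensional tangent space of the template (Gram–Schmidt after projecting out
translations, scaling and rotation), so the true effects are separable and
parameter recovery is well-posed:

- a dimorphism field, with the female and male means separated by
  `dimorphism_magnitude` (default 0.05 Procrustes units, a typical facial
  sexual-dimorphism magnitude);
- age and BMI fields scaled per year and per BMI unit (defaults 0.001 each,
  giving covariate-driven shape displacements of up to ~0.02 over the
  age range — comparable to, but smaller than, the dimorphism signal);
- independent per-coordinate individual variation (default SD 0.002, which
  yields mean averageness ≈ 0.03, in the range reported for real faces) and
  digitization noise (default SD 0.0005).

Ages are uniform on 19–36 and BMI is Normal(23, 2.5²) truncated to
[15, 40]; heights are sex-typical Normals and weight is back-computed so
that weight/height² equals the drawn BMI exactly. With `nuisance` enabled,
each raw configuration is randomly rotated (uniform), scaled (LogNormal(0,
0.1)) and translated (Normal(0,1) per axis) before digitization noise — the
invariances GPA must remove.

Ratings follow a cumulative-threshold (ordinal) latent model: for rater i of
group g and face j, latent = intercept_g + β_age,g·z(age) + β_bmi,g·z(bmi) +
β_avrg,g·z(avrg) + β_sshd,g·z(sshd) + u_i + v_j + ε, cut at six thresholds
(default −2.5 … 2.5) into 1..7; raters rate only opposite-sex faces. The
default group weights make averageness the dominant cue (−0.40 for the
reference group), age and BMI mildly negative and SShD weak, with small
between-group differences — the qualitative pattern reported for this kind
of study. Variance components default to rater SD 0.7, face SD 0.6,
residual SD 0.9 on the latent scale, matching the magnitudes such mixed
models typically estimate from Likert attractiveness data. The rating
distribution and cutpoints are a modelling choice: no empirical rating
histogram was available to calibrate them.

What the generator does *not* emulate: photographic variation, landmark
digitization by human observers (noise is isotropic Gaussian), non-linear
preference functions, rater drift over trials, or any mechanism of the
other-race effect beyond group-specific preference weights. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not the field validity of the study design.

## Rating analyses

**Interrater agreement** is Cronbach's alpha with raters as items and faces
as cases, after listwise deletion of raters with any missing rating:
α = N/(N−1) · (1 − Σ var_r / var_total), sample variances with n−1. The
mixed model, by contrast, uses all individual ratings — the two analyses
deliberately filter missing data differently.

**Correlation screen.** Pearson zero-order correlations among per-group mean
attractiveness, age, BMI, SShD and averageness, two-sided p from the t
transform, adjusted across the full set of pairs. Holm is the default
adjustment (uniformly more powerful than Bonferroni with no dependence
assumptions); Bonferroni is available by flag. Pairs with a constant
variable are flagged, not silently dropped.

**Mixed model.** One model per face sex on individual ratings: fixed effects
are the four face predictors (z-standardized across the rated faces),
rater-group main effects and group × predictor interactions (reference
group CZ); random effects are rater intercepts, rater slopes on each
predictor, and face intercepts. Raters and faces are crossed, which the
statsmodels `MixedLM` engine expresses as variance components within a
single group; a consequence is that the rater random intercept and slopes
are mutually *uncorrelated* — the fully correlated rater covariance of the
lme4 formulation is not expressible in this engine, and random-effect
correlations are accordingly not reported. Predictors are standardized by
default (flag to disable) so coefficients are comparable across predictors.
Ratings are modeled as numeric despite their ordinal generation, exactly as
such studies analyse Likert scores. Gradient optimizers flag spurious
non-convergence when variance components sit on the zero boundary, so the
fit falls back to Powell's method in that case. Fixed-effect t tests use
residual degrees of freedom (no Satterthwaite approximation is available in
this engine), which is mildly liberal for between-rater effects at small
rater counts.

**Group contrasts.** For each coefficient family (intercept or one
predictor's slope), the three pairwise group differences are linear
combinations of fixed effects; SEs come from the fixed-effect covariance
and adjusted p-values from a single-step max-|t| test under the trivariate
t distribution with the contrasts' estimated correlation — the behavior of
the general-linear-hypothesis (glht-style) simultaneous test, which unlike
classical Tukey HSD applies to slopes as well as means. The reference df is
a containment-style choice, n_raters − n_groups: every group contrast is a
between-rater comparison, so the rater level bounds the information. Under
the generator's null this keeps the familywise error of the three contrasts
at or below the nominal 0.05 (slightly conservative), where a plain normal
reference was measurably liberal at small rater counts.

## Path model

The recursive path model over {age, BMI, SShD, averageness, attractiveness}
uses the DAG: age → {bmi, sshd, avrg, attractiveness}; bmi → {sshd, avrg,
attractiveness}; sshd → attractiveness; avrg → attractiveness. All
variables are z-standardized and each endogenous variable is regressed on
its parents by OLS — for a recursive latent-free system this equals the
maximum-likelihood path solution equation-by-equation, so no SEM machinery
is needed. Attractiveness enters as the per-group mean rating per face, and
the pipeline runs six fits (3 rater groups × 2 face sexes). Single-parent
standardized coefficients equal Pearson r exactly (asserted in tests).

**Permutation p-values.** Because such models are fit at modest n (50 faces
per sex), analytic p-values are complemented by a Monte-Carlo permutation
test: in each of n_perm (default 10,000) randomized datasets every variable's
column is permuted independently — destroying all inter-variable association
while preserving marginals — the full model is refit, and the two-sided
add-one p is (1 + #{|β*| ≥ |β|})/(n_perm + 1), which cannot be zero. The
comparison includes a 1e-12 slack so floating-point ties (exact at small n)
count as exceedances. Independent column permutation is the full-null
randomization implied by comparing observed coefficients against "expected
coefficients under randomness"; a Freedman–Lane residual-permutation variant
for conditional nulls is available behind a flag. Reports mark p < 0.05 as
significant and 0.05 ≤ p < 0.1 as a nonsignificant trend (apostrophe).

## Pipeline and reproducibility

One global seed fans out to independent substreams (template fields, face
simulation, rating simulation, one permutation stream per path fit) via
`numpy` `SeedSequence` spawning, so disabling one stage never shifts
another's randomness and the whole run is byte-reproducible: the same
config and seed produce identical result CSVs (the manifest's timings
excepted). Data CSVs are written with shortest-round-trip float formatting
and read with round-trip parsing, so a files-mode run on the written
synthetic data reproduces the in-memory results exactly. The quasi-Monte-
Carlo evaluation of multivariate-t box probabilities in the contrast
adjustment uses a fixed internal stream (accuracy ~1e-4 on p) for the same
reason.

## Problem sizes used in the test suite

Unit tests run on small templates (12–20 landmarks, 8–20 faces per sex,
3–8 raters per group), chosen so that each property is exercised in seconds.
The calibration checks use: 200 replicates of the all-null path model
(n = 100, n_perm = 500); 200 replicates of the null mixed model (20 faces,
8 raters per group); and the dimorphism-recovery check runs at the full
study scale (50+50 faces, 72 landmarks with sliding). These sizes are the
package's own test design; all thresholds were fixed from the statistical
properties being tested, not from observed outcomes.

## Known limitations

- 2-D landmarks only; no 3-D GPA, no relative warps/PCA, no
  symmetry/asymmetry decomposition.
- The mixed-model engine cannot express correlated rater random effects
  (see above); df are residual-based rather than Satterthwaite.
- The sliding loop's convergence flag is conservative (see above).
- No ordinal (cumulative-link) mixed models: ratings are analysed as
  numeric by design, mirroring the analysis chain the package replicates.
- No latent-variable SEM, fit indices, or indirect-effect decompositions:
  only direct path coefficients are estimated and reported.
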
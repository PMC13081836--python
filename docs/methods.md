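# Methods

This note documents the models and procedures the package implements, the
choices made where the design was genuinely open, what the synthetic
generators emulate, and the known limitations.

## Streamline geometry and clustering

Streamlines are polylines in world millimetres. All pairwise comparisons
use the minimum average direct-flip (MDF) distance on arc-length resampled
copies with a common point count K (default 20; MDF requires matched
counts, and K = 20 keeps a 60–80 mm pathway sampled every 3–4 mm, enough to
separate bundles while keeping clustering cheap). Pointwise distances are
sorted before averaging so that symmetry and flip-invariance hold exactly
in floating point, which in turn makes centroid selection bitwise
reproducible across platforms.

Curvature is the mean Menger (circumscribed-circle) curvature over interior
point triples: κ = 4·area(p₀,p₁,p₂)/(|p₀p₁||p₁p₂||p₀p₂|). On
arc-length-resampled curves this is parameterization-robust and
orientation-invariant; it converges to 1/R on circles at dense sampling.

Clustering is deterministic greedy threshold assignment: streamlines are
visited sorted by id, each joins the first cluster whose running
orientation-consistent mean polyline is within the MDF threshold, else
founds a new cluster. This is a deliberately simple, fully reproducible
grouping step; the scientific content of atlas construction lies in the QC
criteria and the centroid rule (argmin of median MDF, ties to the lowest
member index), both of which are exercised independently of how clusters
were formed.

## Reliability QC

ICC is the two-way random-effects, single-measurement, absolute-agreement
form ICC(2,1) computed from ANOVA mean squares — the standard estimand for
scan–rescan designs, where systematic visit effects should count against
agreement. A one-way variant is available via `variant="one_way"`. Values
are clipped to [−1, 1] (the ANOVA ratio can fall below −1 on tiny degenerate
tables). Pre-clustering QC removes ROI pairs with fiber-count ICC
strictly below 0.4; post-clustering QC removes clusters below a minimum
size or whose centroid profile reliability falls below the same threshold.
The post-clustering criterion is interpreted as *reliability* of the FA
profile (not FA magnitude); the magnitude reading is implementable by
passing mean-FA values as the reliability table.

Parcel merging requires all four criteria simultaneously: spatial
adjacency, same functional network, fiber-count-profile correlation > 0.7,
and non-decreasing mean fiber-count ICC after summing the two regions'
counts. Candidates are visited once in descending profile correlation;
each region merges at most once per pass. The merge log records the four
criterion values for every candidate so decisions are auditable.

## Projection

Scalar volumes are sampled by trilinear interpolation
(`scipy.ndimage.map_coordinates`, order 1), exact on linear fields. At each
centroid point the perpendicular plane is spanned by a deterministic
orthonormal basis (helper axis = smallest tangent component), and a polar
grid covers a filled disc: ring spacing equals the step (default 0.1 mm),
angular pitch ≈ the step, enumerated center-first so ties at the maximum
resolve to the candidate nearest the centroid point, then fixed grid order.
The default 4 mm radius bounds the search the way skeleton-projection
methods bound their perpendicular search; both radius and step are
configurable, and points whose entire disc leaves the volume are masked.
Recorded center coordinates are reused verbatim to sample other volumes,
so co-located extraction of the source volume is bit-identical to the
projection.

## Elastic alignment

Profiles on [0,1] are aligned in the square-root slope function (SRSF)
representation q = sign(f′)√|f′|, in which the Fisher–Rao metric is the L2
metric and a warp γ acts as (q∘γ)√γ′. The pairwise alignment energy is

    ‖q_template − (q_f∘γ)√γ′‖² + λ_eff ∫ (√γ′ − 1)² dt,

minimized by dynamic programming on a P×P grid with coprime step slopes
between 1/4 and 4 and midpoint-rule segment costs on a 4× refined grid
(numba-compiled). The identity penalty (√γ′−1)² is the squared SRSF
distance of γ from the identity — the natural regularizer in this
geometry — and λ_eff = λ·L/100 mm grows linearly with streamline length so
long pathways warp more conservatively (a fixed fractional warp moves more
millimetres on a long tract). Flat profiles (q ≈ 0) return the identity
warp by convention, as phase is unidentifiable there.

Because the SRSF differentiates the profile, measurement noise is strongly
amplified; alignment therefore computes q from a short cubic
Savitzky–Golay fit (window 5 by default in cohort alignment) while
returned aligned profiles keep raw values. Cohort templates iterate
align-all / average-aligned-profiles; averaging in function space is exact
for identical inputs and avoids the O(h²) error of integrating a mean
SRSF. The recorded energy trace is non-increasing by construction: the
iteration stops and reverts to the previous state when a step fails to
decrease it. Per-pathway diagnostics record variance reduction and maximum
warp distortion. Alignment is per-pathway within a cohort (the cohort
elastic mean is the template); aligning against a fixed external template
is available through `align_pair`.

## Feature embeddings

Fiber-level features are pathway-mean profile values. Voxel-level features
are, per pathway, subject scores on the top 3 principal components of the
subject × grid-point matrix plus the pathway mean (complete-case over grid
points; masked columns dropped). Network-level features pool the
constituent pathways' PC score columns within each functional network pair
and re-decompose, retaining the smallest component count whose cumulative
explained variance reaches the contribution threshold (default 0.70,
intended tuning range 0.70–0.95). Component signs follow the
largest-|loading|-positive convention so scores are reproducible. All
fitted transforms (means, SDs, loadings) are stored and applied out of
sample without touching apply-set statistics. Outliers are flagged at 5
median absolute deviations; a zero MAD degenerates the rule, in which case
nothing is flagged and a warning is emitted. FC edge vectors are z-scored
per edge and PCA-encoded per network pair; decoding inverts the loadings
and the z-scoring exactly, so a full-rank codec round-trips losslessly.

## Evaluation statistics

avgcorr demeans observed and predicted edge vectors by the training-set
mean before correlating, so shared population structure does not inflate
the score. avgrank follows the printed normalization (inner sum divided by
n_subj), bounding it by (n−1)/n with equality under perfect identification;
a `normalization="n-1"` switch gives the [0,1] variant. Subjects with
degenerate (constant) vectors are excluded and logged. The
pathway→network-pair contribution is the maximum over edges of the
cross-subject correlation between pathway-mean FA and the predicted edge —
a best-match summary chosen because one pathway is expected to drive only
a few edges; the maximum of many null correlations is positively biased
(≈ √(2·log m / n)), which downstream interpretation must keep in mind.
The network SC matrix averages pathway-mean FA per network pair, with 0
denoting absence of any atlas pathway for that pair. Signed decomposition
splits a fitted coefficient vector by sign and projects features on each
part; the two parts sum to the linear predictor exactly.

Brain-age gap is predicted minus chronological age. Correction is
cross-fitted: a seeded half-split, raw BAG regressed on age within each
half, and each record corrected with the *other* half's fit, so no record
influences its own correction. Trait associations regress z-scored
corrected BAG on one z-scored trait at a time plus covariates (a covariate
sharing the trait's name is dropped for that trait), with Bonferroni
flagging at α/n_traits.

## Lifespan trajectories

The model y ~ f(t) + Δ(t)·sex + site + ε uses cubic B-spline bases (12
functions per smooth) with second-order difference penalties (P-splines)
and smoothing chosen by generalized cross-validation via a coordinate-wise
log-grid search — a deliberate substitution of GCV for a REML mixed-model
engine that keeps the penalized-cubic-spline model class while avoiding
mixed-model machinery; one test cross-checks the fitted curves against an
independent R mgcv fit of the same model. Sites are fixed one-hot offsets
(reference = first site); sites with fewer than 2 samples pool into the
reference. Peak ages are grid argmaxima at 0.1-year resolution, flagged
when they sit on the domain boundary.

Sex-difference windows use a simultaneous band Δ̂ ± c·se(t) where c is the
(1 − α/n_tests) quantile of the parametric-bootstrap max-|t| statistic
(2000 draws, seeded). Two covariances are computed: the Bayesian form
σ²(XᵀX+S)⁻¹ for point summaries, and the unpenalized form σ²(XᵀX)⁻¹ for
the band. The band uses the unpenalized (upper-bound) covariance because
the plug-in covariance ignores the sampling variability of data-driven
smoothing selection and measurably under-covers under the null; the
unpenalized form is conservative by construction and holds the family-wise
error below the nominal level in null simulations. Normalized trajectories
divide the fitted curve by its value at a reference age (default 3 years,
clamped into the fitted range within a 2-year margin since sampled cohorts
rarely contain the exact domain edge).

## Synthetic generators

One global seed fans out to per-generator child seeds through
`SeedSequence(entropy=seed, spawn_key=(generator_index, stream))`, so adding
a generator never perturbs existing fixtures. The generators emulate:
bundles as smooth normal-plane offsets around a known centerline; FA
volumes as Gaussian ridges (σ 6 mm, peak 0.8) around centerlines, optionally
modulated along-tract by a warped mother profile; profile cohorts as
mother ∘ γᵢ + amplitude + noise with monotone boundary-fixed warps;
test–retest tables from the variance-components model with
ICC = σ²_subj/(σ²_subj+σ²_noise); FC edges as dense linear mixtures of
pathway FA with noise scaled to a target per-edge R² (one designated
pathway exclusively drives one edge so contribution ranking has a known
answer); and lifespan cohorts with a Gaussian developmental rise (scale
0.15, width 20 years) plus a gentle quadratic late-life decline on a 0.35
FA baseline — peak ages 25 (male) / 28 (female) by default — with residual
noise SD 0.025, in the range of cross-subject network-mean FA residuals.

What the generators do *not* emulate: realistic diffusion signal or
tractography errors (no false-positive streamlines, no partial-volume
bias), anatomically realistic parcellations or surface geometry,
non-Gaussian site effects, or longitudinal within-subject correlation.
Passing recovery tests therefore demonstrates correctness and calibration
of the algorithms under their stated models, not robustness to the failure
modes of real tractography.

## Problem sizes and numerical choices

Validation experiments run at: 100 random clusters (size ≤ 12) for the
centroid oracle; 1000 streamline pairs for MDF properties; a 64³ 1 mm
phantom at 0.1 mm search step; 50 warps on a 101-point grid; 200 random
avgcorr/avgrank instances (≤ 10 subjects, ≤ 20 edges); 100 test–retest
cohorts of n = 500; 20 SC→FC cohorts of n = 500 (R² = 0.3, 10 pathways, 40
edges); n = 2000 for BAG correction; 100 lifespan cohorts of n = 3000 and
500 null simulations of n = 300 for band calibration; and a 30-subject ×
40-pathway end-to-end pipeline run (projection step 0.5 mm at pipeline
scale). DP alignment tolerances: warp slopes bounded in [1/4, 4], Karcher
tolerance 1e-4, at most 20 iterations (8 in the cohort pipeline).

## Limitations

Greedy threshold clustering is order-dependent by design (made
deterministic by sorting) and is not a substitute for learned dictionary
clustering at whole-brain scale. The DP warp grid bounds the warp slope at
4, so extreme phase distortions are unreachable. GCV can undersmooth
relative to REML on small cohorts, and the conservative band trades power
for guaranteed error control. PLS/elastic-net predictive modeling is
intentionally out of scope — any regressor with fit/predict can be plugged
into the SC→FC scaffolding, and ridge regression is used in validation.
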
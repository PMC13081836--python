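# tractometry

Connectome-oriented tractometry for diffusion MRI: build a pathway-centroid
atlas from streamlines, project scalar maps (FA, MD, ...) onto atlas pathways
with sub-voxel precision, elastically align along-tract profiles across
subjects, construct fiber-/voxel-/network-level feature embeddings, and
evaluate structure–function coupling, brain-age-gap statistics and lifespan
trajectories. Everything is testable end-to-end on synthetic cohorts with
known ground truth.

The package is aimed at researchers analyzing large tractography cohorts who
want pathway-resolved, functionally annotated white-matter statistics rather
than voxelwise skeleton statistics.

## The core machinery

**Pathway atlas.** Streamline endpoints snap to the nearest labeled cortical
surface vertex (L2 nearest neighbor), fibers are grouped by unordered ROI
pair, and ROI pairs with fiber-count test–retest reliability ICC < 0.4 are
removed (two-way random-effects, absolute-agreement ICC(2,1) from ANOVA mean
squares). Adjacent same-network parcels whose fiber-count profiles correlate
above 0.7 are merged when merging does not reduce mean reliability. Within
each ROI pair, fibers are clustered on the minimum average direct-flip (MDF)
distance

    MDF(a, b) = min( mean_i |a_i − b_i| , mean_i |a_i − b_{K−i+1}| )

on K-point arc-length-resampled polylines, and each cluster is represented by
its *centroid fiber*

    s* = argmin_{s ∈ C} median_{u ∈ C, u ≠ s} MDF(s, u),

the member with the smallest median MDF distance to the others.

**Projection.** For each centroid point, the subject volume is searched over
a disc perpendicular to the local tract tangent (default radius 4 mm, step
0.1 mm, trilinear interpolation) for the maximum value; the location of that
maximum — the tract center — is recorded and reused to extract co-located
values from the subject's other volumes.

**Elastic alignment.** Along-tract profiles f: [0,1] → R are aligned in the
square-root slope function representation q = sign(f′)√|f′|, where the
optimal warp solves

    min_γ ‖q_template − (q_f ∘ γ)·√γ′‖² + λ_eff ∫ (√γ′ − 1)² dt,

by dynamic programming over monotone boundary-fixed warps, with
λ_eff = λ·L/100 mm scaling the identity penalty by streamline length L.
Cohort templates are elastic means (align-and-average iteration with a
non-increasing energy trace).

**Evaluation.** Predicted vs observed connectivity is summarized by

    avgcorr = Σ_s corr(X_s − μ_tr, X̂_s − μ_tr) / n_subj
    avgrank = Σ_s ( Σ_{a≠s} [corr(X_s, X̂_a) < corr(X_s, X̂_s)] / n_subj ) / n_subj

(the inner avgrank sum is divided by n_subj, so perfect identification gives
(n−1)/n). Pathway→network-pair contributions are the maximum cross-subject
correlation between pathway-mean FA and any predicted edge in the pair.
Brain-age gap (predicted − chronological age) is corrected by a cross-fitted
linear age regression (each half-split corrected with the other half's fit).
Lifespan trajectories use the additive model y ~ f(t) + Δ(t)·sex + site with
penalized cubic B-splines and GCV smoothing; peak ages are the fitted-curve
maxima, and sex-difference age windows come from a simultaneous confidence
band for Δ(t) (parametric bootstrap of the max-|t| statistic, Bonferroni
over network pairs).

## Worked example

```python
import numpy as np
from tractometry.streamlines import (resample_streamline, cluster_streamlines,
                                     select_centroid, streamline_length, mean_curvature)
from tractometry.synthetic import gen_bundle, gen_ridge_volume
from tractometry.projection import project_scalar

# a bent pathway centerline, ~60 mm long, and a 20-fiber bundle around it
t = np.linspace(0, 1, 40)
centerline = np.column_stack([10 + 50*t, 40 + 8*np.sin(np.pi*t), np.full_like(t, 40.0)])
tract, truth = gen_bundle(centerline, n_fibers=20, spread_mm=1.5, seed=7)

resampled = [resample_streamline(s, 20) for s in tract.streamlines]
clusters = cluster_streamlines(resampled, threshold=5.0)
centroid = select_centroid(clusters[0], {r.source_id: r for r in resampled})
print(f"clusters: {len(clusters)}; centroid length {streamline_length(centroid):.1f} mm, "
      f"mean curvature {mean_curvature(centroid):.4f} /mm")

# a Gaussian-ridge FA phantom along the same centerline, projected onto the centroid
vol, _ = gen_ridge_volume(centerline, peak_value=0.8, sigma_mm=6.0, shape=(64, 64, 64))
profile = project_scalar(vol, centroid, radius=4.0, step=0.1)
print(f"projected FA: mean {np.nanmean(profile.values):.3f}, "
      f"max deviation from the 0.8 ridge peak {np.nanmax(np.abs(profile.values - 0.8)):.4f}")
```

Output:

```
clusters: 1; centroid length 53.4 mm, mean curvature 0.0204 /mm
projected FA: mean 0.798, max deviation from the 0.8 ridge peak 0.0027
```

The 20 fibers collapse into one cluster (they share a centerline); the
selected centroid is ~53 mm long with the gentle curvature of the sine bend,
and the perpendicular max-search recovers the phantom's 0.8 ridge amplitude
to within 0.003 despite the 2 mm bundle spread.

## Command-line pipeline

`tractometry run-all <workdir>` generates a synthetic mini-cohort
(30 subjects × 40 pathways by default) and runs every stage — atlas,
projection, alignment, features, evaluation metrics, lifespan trajectories —
writing CSV/JSON outputs with config-hash provenance. Individual stages are
available as `generate`, `build-atlas`, `project`, `align`, `features`,
`evaluate` and `trajectories`; identical config and seed reproduce outputs
byte-for-byte.

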
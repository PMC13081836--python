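"""Synthetic-recovery validation experiments for every pipeline component.

Each function runs one self-contained experiment on generated data with
known ground truth and returns the measured quantities as a small dict
(including the problem size under ``n``).  The test suite asserts on these
measurements; ``scripts/acceptance.py`` re-runs them from scratch and
reports them.
"""

from __future__ import annotations

import numpy as np

from .atlas import icc
from .elastic import ProfileFunction, align_pair
from .lifespan import LifespanSample, fit_trajectory, peak_age, sex_difference_intervals
from .metrics import PredictionSet, avgcorr, avgrank, bag_bias_correct, BAGRecord, sc_fc_contribution
from .projection import project_scalar
from .streamlines import Cluster, ResampledStreamline, mdf_distance, select_centroid
from .synthetic import (
    gen_lifespan_cohort,
    gen_ridge_volume,
    gen_sc_fc_cohort,
    gen_test_retest,
)

__all__ = [
    "centroid_oracle_check",
    "mdf_property_check",
    "projection_phantom_check",
    "warp_recovery_check",
    "metric_oracle_check",
    "avgrank_bound_check",
    "icc_recovery_check",
    "sc_fc_pipeline_check",
    "bag_correction_check",
    "lifespan_recovery_check",
    "sex_interval_fwer_check",
    "pipeline_determinism_check",
]


def _random_streamline(rng, n_points=12, scale=10.0):
    start = rng.normal(0, scale, 3)
    steps = rng.normal(0, 1.0, (n_points - 1, 3))
    pts = start + np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    return ResampledStreamline(points=pts)


def centroid_oracle_check(seed: int = 0, n_trials: int = 100) -> dict:
    """Fraction of random clusters where the centroid matches the
    exhaustive argmin-of-median-MDF oracle (expected: 1.0)."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        size = int(rng.integers(2, 13))
        members = {i: _random_streamline(rng) for i in range(size)}
        got = select_centroid(Cluster(member_ids=list(members)), members)
        best, best_med = None, np.inf
        for i, s in members.items():
            med = np.median(
                [mdf_distance(s, o) for j, o in members.items() if j != i]
            )
            if med < best_med:
                best, best_med = i, med
        agree += int(got is members[best])
    return {"value": agree / n_trials, "n": n_trials}


def mdf_property_check(seed: int = 0, n_pairs: int = 1000) -> dict:
    """Largest violation of MDF symmetry / flip-invariance (expected: 0)."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_pairs):
        a = _random_streamline(rng)
        b = _random_streamline(rng)
        d = mdf_distance(a, b)
        worst = max(worst, abs(d - mdf_distance(b, a)))
        flipped = ResampledStreamline(points=b.points[::-1])
        worst = max(worst, abs(d - mdf_distance(a, flipped)))
    return {"value": worst, "n": n_pairs}


def projection_phantom_check(step: float = 0.1) -> dict:
    """Max |projected - true peak| on the Gaussian-ridge phantom."""
    t = np.linspace(10, 50, 30)
    ridge = np.column_stack([t, np.full_like(t, 22.0), np.full_like(t, 30.0)])
    vol, truth = gen_ridge_volume(ridge, peak_value=0.8, sigma_mm=6.0, shape=(64, 64, 64))
    centroid = ResampledStreamline(
        points=np.column_stack(
            [np.linspace(15, 45, 20), np.full(20, 20.0), np.full(20, 30.0)]
        )
    )
    prof = project_scalar(vol, centroid, radius=4.0, step=step)
    err = float(np.max(np.abs(prof.values[prof.mask] - 0.8)))
    return {"value": err, "n": int(prof.mask.sum())}


def _validation_mother(t):
    t = np.asarray(t, dtype=float)
    return (
        np.exp(-((t - 0.35) ** 2) / (2 * 0.05**2))
        + 0.8 * np.exp(-((t - 0.7) ** 2) / (2 * 0.04**2))
    )


def warp_recovery_check(seed: int = 0, n_warps: int = 50) -> dict:
    """Worst-case warp-recovery RMSE over random smooth warps of a mother
    profile, and the cross-subject pointwise variance reduction after
    aligning all warped copies back to the mother."""
    rng = np.random.default_rng(seed)
    n = 101
    t = np.linspace(0, 1, n)
    template = ProfileFunction(values=_validation_mother(t))
    rmses = []
    aligned_vals = []
    warped_vals = []
    for _ in range(n_warps):
        g = t.copy()
        for k in (1, 2):
            g = g + rng.uniform(-0.07, 0.07) / k * np.sin(np.pi * k * t)
        g = np.clip(g, 0, 1)
        g[0], g[-1] = 0.0, 1.0
        f = ProfileFunction(values=_validation_mother(g))
        ghat, fa = align_pair(f, template, lam=1e-3)
        gam_inv = np.interp(t, g, t)
        rmses.append(float(np.sqrt(np.mean((ghat.gamma - gam_inv) ** 2))))
        warped_vals.append(f.values)
        aligned_vals.append(fa.values)
    var_before = np.stack(warped_vals).var(axis=0).mean()
    var_after = np.stack(aligned_vals).var(axis=0).mean()
    return {
        "max_rmse": max(rmses),
        "mean_rmse": float(np.mean(rmses)),
        "variance_reduction": float(1.0 - var_after / var_before),
        "n": n_warps,
    }


def metric_oracle_check(seed: int = 0, n_instances: int = 200) -> dict:
    """Largest |implementation - brute force| over random avgcorr/avgrank
    instances (expected: 0 to numerical precision)."""
    rng = np.random.default_rng(seed)
    worst_corr, worst_rank = 0.0, 0.0
    for _ in range(n_instances):
        n, e = int(rng.integers(2, 11)), int(rng.integers(3, 21))
        obs = rng.normal(0, 1, (n, e))
        pred = rng.normal(0, 1, (n, e))
        mu = rng.normal(0, 1, e)
        p = PredictionSet(observed=obs, predicted=pred, mu_tr=mu)
        ref_corr = np.mean(
            [np.corrcoef(obs[s] - mu, pred[s] - mu)[0, 1] for s in range(n)]
        )
        total = 0.0
        for s in range(n):
            self_r = np.corrcoef(obs[s], pred[s])[0, 1]
            total += sum(
                np.corrcoef(obs[s], pred[a])[0, 1] < self_r
                for a in range(n) if a != s
            ) / n
        ref_rank = total / n
        worst_corr = max(worst_corr, abs(avgcorr(p) - ref_corr))
        worst_rank = max(worst_rank, abs(avgrank(p) - ref_rank))
    return {"avgcorr_dev": worst_corr, "avgrank_dev": worst_rank, "n": n_instances}


def avgrank_bound_check(seed: int = 0, n_instances: int = 100) -> dict:
    """avgrank never exceeds (n-1)/n and attains it under perfect
    identification."""
    rng = np.random.default_rng(seed)
    max_excess = -np.inf
    for _ in range(n_instances):
        n = int(rng.integers(2, 9))
        obs = rng.normal(0, 1, (n, 12))
        pred = rng.normal(0, 1, (n, 12))
        p = PredictionSet(observed=obs, predicted=pred, mu_tr=np.zeros(12))
        max_excess = max(max_excess, avgrank(p) - (n - 1) / n)
    # perfect identification at n=4: orthogonal-ish observed rows
    n = 4
    obs = np.eye(n, 8) + 0.01 * rng.normal(0, 1, (n, 8))
    perfect = avgrank(
        PredictionSet(observed=obs, predicted=obs.copy(), mu_tr=np.zeros(8))
    )
    return {
        "max_excess_over_bound": float(max_excess),
        "perfect_identification_value": float(perfect),
        "n": n_instances,
    }


def icc_recovery_check(seed: int = 0, n_reps: int = 100, icc_true: float = 0.8,
                       n_subjects: int = 500) -> dict:
    """ICC estimation error over seeded replicates: the absolute error of
    the mean estimate (recovery), the 95th-percentile per-replicate error
    and the worst case."""
    ests = []
    for rep in range(n_reps):
        tab, _ = gen_test_retest(
            n_subjects=n_subjects, icc_true=icc_true, seed=seed, stream=rep
        )
        ests.append(icc(tab))
    errs = np.abs(np.asarray(ests) - icc_true)
    return {
        "value": float(abs(np.mean(ests) - icc_true)),
        "p95_abs_error": float(np.quantile(errs, 0.95)),
        "max_abs_error": float(np.max(errs)),
        "n": n_reps,
    }


def sc_fc_pipeline_check(seed: int = 0, n_reps: int = 20) -> dict:
    """Held-out identification and contribution ranking on structurally
    driven FC cohorts (R^2 = 0.3, n = 500)."""
    from sklearn.linear_model import Ridge

    ranks, wins = [], 0
    for rep in range(n_reps):
        fa, fc, truth = gen_sc_fc_cohort(
            n_subjects=500, n_pathways=10, n_edges=40, coupling_r2=0.3,
            dominant_pathway=2, seed=seed, stream=rep,
        )
        tr, te = slice(0, 250), slice(250, 500)
        model = Ridge(alpha=1.0).fit(fa[tr], fc[tr])
        pred = model.predict(fa[te])
        p = PredictionSet(observed=fc[te], predicted=pred, mu_tr=fc[tr].mean(0))
        ranks.append(avgrank(p))
        contribs = [sc_fc_contribution(fa[te][:, j], pred) for j in range(10)]
        wins += int(np.argmax(contribs) == 2)
    return {
        "min_avgrank": float(np.min(ranks)),
        "mean_avgrank": float(np.mean(ranks)),
        "dominant_first_rate": wins / n_reps,
        "n": n_reps,
    }


def bag_correction_check(seed: int = 0, n: int = 2000) -> dict:
    """Residual |corr(corrected BAG, age)| on linear-bias cohorts, plus a
    leakage probe: shifting one fold's predictions must shift that fold's
    corrected values one-to-one (the trend comes from the other fold)."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(45, 80, n)
    pred = 0.6 * ages + 20 + rng.normal(0, 2.0, n)
    records = [
        BAGRecord(i, float(a), float(p)) for i, (a, p) in enumerate(zip(ages, pred))
    ]
    out = bag_bias_correct(records, seed=seed)
    cbag = np.array([r.corrected_bag for r in out])
    r = abs(float(np.corrcoef(cbag, ages)[0, 1]))
    fold_of = {rec.subject_id: rec.fold for rec in out}
    shifted = [
        BAGRecord(rec.subject_id, rec.age,
                  rec.predicted_age + (5.0 if fold_of[rec.subject_id] == 1 else 0.0))
        for rec in records
    ]
    out2 = bag_bias_correct(shifted, seed=seed)
    leak = max(
        abs((r2.corrected_bag - r1.corrected_bag) - 5.0)
        for r1, r2 in zip(out, out2) if r1.fold == 1
    )
    return {"abs_corr_with_age": r, "leakage_deviation": float(leak), "n": n}


def lifespan_recovery_check(seed: int = 0, n_reps: int = 100, n: int = 3000) -> dict:
    """Fraction of replicates recovering both sex-specific peak ages
    (truth 25 male / 28 female) within +/- 2 years."""
    hits = 0
    errs = []
    for rep in range(n_reps):
        samples, truth = gen_lifespan_cohort(n=n, seed=seed, stream=rep)
        fit = fit_trajectory(samples)
        pm, _ = peak_age(fit, 1)
        pf, _ = peak_age(fit, 0)
        em = abs(pm - truth.params["peak_male"])
        ef = abs(pf - truth.params["peak_female"])
        errs.append(max(em, ef))
        hits += int(em <= 2.0 and ef <= 2.0)
    return {
        "recovery_rate": hits / n_reps,
        "max_error_years": float(np.max(errs)),
        "n": n_reps,
    }


def sex_interval_fwer_check(seed: int = 0, n_sims: int = 500, n: int = 300) -> dict:
    """Family-wise error of the simultaneous sex-difference interval
    procedure under a no-sex-effect null."""
    rng = np.random.default_rng(seed)
    false_pos = 0
    for sim in range(n_sims):
        ages = rng.uniform(3, 90, n)
        sex = rng.integers(0, 2, n)
        y = 0.4 + 0.002 * ages - 2e-5 * ages**2 + rng.normal(0, 0.05, n)
        samples = [
            LifespanSample(i, float(ages[i]), int(sex[i]), "s0", float(y[i]))
            for i in range(n)
        ]
        fit = fit_trajectory(samples)
        intervals = sex_difference_intervals(fit, n_tests=1, n_boot=1000, seed=sim)
        false_pos += int(bool(intervals))
    return {"value": false_pos / n_sims, "n": n_sims}


def pipeline_determinism_check(seed: int = 0, workdir=None,
                               n_subjects: int = 30, n_pathways: int = 40) -> dict:
    """Run the full pipeline twice with the same seed and compare metric
    outputs byte-for-byte (1.0 = identical)."""
    import tempfile
    from pathlib import Path

    from . import pipeline
    from .io import PipelineConfig

    outputs = ["metrics.csv", "trajectory_curves.csv", "network_sc_matrix.csv",
               "atlas_pathways.csv"]
    blobs = []
    base = Path(workdir) if workdir else Path(tempfile.mkdtemp(prefix="tractometry_"))
    for run in (0, 1):
        wd = base / f"run{run}"
        cfg = PipelineConfig(seed=seed)
        pipeline.run_all(wd, cfg, n_subjects=n_subjects, n_pathways=n_pathways)
        blobs.append({name: (wd / name).read_bytes() for name in outputs})
    identical = all(blobs[0][name] == blobs[1][name] for name in outputs)
    return {"value": float(identical), "n": n_subjects}
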
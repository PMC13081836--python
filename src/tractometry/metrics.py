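"""Evaluation statistics for structure-function coupling and brain aging.

avgcorr and avgrank summarize how well predicted functional-connectivity
(FC) edge vectors match the observed ones across a cohort:

    avgcorr = (1/n) sum_s corr(X_s - mu_tr, Xhat_s - mu_tr)
    avgrank = (1/n) sum_s (1/n) sum_{a != s} [ corr(X_s, Xhat_a) < corr(X_s, Xhat_s) ]

where mu_tr is the training-set mean edge vector.  Note the inner avgrank
sum is normalized by n (not n-1), so perfect identification yields
(n-1)/n; a ``normalization`` switch provides the n-1 variant.

The brain-age gap (BAG) is predicted minus chronological age; because raw
BAG retains a residual age trend, a cross-fitted linear age-bias
correction regresses BAG on age in the opposite half-split and subtracts
the fitted effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionSet",
    "BAGRecord",
    "avgcorr",
    "avgrank",
    "sc_fc_contribution",
    "network_sc_matrix",
    "signed_decomposition",
    "bag_bias_correct",
    "trait_association_scan",
]


@dataclass
class PredictionSet:
    observed: np.ndarray  # subjects x edges
    predicted: np.ndarray
    mu_tr: np.ndarray  # training-mean edge vector

    def __post_init__(self):
        self.observed = np.asarray(self.observed, dtype=float)
        self.predicted = np.asarray(self.predicted, dtype=float)
        self.mu_tr = np.asarray(self.mu_tr, dtype=float)
        if self.observed.shape != self.predicted.shape:
            raise ValueError("observed and predicted shapes differ")
        if self.mu_tr.shape != (self.observed.shape[1],):
            raise ValueError("mu_tr length must equal edge count")


@dataclass
class BAGRecord:
    subject_id: object
    age: float
    predicted_age: float
    raw_bag: float = None  # type: ignore[assignment]
    corrected_bag: float | None = None
    fold: int | None = None

    def __post_init__(self):
        if self.raw_bag is None:
            self.raw_bag = self.predicted_age - self.age
        elif abs(self.raw_bag - (self.predicted_age - self.age)) > 1e-9:
            raise ValueError("raw BAG must equal predicted minus chronological age")


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def avgcorr(p: PredictionSet) -> float:
    """Mean over subjects of the demeaned observed/predicted correlation.

    Subjects whose demeaned vector is constant (undefined correlation) are
    excluded with a log entry.
    """
    obs = p.observed - p.mu_tr
    pred = p.predicted - p.mu_tr
    vals = []
    for s in range(obs.shape[0]):
        r = _corr(obs[s], pred[s])
        if np.isnan(r):
            logger.warning("avgcorr: subject %d excluded (constant vector)", s)
            continue
        vals.append(r)
    if not vals:
        raise ValueError("no subject with a defined correlation")
    return float(np.mean(vals))


def avgrank(p: PredictionSet, normalization: str = "n") -> float:
    """Identification-rank statistic of predicted vs observed FC.

    For each subject s, the fraction of other subjects a whose predicted
    vector correlates strictly less with X_s than the subject's own
    prediction does; averaged over subjects.  ``normalization="n"`` (the
    printed form) divides the inner count by n_subj, bounding the result
    by (n-1)/n; ``"n-1"`` divides by n_subj - 1.
    """
    obs, pred = p.observed, p.predicted
    n = obs.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    # correlation matrix C[s, a] = corr(X_s, Xhat_a)
    C = np.empty((n, n))
    for s in range(n):
        for a in range(n):
            C[s, a] = _corr(obs[s], pred[a])
    valid = ~np.isnan(np.diag(C))
    if not valid.all():
        logger.warning("avgrank: %d subjects excluded (degenerate vectors)",
                       int((~valid).sum()))
    denom = {"n": n, "n-1": n - 1}[normalization]
    ranks = []
    for s in range(n):
        if not valid[s]:
            continue
        others = [a for a in range(n) if a != s and not np.isnan(C[s, a])]
        count = sum(C[s, a] < C[s, s] for a in others)
        ranks.append(count / denom)
    if not ranks:
        raise ValueError("no subject with a defined self-correlation")
    return float(np.mean(ranks))


def sc_fc_contribution(pathway_fa: np.ndarray, predicted_fc: np.ndarray) -> float:
    """Contribution of one pathway to a network pair's predicted FC.

    The per-edge contribution is the cross-subject Pearson correlation
    between pathway-averaged FA and the predicted FC of that edge; the
    network-pair contribution is the maximum over its edges (the best
    match, since a pathway is expected to drive only some edges).
    Zero-variance columns are skipped.
    """
    fa = np.asarray(pathway_fa, dtype=float)
    fc = np.asarray(predicted_fc, dtype=float)
    if fc.ndim == 1:
        fc = fc[:, None]
    if len(fa) < 3:
        raise ValueError("need at least 3 subjects")
    best = -np.inf
    for j in range(fc.shape[1]):
        r = _corr(fa, fc[:, j])
        if not np.isnan(r):
            best = max(best, r)
    if best == -np.inf:
        raise ValueError("all FC columns degenerate")
    return float(best)


def network_sc_matrix(
    fiber_means: dict, atlas, networks: list[str]
) -> pd.DataFrame:
    """FA-weighted structural connectivity among functional networks.

    Entry (A, B) is the mean over atlas pathways labeled with network pair
    {A, B} of the pathway-mean FA (``fiber_means`` maps pathway index or
    id -> cohort-mean FA).  Network pairs with no pathway get 0, denoting
    absence of a pathway in the atlas.
    """
    nets = list(networks)
    acc: dict[tuple, list[float]] = {}
    for i, entry in enumerate(atlas.entries):
        key = i if i in fiber_means else getattr(entry.centroid, "source_id", i)
        if key not in fiber_means:
            continue
        a, b = entry.network_pair
        acc.setdefault((a, b), []).append(float(fiber_means[key]))
    mat = np.zeros((len(nets), len(nets)))
    for (a, b), vals in acc.items():
        ia, ib = nets.index(a), nets.index(b)
        m = float(np.mean(vals))
        mat[ia, ib] = m
        mat[ib, ia] = m
    return pd.DataFrame(mat, index=nets, columns=nets)


def signed_decomposition(coefficients, features):
    """Split the linear predictor by coefficient sign.

    pos = X (w * [w > 0]); neg = X (w * [w < 0]); pos + neg equals the
    full linear predictor (minus any intercept) exactly.
    """
    w = np.asarray(coefficients, dtype=float)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    pos = X @ np.where(w > 0, w, 0.0)
    neg = X @ np.where(w < 0, w, 0.0)
    return pos, neg


def bag_bias_correct(records: list[BAGRecord], seed: int = 0) -> list[BAGRecord]:
    """Cross-fitted linear age-bias correction of raw brain-age gaps.

    Subjects are randomly split into two halves (seeded, fold recorded);
    within each half, the age trend removed is the one fitted by
    regressing raw BAG on chronological age in the *other* half, so no
    record's own half influences its correction.
    """
    if len(records) < 20:
        raise ValueError("need at least 20 records for a stable correction")
    ages = np.array([r.age for r in records], dtype=float)
    raw = np.array([r.raw_bag for r in records], dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(records))
    fold = np.empty(len(records), dtype=int)
    fold[order[: len(records) // 2]] = 0
    fold[order[len(records) // 2:]] = 1
    coefs = {}
    for f in (0, 1):
        a = ages[fold == f]
        if np.ptp(a) == 0:
            raise ValueError(f"constant age in fold {f}")
        b = raw[fold == f]
        slope, intercept = np.polyfit(a, b, 1)
        coefs[f] = (slope, intercept)
    out = []
    for i, r in enumerate(records):
        slope, intercept = coefs[1 - fold[i]]
        corrected = r.raw_bag - (slope * r.age + intercept)
        out.append(
            BAGRecord(
                subject_id=r.subject_id,
                age=r.age,
                predicted_age=r.predicted_age,
                raw_bag=r.raw_bag,
                corrected_bag=float(corrected),
                fold=int(fold[i]),
            )
        )
    return out


def trait_association_scan(
    corrected_bag: np.ndarray,
    traits: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    n_traits: int | None = None,
) -> pd.DataFrame:
    """Per-trait linear association with corrected BAG, Bonferroni flagged.

    Each trait is z-scored and entered one at a time as the predictor of a
    linear model for z-scored corrected BAG with the covariate columns as
    adjustments.  A covariate with the same name as the trait of interest
    is dropped from the adjustment set for that trait.  Collinear designs
    skip the trait with a diagnostic.
    """
    import statsmodels.api as sm

    y_raw = np.asarray(corrected_bag, dtype=float)
    n_traits = n_traits if n_traits is not None else traits.shape[1]
    rows = []
    for trait in traits.columns:
        x = traits[trait].to_numpy(dtype=float)
        cov = covariates.drop(columns=[trait], errors="ignore") if covariates is not None else None
        keep = np.isfinite(x) & np.isfinite(y_raw)
        if cov is not None:
            keep &= np.all(np.isfinite(cov.to_numpy(dtype=float)), axis=1)
        xs, ys = x[keep], y_raw[keep]
        if xs.std() == 0 or ys.std() == 0:
            rows.append({"trait": trait, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "bonferroni_sig": False,
                         "note": "degenerate"})
            continue
        X = [(xs - xs.mean()) / xs.std()]
        if cov is not None:
            for c in cov.columns:
                X.append(cov[c].to_numpy(dtype=float)[keep])
        X = sm.add_constant(np.column_stack(X))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            rows.append({"trait": trait, "beta": np.nan, "se": np.nan,
                         "p": np.nan, "bonferroni_sig": False,
                         "note": "collinear covariates"})
            continue
        yz = (ys - ys.mean()) / ys.std()
        fit = sm.OLS(yz, X).fit()
        beta, se, pval = fit.params[1], fit.bse[1], fit.pvalues[1]
        rows.append({"trait": trait, "beta": float(beta), "se": float(se),
                     "p": float(pval),
                     "bonferroni_sig": bool(pval < alpha / n_traits),
                     "note": ""})
    return pd.DataFrame(rows)
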
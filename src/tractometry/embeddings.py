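"""Fiber-, voxel- and network-level subject feature matrices, plus the
principal-component codec used to predict functional connectivity.

Three granularities of structural features are built from aligned tract
profiles:

* fiber level — one feature per pathway, the pathway-mean scalar value;
* voxel level — per pathway, subject scores on the top principal
  components of the subject x profile-point matrix plus the pathway mean
  (default 3 PCs + mean = 4 features per pathway);
* network level — hierarchical PCs of the pooled constituent-fiber PC
  scores within each functional network pair, retained up to a cumulative
  explained-variance threshold.

All fitted transforms (means, standard deviations, loadings) are stored so
that the identical transform applies out of sample without leaking
statistics from the apply set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureEmbedding",
    "FCMatrixSet",
    "FCCodec",
    "fiber_level_features",
    "voxel_level_features",
    "network_level_features",
    "zscore_features",
    "mad_filter",
    "fc_pc_encode",
    "fc_pc_decode",
]


@dataclass
class FeatureEmbedding:
    level: str  # fiber | voxel | network
    subjects: list
    matrix: np.ndarray  # subjects x features
    feature_meta: list[dict]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.feature_meta):
            raise ValueError("feature metadata length must equal feature count")


@dataclass
class FCMatrixSet:
    """Subject x edge functional-connectivity values with an edge map."""

    subjects: list
    edges: np.ndarray  # subjects x n_edges
    edge_meta: list[dict]  # per edge: roi_a, roi_b, network_pair

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.shape[1] != len(self.edge_meta):
            raise ValueError("edge metadata length must equal edge count")


def _fix_sign(components: np.ndarray) -> np.ndarray:
    """Force the largest-|loading| entry of each component positive."""
    out = components.copy()
    for i in range(out.shape[0]):
        j = int(np.argmax(np.abs(out[i])))
        if out[i, j] < 0:
            out[i] = -out[i]
    return out


def _profile_matrix(subj_profiles: dict, subjects: list) -> np.ndarray | None:
    """Subjects x grid matrix over complete-case grid columns; None if empty."""
    mats, masks = [], []
    for s in subjects:
        p = subj_profiles[s]
        mats.append(np.asarray(p.values, dtype=float))
        masks.append(np.asarray(getattr(p, "mask", np.isfinite(p.values)), dtype=bool))
    mat = np.stack(mats)
    keep = np.all(np.stack(masks), axis=0) & np.all(np.isfinite(mat), axis=0)
    if not keep.any():
        return None
    return mat[:, keep]


def fiber_level_features(aligned_cohort: dict) -> FeatureEmbedding:
    """One feature per pathway: the mean of unmasked profile values."""
    pathways = sorted(aligned_cohort, key=str)
    subjects = sorted(
        {s for pid in pathways for s in aligned_cohort[pid]}, key=str
    )
    cols, meta = [], []
    for pid in pathways:
        sp = aligned_cohort[pid]
        if set(sp) != set(subjects):
            raise ValueError(f"pathway {pid!r} missing for some subjects")
        mat = _profile_matrix(sp, subjects)
        if mat is None:
            logger.warning("pathway %r dropped: all grid points masked", pid)
            continue
        cols.append(mat.mean(axis=1))
        meta.append({"pathway_id": pid, "feature": "mean"})
    return FeatureEmbedding(
        level="fiber",
        subjects=subjects,
        matrix=np.column_stack(cols) if cols else np.empty((len(subjects), 0)),
        feature_meta=meta,
    )


def voxel_level_features(aligned_cohort: dict, n_pcs: int = 3) -> FeatureEmbedding:
    """Per pathway: top-``n_pcs`` PC scores of the along-tract matrix + mean.

    PCA is fit on the subject x profile-point matrix of each pathway
    (complete-case over grid points).  Component signs follow the
    largest-|loading|-positive convention so scores are reproducible across
    platforms.  Rank-deficient pathways retain the available components.
    """
    pathways = sorted(aligned_cohort, key=str)
    subjects = sorted({s for pid in pathways for s in aligned_cohort[pid]}, key=str)
    if len(subjects) < 4:
        raise ValueError("voxel-level features need at least 4 subjects")
    cols, meta = [], []
    params = {}
    for pid in pathways:
        mat = _profile_matrix(aligned_cohort[pid], subjects)
        if mat is None:
            logger.warning("pathway %r dropped: all grid points masked", pid)
            continue
        k = min(n_pcs, len(subjects) - 1, mat.shape[1])
        pca = PCA(n_components=k)
        scores = pca.fit_transform(mat)
        comps = _fix_sign(pca.components_)
        scores = (mat - pca.mean_) @ comps.T
        if k < n_pcs:
            logger.warning("pathway %r: rank %d < %d PCs retained", pid, k, n_pcs)
        for c in range(k):
            cols.append(scores[:, c])
            meta.append({"pathway_id": pid, "feature": f"pc{c + 1}"})
        cols.append(mat.mean(axis=1))
        meta.append({"pathway_id": pid, "feature": "mean"})
        params[pid] = {
            "mean": pca.mean_,
            "components": comps,
            "explained_variance": pca.explained_variance_,
        }
    return FeatureEmbedding(
        level="voxel",
        subjects=subjects,
        matrix=np.column_stack(cols) if cols else np.empty((len(subjects), 0)),
        feature_meta=meta,
        params=params,
    )


def n_components_for_threshold(explained_variance: np.ndarray, threshold: float) -> int:
    """Smallest m whose cumulative explained-variance ratio >= threshold."""
    ev = np.asarray(explained_variance, dtype=float)
    ratio = np.cumsum(ev) / ev.sum()
    return int(np.searchsorted(ratio, threshold - 1e-12) + 1)


def network_level_features(
    voxel_embedding: FeatureEmbedding,
    network_map: dict,
    contribution_threshold: float = 0.70,
) -> FeatureEmbedding:
    """Hierarchical PCs pooled over constituent fibers per network pair.

    ``network_map`` maps pathway_id -> network pair.  For each network
    pair, the PC-score columns (not the means) of its constituent pathways
    are pooled and re-decomposed; the smallest component count reaching the
    cumulative explained-variance ``contribution_threshold`` is retained.
    Network pairs with no pathways are omitted.
    """
    if not 0.0 < contribution_threshold <= 1.0:
        raise ValueError("contribution threshold must be in (0, 1]")
    subjects = voxel_embedding.subjects
    by_pair: dict[tuple, list[int]] = {}
    for j, m in enumerate(voxel_embedding.feature_meta):
        if m["feature"] == "mean":
            continue
        pair = network_map.get(m["pathway_id"])
        if pair is None:
            continue
        by_pair.setdefault(tuple(pair), []).append(j)
    cols, meta = [], []
    params = {}
    for pair in sorted(by_pair):
        block = voxel_embedding.matrix[:, by_pair[pair]]
        k_max = min(block.shape[1], len(subjects) - 1)
        pca = PCA(n_components=k_max)
        pca.fit(block)
        m = n_components_for_threshold(pca.explained_variance_, contribution_threshold)
        comps = _fix_sign(pca.components_[:m])
        scores = (block - pca.mean_) @ comps.T
        for c in range(m):
            cols.append(scores[:, c])
            meta.append({"network_pair": pair, "feature": f"hpc{c + 1}"})
        params[pair] = {"mean": pca.mean_, "components": comps,
                        "explained_variance": pca.explained_variance_}
    return FeatureEmbedding(
        level="network",
        subjects=subjects,
        matrix=np.column_stack(cols) if cols else np.empty((len(subjects), 0)),
        feature_meta=meta,
        params=params,
    )


def zscore_features(
    e: FeatureEmbedding, fit_ids: list, apply_ids: list | None = None
) -> FeatureEmbedding:
    """Z-score features with statistics from the fit subjects only.

    Features with zero standard deviation on the fit set are dropped (with
    a log entry); the stored (mean, sd) parameters make the transform
    reusable out of sample.
    """
    if not fit_ids:
        raise ValueError("fit set must be nonempty")
    apply_ids = list(apply_ids) if apply_ids is not None else list(e.subjects)
    pos = {s: i for i, s in enumerate(e.subjects)}
    fit_rows = e.matrix[[pos[s] for s in fit_ids]]
    mean = fit_rows.mean(axis=0)
    sd = fit_rows.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d zero-variance features", int((~keep).sum()))
    apply_rows = e.matrix[[pos[s] for s in apply_ids]]
    z = (apply_rows[:, keep] - mean[keep]) / sd[keep]
    return FeatureEmbedding(
        level=e.level,
        subjects=apply_ids,
        matrix=z,
        feature_meta=[m for m, k in zip(e.feature_meta, keep) if k],
        params={"mean": mean[keep], "sd": sd[keep], "fit_ids": list(fit_ids)},
    )


def mad_filter(values, k: float = 5.0) -> np.ndarray:
    """Flag values beyond k median-absolute-deviations of the median.

    Returns a boolean mask, True = outlier.  When the MAD is zero the rule
    degenerates; the policy is to flag nothing and warn.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        logger.warning("MAD is zero; outlier rule degenerate, flagging nothing")
        return np.zeros(x.shape, dtype=bool)
    return np.abs(x - med) > k * mad


@dataclass
class FCCodec:
    """Fitted per-network-pair PC codec for FC edge vectors."""

    network_pair: tuple
    edge_indices: np.ndarray
    edge_mean: np.ndarray
    edge_sd: np.ndarray
    pc_mean: np.ndarray
    components: np.ndarray  # m x n_edges_in_pair


def fc_pc_encode(
    fc: FCMatrixSet,
    network_pair: tuple,
    n_components: int | None = None,
    threshold: float | None = None,
) -> tuple[np.ndarray, FCCodec]:
    """PCA-encode the FC edges of one network pair into subject scores.

    Edges are z-scored across subjects before decomposition (the codec
    stores the statistics for exact decoding).  Either an explicit
    component count or a cumulative-variance threshold selects the rank; a
    count exceeding the available rank is reduced with a warning.
    """
    idx = np.array(
        [j for j, m in enumerate(fc.edge_meta) if tuple(m["network_pair"]) == tuple(network_pair)]
    )
    if idx.size == 0:
        raise ValueError(f"no edges for network pair {network_pair}")
    block = fc.edges[:, idx]
    mean = block.mean(axis=0)
    sd = block.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (block - mean) / sd
    k_max = min(z.shape[0] - 1, z.shape[1]) or 1
    pca = PCA(n_components=k_max)
    pca.fit(z)
    if n_components is not None:
        if n_components > k_max:
            logger.warning("reducing components from %d to %d", n_components, k_max)
        m = min(n_components, k_max)
    elif threshold is not None:
        m = n_components_for_threshold(pca.explained_variance_, threshold)
    else:
        m = k_max
    comps = _fix_sign(pca.components_[:m])
    scores = (z - pca.mean_) @ comps.T
    codec = FCCodec(
        network_pair=tuple(network_pair),
        edge_indices=idx,
        edge_mean=mean,
        edge_sd=sd,
        pc_mean=pca.mean_,
        components=comps,
    )
    return scores, codec


def fc_pc_decode(scores: np.ndarray, codec: FCCodec) -> np.ndarray:
    """Reconstruct FC edge values from (predicted) PC scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[None, :]
    if scores.shape[1] != codec.components.shape[0]:
        raise ValueError(
            f"score dimension {scores.shape[1]} != codec rank {codec.components.shape[0]}"
        )
    z = scores @ codec.components + codec.pc_mean
    return z * codec.edge_sd + codec.edge_mean
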
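"""End-to-end orchestration of the tractometry pipeline on a cohort directory.

Each stage reads the outputs of the previous one from a working directory
and writes its own, so stages can run individually (the CLI exposes one
subcommand per stage) or chained via ``run_all``.  All randomness derives
from the seed in the saved config; rerunning a stage with the same config
and inputs reproduces its outputs byte-identically.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import __version__
from .atlas import (
    PathwayAtlas,
    assemble_atlas,
    filter_post_clustering,
    filter_pre_clustering,
    group_by_roi_pair,
    icc,
    snap_endpoints,
)
from .elastic import ProfileFunction, align_cohort
from .embeddings import (
    fiber_level_features,
    network_level_features,
    voxel_level_features,
)
from .io import (
    PipelineConfig,
    read_parcellation,
    read_surface,
    read_tractogram,
    write_tractogram,
    write_volume,
)
from .metrics import (
    BAGRecord,
    PredictionSet,
    avgcorr,
    avgrank,
    bag_bias_correct,
    network_sc_matrix,
    sc_fc_contribution,
    signed_decomposition,
)
from .lifespan import fit_trajectory, normalized_trajectory, peak_age, sex_difference_intervals
from .projection import ScalarVolume, project_scalar
from .streamlines import (
    Cluster,
    Streamline,
    Tractogram,
    cluster_streamlines,
    mean_curvature,
    resample_streamline,
    select_centroid,
    streamline_length,
)
from .synthetic import child_seed, gen_bundle, gen_lifespan_cohort

logger = logging.getLogger(__name__)

NETWORKS = [
    "VIS1", "VIS2", "SMN", "CON", "DAN", "LAN", "FPN",
    "AUD", "DMN", "PMM", "VMM", "ORA", "SUB",
]


def _write_log(workdir: Path, stage: str, cfg: PipelineConfig) -> None:
    entry = {"stage": stage, "config_hash": cfg.hash(), "seed": cfg.seed,
             "version": __version__}
    with open(workdir / "pipeline.log", "a") as fh:
        fh.write(json.dumps(entry, sort_keys=True) + "\n")


def _mother_profile(t: np.ndarray) -> np.ndarray:
    """Along-tract FA modulation shared by all synthetic pathways."""
    return (
        0.55
        + 0.25 * np.exp(-((t - 0.35) ** 2) / (2 * 0.08**2))
        + 0.18 * np.exp(-((t - 0.75) ** 2) / (2 * 0.06**2))
        - 0.15 * t
    )


def generate_cohort(
    workdir,
    cfg: PipelineConfig,
    n_subjects: int = 30,
    n_pathways: int = 40,
    n_fibers: int = 12,
    grid_shape: tuple = (48, 48, 48),
    voxel_mm: float = 2.0,
) -> None:
    """Generate the mini-cohort every downstream stage consumes.

    Writes a population tractogram (bundles around known centerlines
    connecting region pairs), a parcellation + labeled-surface pair, one
    FA volume per subject whose ridge amplitudes follow a warped
    along-tract mother profile, fiber-count test-retest tables, a
    phenotype table and the ground-truth JSON.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(child_seed(cfg.seed, "bundle", 1000))
    extent = voxel_mm * (np.array(grid_shape) - 1)

    # regions: two per network placed on a sphere-ish shell inside the grid
    n_regions = 2 * len(NETWORKS)
    centers = []
    golden = np.pi * (3 - np.sqrt(5))
    for i in range(n_regions):
        z = 1 - 2 * (i + 0.5) / n_regions
        r = np.sqrt(1 - z * z)
        th = golden * i
        centers.append([r * np.cos(th), r * np.sin(th), z])
    centers = extent / 2 + 0.38 * extent * np.array(centers)
    regions = [
        (i + 1, f"R{i + 1}", NETWORKS[i % len(NETWORKS)]) for i in range(n_regions)
    ]
    parc = pd.DataFrame(
        {"region_id": [r[0] for r in regions],
         "name": [r[1] for r in regions],
         "network": [r[2] for r in regions]}
    )
    parc.to_csv(workdir / "parcellation.tsv", sep="\t", index=False)

    # labeled surface: a small vertex cloud around each region center
    verts, labels = [], []
    for rid, _, _ in regions:
        pts = centers[rid - 1] + rng.normal(0, 2.0, size=(20, 3))
        verts.append(pts)
        labels.extend([rid] * 20)
    surf = pd.DataFrame(np.vstack(verts), columns=["x", "y", "z"])
    surf["region_id"] = labels
    surf.to_csv(workdir / "surface.tsv", sep="\t", index=False)

    # pathway centerlines: quadratic arcs between distinct region pairs
    pairs = []
    while len(pairs) < n_pathways:
        a, b = sorted(rng.choice(n_regions, size=2, replace=False) + 1)
        if (a, b) not in pairs:
            pairs.append((int(a), int(b)))
    centerlines = []
    for a, b in pairs:
        p0, p1 = centers[a - 1], centers[b - 1]
        mid = (p0 + p1) / 2
        bow = rng.normal(0, 1, 3)
        bow -= bow.dot(p1 - p0) / max(np.dot(p1 - p0, p1 - p0), 1e-9) * (p1 - p0)
        bow = bow / max(np.linalg.norm(bow), 1e-9) * 0.15 * np.linalg.norm(p1 - p0)
        tt = np.linspace(0, 1, 40)[:, None]
        arc = (1 - tt) * p0 + tt * p1 + 4 * tt * (1 - tt) * bow
        centerlines.append(arc)

    # population tractogram: one bundle per pathway
    all_streamlines = []
    for k, arc in enumerate(centerlines):
        tg, _ = gen_bundle(arc, n_fibers=n_fibers, spread_mm=1.5, seed=cfg.seed, stream=k)
        all_streamlines.extend(tg.streamlines)
    write_tractogram(
        Tractogram(streamlines=all_streamlines, space="synthetic"),
        workdir / "population.trk",
    )

    # per-subject FA volumes: ridge amplitude = subject warp of mother profile
    affine = np.diag([voxel_mm] * 3 + [1.0])
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in grid_shape), indexing="ij")
    world = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel()]) * voxel_mm
    dense_pts, dense_t, dense_path = [], [], []
    for k, arc in enumerate(centerlines):
        dense = resample_streamline(Streamline(points=arc, id=str(k)), 150).points
        dense_pts.append(dense)
        dense_t.append(np.linspace(0, 1, 150))
        dense_path.extend([k] * 150)
    tree = cKDTree(np.vstack(dense_pts))
    tvals = np.concatenate(dense_t)
    pathk = np.array(dense_path)
    d, idx = tree.query(world)
    sigma = 4.0
    envelope = np.exp(-(d**2) / (2 * sigma**2))

    sub_rng = np.random.default_rng(child_seed(cfg.seed, "bundle", 2000))
    t_grid = np.linspace(0, 1, 64)
    subject_meta = []
    for s in range(n_subjects):
        amp = 1.0 + sub_rng.normal(0, 0.05)
        shift = sub_rng.normal(0, 0.05)
        warped = np.clip(tvals + shift * np.sin(np.pi * tvals), 0, 1)
        prof_val = np.interp(warped, t_grid, _mother_profile(t_grid))
        data = (amp * envelope * prof_val[idx]).reshape(grid_shape)
        vol = ScalarVolume(data=data, affine=affine, space="synthetic")
        write_volume(vol, workdir / f"fa_sub{s:03d}.nii.gz")
        subject_meta.append({"subject": f"sub{s:03d}", "amp": amp, "shift": shift})

    # fiber-count test-retest tables per ROI pair (all reliable by design)
    tr_rng = np.random.default_rng(child_seed(cfg.seed, "test_retest", 1000))
    rows = []
    for a, b in pairs:
        base = tr_rng.uniform(50, 200)
        subj = tr_rng.normal(0, 20, n_subjects)
        for s in range(n_subjects):
            v1, v2 = base + subj[s] + tr_rng.normal(0, 5, 2)
            rows.append({"roi_a": a, "roi_b": b, "subject": f"sub{s:03d}",
                         "count_visit1": v1, "count_visit2": v2})
    pd.DataFrame(rows).to_csv(workdir / "fiber_counts_retest.csv", index=False)

    # phenotypes
    ph_rng = np.random.default_rng(child_seed(cfg.seed, "lifespan_cohort", 1000))
    pheno = pd.DataFrame(
        {
            "subject": [m["subject"] for m in subject_meta],
            "age": ph_rng.uniform(20, 80, n_subjects).round(2),
            "sex": ph_rng.integers(0, 2, n_subjects),
            "site": [f"site_{i % 2}" for i in range(n_subjects)],
        }
    )
    pheno.to_csv(workdir / "phenotypes.csv", index=False)

    truth = {
        "pairs": pairs,
        "centerlines": [c.tolist() for c in centerlines],
        "subjects": subject_meta,
        "sigma_mm": sigma,
        "networks": NETWORKS,
    }
    (workdir / "truth.json").write_text(json.dumps(truth, sort_keys=True))
    cfg.save(workdir / "config.json")
    _write_log(workdir, "generate", cfg)


def build_atlas_stage(workdir, cfg: PipelineConfig) -> PathwayAtlas:
    """Snap endpoints, QC-filter, cluster and assemble the pathway atlas."""
    workdir = Path(workdir)
    tract = read_tractogram(workdir / "population.trk")
    parc = read_parcellation(workdir / "parcellation.tsv")
    surf = read_surface(workdir / "surface.tsv")

    assignments = snap_endpoints(tract, surf)
    groups = group_by_roi_pair(assignments)

    retest = pd.read_csv(workdir / "fiber_counts_retest.csv")
    reliability = {}
    for (a, b), sub in retest.groupby(["roi_a", "roi_b"]):
        tab = sub[["count_visit1", "count_visit2"]].to_numpy()
        reliability[(int(a), int(b))] = icc(tab)
    for key in groups:
        reliability.setdefault(key, 0.0)  # pairs without retest data fail QC
    groups, removed = filter_pre_clustering(groups, reliability, icc_min=cfg.icc_min)

    by_id = {}
    resampled = {}
    for s in tract.streamlines:
        r = resample_streamline(s, cfg.resample_points)
        by_id[s.id] = r
        resampled[s.id] = r

    retained = []
    cluster_sizes = []
    for pair, member_ids in sorted(groups.items()):
        members = [resampled[i] for i in sorted(member_ids, key=str)]
        clusters = cluster_streamlines(members, threshold=cfg.cluster_threshold_mm)
        for c in clusters:
            cluster_sizes.append(((pair, tuple(c.member_ids)), len(c.member_ids)))
    centroid_rel = {key: 1.0 for key, _ in cluster_sizes}  # profile QC upstream
    kept, _ = filter_post_clustering(
        cluster_sizes, centroid_rel, min_size=cfg.min_cluster_size, icc_min=cfg.icc_min
    )
    for (pair, member_ids), size in kept:
        centroid = select_centroid(Cluster(member_ids=list(member_ids)), resampled)
        retained.append((centroid, pair, size))
    atlas = assemble_atlas(
        retained, parc,
        provenance={"config_hash": cfg.hash(), "n_pre_qc_removed": len(removed)},
    )
    atlas.save(workdir / "atlas")

    rows = []
    for i, e in enumerate(atlas.entries):
        rows.append({
            "pathway": i,
            "roi_a": e.roi_pair[0], "roi_b": e.roi_pair[1],
            "network_a": e.network_pair[0], "network_b": e.network_pair[1],
            "n_members": e.n_members,
            "length_mm": round(streamline_length(e.centroid), 4),
            "mean_curvature": round(mean_curvature(e.centroid), 6),
        })
    pd.DataFrame(rows).to_csv(workdir / "atlas_pathways.csv", index=False)
    _write_log(workdir, "build-atlas", cfg)
    return atlas


def project_stage(workdir, cfg: PipelineConfig, radius=None, step=None) -> pd.DataFrame:
    """Project every subject's FA volume onto every atlas centroid."""
    from .io import read_volume

    workdir = Path(workdir)
    atlas = PathwayAtlas.load(workdir / "atlas")
    pheno = pd.read_csv(workdir / "phenotypes.csv")
    radius = radius if radius is not None else cfg.search_radius_mm
    step = step if step is not None else cfg.search_step_mm
    rows = []
    for subject in pheno["subject"]:
        vol = read_volume(workdir / f"fa_{subject}.nii.gz", space="synthetic")
        for p, entry in enumerate(atlas.entries):
            prof = project_scalar(vol, entry.centroid, radius=radius, step=step,
                                  pathway_id=p)
            for i in range(len(prof)):
                rows.append({
                    "subject": subject, "pathway": p, "point_index": i,
                    "value": prof.values[i],
                    "x": prof.centers[i, 0], "y": prof.centers[i, 1],
                    "z": prof.centers[i, 2],
                    "masked": int(not prof.mask[i]),
                })
    df = pd.DataFrame(rows)
    df.to_csv(workdir / "profiles.csv", index=False, float_format="%.6f")
    _write_log(workdir, "project", cfg)
    return df


def align_stage(workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Elastically align the projected profiles per pathway across subjects."""
    workdir = Path(workdir)
    prof = pd.read_csv(workdir / "profiles.csv")
    lengths = pd.read_csv(workdir / "atlas_pathways.csv").set_index("pathway")[
        "length_mm"].to_dict()
    cohort = {}
    for (pathway, subject), sub in prof.groupby(["pathway", "subject"]):
        sub = sub.sort_values("point_index")
        vals = sub["value"].to_numpy()
        vals = np.where(np.isfinite(vals), vals, np.nanmean(vals))
        cohort.setdefault(pathway, {})[subject] = ProfileFunction(
            values=vals, subject_id=subject, pathway_id=pathway
        )
    aligned, warps, diag = align_cohort(
        cohort, lam=cfg.elastic_lambda, lengths=lengths, max_iter=8
    )
    rows = []
    for pathway in sorted(aligned):
        for subject in sorted(aligned[pathway]):
            f = aligned[pathway][subject]
            g = warps[pathway][subject].gamma
            for i, (v, gv) in enumerate(zip(f.values, g)):
                rows.append({"subject": subject, "pathway": pathway,
                             "point_index": i, "value": v, "gamma": gv})
    df = pd.DataFrame(rows)
    df.to_csv(workdir / "aligned_profiles.csv", index=False, float_format="%.6f")
    diag_out = {
        str(k): {kk: (vv.tolist() if isinstance(vv, np.ndarray) else vv)
                 for kk, vv in d.items()}
        for k, d in diag.items()
    }
    (workdir / "alignment_diagnostics.json").write_text(
        json.dumps(diag_out, sort_keys=True))
    _write_log(workdir, "align", cfg)
    return df


def _load_aligned_cohort(workdir) -> dict:
    df = pd.read_csv(Path(workdir) / "aligned_profiles.csv")
    cohort = {}
    for (pathway, subject), sub in df.groupby(["pathway", "subject"]):
        sub = sub.sort_values("point_index")
        cohort.setdefault(pathway, {})[subject] = ProfileFunction(
            values=sub["value"].to_numpy(), subject_id=subject, pathway_id=pathway
        )
    return cohort


def features_stage(workdir, cfg: PipelineConfig) -> dict:
    """Fiber-, voxel- and network-level feature matrices from aligned profiles."""
    workdir = Path(workdir)
    cohort = _load_aligned_cohort(workdir)
    fiber = fiber_level_features(cohort)
    voxel = voxel_level_features(cohort, n_pcs=cfg.n_voxel_pcs)
    meta = pd.read_csv(workdir / "atlas_pathways.csv")
    network_map = {
        int(r.pathway): (r.network_a, r.network_b) for r in meta.itertuples()
    }
    network = network_level_features(
        voxel, network_map, contribution_threshold=cfg.contribution_threshold
    )
    for emb, name in ((fiber, "fiber"), (voxel, "voxel"), (network, "network")):
        df = pd.DataFrame(emb.matrix, columns=[
            json.dumps(m, sort_keys=True, default=str) for m in emb.feature_meta
        ])
        df.insert(0, "subject", emb.subjects)
        df.to_csv(workdir / f"features_{name}.csv", index=False,
                  float_format="%.6g")
    _write_log(workdir, "features", cfg)
    return {"fiber": fiber, "voxel": voxel, "network": network}


def evaluate_stage(workdir, cfg: PipelineConfig) -> pd.DataFrame:
    """Coupling metrics, network SC matrix and BAG correction on the cohort.

    A synthetic FC table is derived from the fiber features with a seeded
    mixing matrix, the cohort is split in half, a ridge regressor predicts
    held-out FC, and avgcorr / avgrank / contribution / signed
    decomposition / BAG statistics are written to ``metrics.csv``.
    """
    from sklearn.linear_model import Ridge

    workdir = Path(workdir)
    fiber = pd.read_csv(workdir / "features_fiber.csv")
    subjects = fiber["subject"].tolist()
    X = fiber.drop(columns="subject").to_numpy()
    n, p = X.shape
    rng = np.random.default_rng(child_seed(cfg.seed, "sc_fc_cohort", 3000))
    n_edges = 3 * p
    W = rng.normal(0, 1, (p, n_edges)) * (rng.random((p, n_edges)) < 0.5)
    signal = (X - X.mean(0)) @ W
    sd = signal.std(0)
    sd[sd == 0] = 1.0
    fc = signal + rng.normal(0, 1, signal.shape) * sd * np.sqrt(0.3 / 0.7)

    half = n // 2
    tr, te = np.arange(half), np.arange(half, n)
    model = Ridge(alpha=1.0)
    model.fit(X[tr], fc[tr])
    pred = model.predict(X[te])
    pset = PredictionSet(observed=fc[te], predicted=pred, mu_tr=fc[tr].mean(0))
    m_avgcorr = avgcorr(pset)
    m_avgrank = avgrank(pset)

    contrib = [sc_fc_contribution(X[te][:, j], pred) for j in range(p)]
    # signed decomposition of the first edge's ridge coefficients
    pos, neg = signed_decomposition(model.coef_[0], X[te])
    full = X[te] @ model.coef_[0]
    conserve = float(np.max(np.abs(pos + neg - full)))

    meta = pd.read_csv(workdir / "atlas_pathways.csv")
    atlas = PathwayAtlas.load(workdir / "atlas")
    col_meta = [json.loads(c) for c in fiber.columns[1:]]
    fiber_means = {
        int(m["pathway_id"]): X[:, j].mean() for j, m in enumerate(col_meta)
    }
    sc = network_sc_matrix(fiber_means, atlas, NETWORKS)
    sc.to_csv(workdir / "network_sc_matrix.csv", float_format="%.6f")

    pheno = pd.read_csv(workdir / "phenotypes.csv")
    ages = pheno.set_index("subject").loc[subjects, "age"].to_numpy()
    beta = rng.normal(0, 0.5, p)
    pred_age = 0.6 * ages + 20 + (X - X.mean(0)) @ beta
    records = [BAGRecord(s, float(a), float(pa))
               for s, a, pa in zip(subjects, ages, pred_age)]
    corrected = bag_bias_correct(records, seed=cfg.seed)
    cbag = np.array([r.corrected_bag for r in corrected])
    r_bag_age = float(np.corrcoef(cbag, ages)[0, 1])

    rows = [
        {"metric": "avgcorr", "scope": "global", "value": m_avgcorr, "n": len(te)},
        {"metric": "avgrank", "scope": "global", "value": m_avgrank, "n": len(te)},
        {"metric": "max_contribution", "scope": "global",
         "value": float(np.max(contrib)), "n": len(te)},
        {"metric": "signed_decomposition_gap", "scope": "global",
         "value": conserve, "n": len(te)},
        {"metric": "corr_corrected_bag_age", "scope": "global",
         "value": r_bag_age, "n": n},
        {"metric": "mean_pathway_length_mm", "scope": "global",
         "value": float(meta["length_mm"].mean()), "n": len(meta)},
        {"metric": "length_curvature_corr", "scope": "global",
         "value": float(np.corrcoef(meta["length_mm"],
                                    meta["mean_curvature"])[0, 1]),
         "n": len(meta)},
    ]
    df = pd.DataFrame(rows)
    df.to_csv(workdir / "metrics.csv", index=False, float_format="%.8f")
    _write_log(workdir, "evaluate", cfg)
    return df


def trajectories_stage(workdir, cfg: PipelineConfig, n: int = 1500) -> pd.DataFrame:
    """Fit a lifespan trajectory on a generated cohort; write curve tables."""
    workdir = Path(workdir)
    samples, truth = gen_lifespan_cohort(n=n, seed=cfg.seed)
    fit = fit_trajectory(samples)
    pm, bm = peak_age(fit, 1)
    pf, bf = peak_age(fit, 0)
    intervals = sex_difference_intervals(
        fit, level=1 - cfg.alpha, n_tests=cfg.n_tests, seed=cfg.seed
    )
    grid, norm_m, rate_m = normalized_trajectory(fit, 1, reference_age=fit.grid[0])
    _, norm_f, rate_f = normalized_trajectory(fit, 0, reference_age=fit.grid[0])
    se = fit.delta_se()
    curves = pd.DataFrame({
        "age": fit.grid, "male": fit.curve(1), "female": fit.curve(0),
        "delta": fit.delta_hat, "delta_se": se,
        "norm_male": norm_m, "norm_female": norm_f,
        "rate_male": rate_m, "rate_female": rate_f,
    })
    curves.to_csv(workdir / "trajectory_curves.csv", index=False,
                  float_format="%.6f")
    summary = pd.DataFrame([
        {"quantity": "peak_age_male", "value": pm, "boundary": bm},
        {"quantity": "peak_age_female", "value": pf, "boundary": bf},
        {"quantity": "true_peak_male", "value": truth.params["peak_male"],
         "boundary": False},
        {"quantity": "true_peak_female", "value": truth.params["peak_female"],
         "boundary": False},
        {"quantity": "n_sex_difference_intervals", "value": len(intervals),
         "boundary": False},
    ])
    summary.to_csv(workdir / "trajectory_summary.csv", index=False)
    _write_log(workdir, "trajectories", cfg)
    return summary


def run_all(workdir, cfg: PipelineConfig, **generate_kwargs) -> None:
    """Generate a mini-cohort and run every stage in order."""
    generate_cohort(workdir, cfg, **generate_kwargs)
    build_atlas_stage(workdir, cfg)
    project_stage(workdir, cfg)
    align_stage(workdir, cfg)
    features_stage(workdir, cfg)
    evaluate_stage(workdir, cfg)
    trajectories_stage(workdir, cfg)
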
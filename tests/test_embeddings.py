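import numpy as np
import pytest

from tractometry.elastic import ProfileFunction
from tractometry.embeddings import (
    FCMatrixSet,
    FeatureEmbedding,
    fc_pc_decode,
    fc_pc_encode,
    fiber_level_features,
    mad_filter,
    n_components_for_threshold,
    network_level_features,
    voxel_level_features,
    zscore_features,
)


def make_cohort(rng, n_subjects=10, n_pathways=3, n_points=16, offsets=None):
    cohort = {}
    base = np.linspace(0.3, 0.6, n_points)
    for p in range(n_pathways):
        cohort[p] = {}
        for s in range(n_subjects):
            off = offsets[s] if offsets is not None else rng.normal(0, 0.05)
            noise = rng.normal(0, 0.01, n_points)
            cohort[p][f"s{s:02d}"] = ProfileFunction(
                values=base + off + noise, subject_id=f"s{s:02d}", pathway_id=p
            )
    return cohort


class TestFiberLevel:
    def test_constant_profile_mean(self):
        cohort = {0: {"a": ProfileFunction(values=np.full(10, 0.5))}}
        emb = fiber_level_features(cohort)
        assert emb.matrix[0, 0] == pytest.approx(0.5)

    def test_arithmetic_mean(self):
        vals = np.array([0.2, 0.4, 0.6] * 4)
        cohort = {0: {"a": ProfileFunction(values=vals)}}
        emb = fiber_level_features(cohort)
        assert emb.matrix[0, 0] == pytest.approx(0.4)

    def test_matches_brute_force_means(self, rng):
        cohort = make_cohort(rng)
        emb = fiber_level_features(cohort)
        for j, meta in enumerate(emb.feature_meta):
            p = meta["pathway_id"]
            for i, s in enumerate(emb.subjects):
                assert emb.matrix[i, j] == pytest.approx(
                    cohort[p][s].values.mean()
                )


class TestVoxelLevel:
    def test_offset_only_cohort_rank_one(self, rng):
        offsets = rng.normal(0, 0.1, 12)
        cohort = {}
        base = np.linspace(0.3, 0.6, 16)
        cohort[0] = {
            f"s{s:02d}": ProfileFunction(values=base + offsets[s])
            for s in range(12)
        }
        emb = voxel_level_features(cohort)
        pc1 = emb.matrix[:, 0]
        order = np.argsort([f"s{s:02d}" for s in range(12)])
        r = np.corrcoef(pc1, offsets[order])[0, 1]
        assert abs(r) == pytest.approx(1.0, abs=1e-8)
        # PC2/PC3 carry no variance on a rank-1 construction
        assert emb.matrix[:, 1].std() < 1e-9
        assert emb.matrix[:, 2].std() < 1e-9

    def test_identical_subjects_zero_scores(self):
        base = np.linspace(0.3, 0.6, 16)
        cohort = {0: {f"s{i}": ProfileFunction(values=base) for i in range(6)}}
        emb = voxel_level_features(cohort)
        assert np.allclose(emb.matrix[:, :3], 0.0, atol=1e-12)
        assert np.allclose(emb.matrix[:, 3], base.mean())

    def test_matches_svd_oracle(self, rng):
        cohort = make_cohort(rng, n_subjects=15, n_pathways=1)
        emb = voxel_level_features(cohort)
        mat = np.stack([cohort[0][s].values for s in emb.subjects])
        X = mat - mat.mean(axis=0)
        U, S, Vt = np.linalg.svd(X, full_matrices=False)
        for c in range(3):
            v = Vt[c]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            assert np.allclose(emb.matrix[:, c], X @ v, atol=1e-8)

    def test_variance_conservation_bound(self, rng):
        cohort = make_cohort(rng, n_subjects=12, n_pathways=2)
        emb = voxel_level_features(cohort)
        for p in range(2):
            mat = np.stack([cohort[p][s].values for s in emb.subjects])
            total = ((mat - mat.mean(0)) ** 2).sum() / (len(mat) - 1)
            cols = [j for j, m in enumerate(emb.feature_meta)
                    if m["pathway_id"] == p and m["feature"] != "mean"]
            retained = sum(emb.matrix[:, j].var(ddof=1) for j in cols)
            assert retained <= total + 1e-9

    def test_too_few_subjects_rejected(self):
        base = np.linspace(0, 1, 16)
        cohort = {0: {f"s{i}": ProfileFunction(values=base) for i in range(3)}}
        with pytest.raises(ValueError, match="4 subjects"):
            voxel_level_features(cohort)


class TestNetworkLevel:
    def test_threshold_component_count_known_spectrum(self, rng):
        # scores with variances 4, 3, 2, 1: cumulative 0.4, 0.7, 0.9, 1.0
        n = 2000
        Z = rng.standard_normal((n, 4))
        Z = (Z - Z.mean(0)) / Z.std(0)
        # orthogonalize so the sample spectrum is exactly as constructed
        Q, _ = np.linalg.qr(Z)
        Q *= np.sqrt(n)
        X = Q * np.sqrt(np.array([4.0, 3.0, 2.0, 1.0]))
        ev = np.var(X, axis=0, ddof=0)
        assert n_components_for_threshold(ev, 0.70) == 2
        assert n_components_for_threshold(ev, 0.95) == 4
        assert n_components_for_threshold(ev, 0.90) == 3

    def test_threshold_monotonicity(self, rng):
        ev = np.sort(rng.uniform(0.1, 5.0, 8))[::-1]
        assert n_components_for_threshold(ev, 0.95) >= n_components_for_threshold(ev, 0.70)

    def test_single_fiber_network_preserves_variance(self, rng):
        cohort = make_cohort(rng, n_subjects=12, n_pathways=1)
        voxel = voxel_level_features(cohort)
        net = network_level_features(voxel, {0: ("A", "B")}, contribution_threshold=1.0)
        pc_cols = [j for j, m in enumerate(voxel.feature_meta) if m["feature"] != "mean"]
        var_in = sum(voxel.matrix[:, j].var(ddof=1) for j in pc_cols)
        var_out = sum(net.matrix[:, j].var(ddof=1) for j in range(net.matrix.shape[1]))
        assert var_out == pytest.approx(var_in, rel=1e-8)

    def test_empty_network_pair_omitted(self, rng):
        cohort = make_cohort(rng, n_subjects=12, n_pathways=1)
        voxel = voxel_level_features(cohort)
        net = network_level_features(voxel, {0: ("A", "B")})
        pairs = {m["network_pair"] for m in net.feature_meta}
        assert pairs == {("A", "B")}


class TestZScore:
    def test_fit_equals_apply_standardizes(self, rng):
        emb = FeatureEmbedding(
            level="fiber", subjects=[f"s{i}" for i in range(20)],
            matrix=rng.normal(3, 2, (20, 5)),
            feature_meta=[{"f": i} for i in range(5)],
        )
        z = zscore_features(emb, emb.subjects)
        assert np.allclose(z.matrix.mean(0), 0, atol=1e-12)
        assert np.allclose(z.matrix.std(0), 1, atol=1e-12)

    def test_out_of_sample_no_leakage(self, rng):
        mat = rng.normal(0, 1, (30, 4))
        emb = FeatureEmbedding(
            level="fiber", subjects=[f"s{i}" for i in range(30)],
            matrix=mat, feature_meta=[{"f": i} for i in range(4)],
        )
        fit_ids = emb.subjects[:20]
        z1 = zscore_features(emb, fit_ids, emb.subjects[20:])
        # perturbing the apply set must not change the fitted parameters
        mat2 = mat.copy()
        mat2[25] += 100.0
        emb2 = FeatureEmbedding(
            level="fiber", subjects=emb.subjects, matrix=mat2,
            feature_meta=emb.feature_meta,
        )
        z2 = zscore_features(emb2, fit_ids, emb.subjects[20:])
        assert np.allclose(z1.params["mean"], z2.params["mean"])
        assert np.allclose(z1.params["sd"], z2.params["sd"])

    def test_subject_at_fit_mean_maps_to_zero(self, rng):
        mat = rng.normal(0, 1, (10, 3))
        mat[9] = mat[:9].mean(0)
        emb = FeatureEmbedding(
            level="fiber", subjects=[f"s{i}" for i in range(10)],
            matrix=mat, feature_meta=[{"f": i} for i in range(3)],
        )
        z = zscore_features(emb, emb.subjects[:9], [emb.subjects[9]])
        assert np.allclose(z.matrix, 0, atol=1e-12)

    def test_zero_variance_feature_dropped(self, rng):
        mat = rng.normal(0, 1, (10, 3))
        mat[:, 1] = 7.0
        emb = FeatureEmbedding(
            level="fiber", subjects=[f"s{i}" for i in range(10)],
            matrix=mat, feature_meta=[{"f": i} for i in range(3)],
        )
        z = zscore_features(emb, emb.subjects)
        assert z.matrix.shape[1] == 2


class TestMADFilter:
    def test_hand_computed_example(self):
        mask = mad_filter([1, 2, 3, 4, 100])
        # median 3, MAD 1: only 100 exceeds 5 MADs
        assert list(mask) == [False, False, False, False, True]

    def test_all_equal_flags_nothing(self):
        assert not mad_filter([5.0] * 10).any()

    def test_inliers_untouched(self, rng):
        x = rng.normal(0, 1, 100)
        x = np.clip(x, -3, 3)
        assert not mad_filter(x, k=5).any()

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            mad_filter([1.0, 2.0])


class TestFCCodec:
    def _fc(self, rng, n_subj=40, n_edges=12):
        edges = rng.normal(0, 1, (n_subj, n_edges))
        meta = [
            {"roi_a": j, "roi_b": j + 1, "network_pair": ("A", "B")}
            for j in range(n_edges)
        ]
        return FCMatrixSet(
            subjects=[f"s{i}" for i in range(n_subj)], edges=edges, edge_meta=meta
        )

    def test_full_rank_round_trip(self, rng):
        fc = self._fc(rng)
        scores, codec = fc_pc_encode(fc, ("A", "B"))
        back = fc_pc_decode(scores, codec)
        assert np.allclose(back, fc.edges, atol=1e-8)

    def test_rank_one_block_single_component(self, rng):
        n = 40
        u = rng.normal(0, 1, n)
        edges = np.outer(u, rng.normal(0, 1, 8))
        meta = [{"roi_a": j, "roi_b": j + 1, "network_pair": ("A", "B")} for j in range(8)]
        fc = FCMatrixSet(subjects=list(range(n)), edges=edges, edge_meta=meta)
        scores, codec = fc_pc_encode(fc, ("A", "B"), threshold=0.99)
        assert codec.components.shape[0] == 1

    def test_zero_scores_decode_to_training_means(self, rng):
        fc = self._fc(rng)
        scores, codec = fc_pc_encode(fc, ("A", "B"), n_components=3)
        back = fc_pc_decode(np.zeros((1, 3)), codec)
        assert np.allclose(back[0], fc.edges.mean(axis=0), atol=1e-8)

    def test_score_columns_uncorrelated(self, rng):
        fc = self._fc(rng)
        scores, _ = fc_pc_encode(fc, ("A", "B"), n_components=4)
        c = np.corrcoef(scores.T)
        off = c - np.diag(np.diag(c))
        assert np.max(np.abs(off)) < 1e-8

    def test_round_trip_error_decreases_with_rank(self, rng):
        fc = self._fc(rng)
        errs = []
        for m in (2, 5, 9, 12):
            scores, codec = fc_pc_encode(fc, ("A", "B"), n_components=m)
            back = fc_pc_decode(scores, codec)
            errs.append(np.abs(back - fc.edges).max())
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] < 1e-8

    def test_dimension_mismatch_raises(self, rng):
        fc = self._fc(rng)
        _, codec = fc_pc_encode(fc, ("A", "B"), n_components=3)
        with pytest.raises(ValueError, match="rank"):
            fc_pc_decode(np.zeros((1, 5)), codec)
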
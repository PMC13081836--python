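import numpy as np
import pytest

from tractometry.atlas import (
    LabeledSurface,
    Parcellation,
    assemble_atlas,
    filter_post_clustering,
    filter_pre_clustering,
    group_by_roi_pair,
    icc,
    merge_parcels,
    snap_endpoints,
)
from tractometry.streamlines import Streamline, Tractogram

from .conftest import make_line


@pytest.fixture
def toy_parcellation():
    regions = [
        (1, "A1", "DMN"), (2, "A2", "DMN"),
        (3, "B1", "FPN"), (4, "B2", "FPN"),
        (5, "C1", "VIS"), (6, "C2", "VIS"),
    ]
    adjacency = {frozenset((1, 2)), frozenset((3, 4)), frozenset((2, 3)),
                 frozenset((5, 6))}
    return Parcellation(regions=regions, adjacency=adjacency)


class TestSnapEndpoints:
    def test_nearest_vertex_label(self):
        surf = LabeledSurface(
            vertices=[(0, 0, 0), (1, 0, 0)], labels=[1, 2]
        )
        s = Streamline(points=[(0.4, 0, 0), (1.1, 0, 0)], id="f")
        t = Tractogram(streamlines=[s], space="t")
        [(sid, a, b)] = snap_endpoints(t, surf)
        assert (a, b) == (1, 2)

    def test_equidistant_tie_goes_to_lower_region_id(self):
        surf = LabeledSurface(
            vertices=[(0, 0, 0), (1, 0, 0)], labels=[7, 3]
        )
        s = Streamline(points=[(0.5, 0, 0), (0.5, 1e-4, 0)], id="f")
        t = Tractogram(streamlines=[s], space="t")
        [(_, a, b)] = snap_endpoints(t, surf)
        assert a == 3 and b == 3

    def test_pairs_stored_canonically(self):
        surf = LabeledSurface(vertices=[(0, 0, 0), (9, 0, 0)], labels=[5, 2])
        s = Streamline(points=[(0, 0, 0), (9, 0, 0)], id="f")
        t = Tractogram(streamlines=[s], space="t")
        [(_, a, b)] = snap_endpoints(t, surf)
        assert (a, b) == (2, 5)

    def test_matches_brute_force_scan(self, rng):
        verts = rng.uniform(0, 50, (500, 3))
        labels = rng.integers(1, 40, 500)
        surf = LabeledSurface(vertices=verts, labels=labels)
        streamlines = []
        for i in range(500):
            p, q = rng.uniform(0, 50, (2, 3))
            streamlines.append(Streamline(points=[p, q], id=str(i)))
        t = Tractogram(streamlines=streamlines, space="t")
        got = snap_endpoints(t, surf)
        for sid, a, b in got:
            s = streamlines[int(sid)]
            la = labels[np.argmin(np.linalg.norm(verts - s.points[0], axis=1))]
            lb = labels[np.argmin(np.linalg.norm(verts - s.points[-1], axis=1))]
            assert (a, b) == (min(la, lb), max(la, lb))

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError):
            LabeledSurface(vertices=np.empty((0, 3)), labels=np.empty(0))


class TestGrouping:
    def test_unordered_pairs_merge(self):
        groups = group_by_roi_pair([("f1", 1, 2), ("f2", 2, 1), ("f3", 3, 4)])
        assert {k: len(v) for k, v in groups.items()} == {(1, 2): 2, (3, 4): 1}

    def test_empty(self):
        assert group_by_roi_pair([]) == {}

    def test_partition_conserves_count(self, rng):
        assignments = [
            (i, int(rng.integers(1, 6)), int(rng.integers(1, 6)))
            for i in range(200)
        ]
        groups = group_by_roi_pair(assignments)
        assert sum(len(v) for v in groups.values()) == 200


class TestICC:
    def test_perfect_agreement(self):
        tab = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc(tab) == pytest.approx(1.0)

    def test_hand_computed_three_by_two(self):
        # ANOVA mean squares for [[1,1],[2,2],[3,3.5]] give ICC(2,1)=30/31
        assert icc(np.array([[1, 1], [2, 2], [3, 3.5]])) == pytest.approx(30 / 31)

    def test_pure_noise_near_zero(self, rng):
        tab = rng.normal(0, 1, (2000, 2))
        assert abs(icc(tab)) < 0.06

    def test_matches_anova_closed_form_random_tables(self, rng):
        for _ in range(100):
            n, k = int(rng.integers(3, 15)), int(rng.integers(2, 5))
            tab = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.5, (n, k))
            # independent closed-form oracle from explicit sums of squares
            grand = tab.mean()
            msr = k * ((tab.mean(1) - grand) ** 2).sum() / (n - 1)
            msc = n * ((tab.mean(0) - grand) ** 2).sum() / (k - 1)
            mse = (
                ((tab - grand) ** 2).sum()
                - (n - 1) * msr
                - (k - 1) * msc
            ) / ((n - 1) * (k - 1))
            want = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
            want = float(np.clip(want, -1.0, 1.0))  # reported range is [-1, 1]
            assert icc(tab) == pytest.approx(want, rel=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        for _ in range(10):
            n, k = int(rng.integers(4, 12)), int(rng.integers(2, 4))
            tab = rng.normal(0, 1, (n, 1)) + rng.normal(0, 0.5, (n, k))
            df = pd.DataFrame({
                "t": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "y": tab.ravel(),
            })
            res = pg.intraclass_corr(df, targets="t", raters="r", ratings="y")
            want = float(res.set_index("Type").loc["ICC(A,1)", "ICC"])
            assert icc(tab) == pytest.approx(want, abs=1e-10)

    def test_degenerate_constant_table_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(np.full((5, 2), 3.0))


def _retest_tables(rng, region_ids, icc_like=0.9, n=40):
    out = {}
    for rid in region_ids:
        subj = rng.normal(0, 3.0, n)
        noise = rng.normal(0, 1.0, (n, 2))
        out[rid] = 100 + subj[:, None] + noise
    return out


class TestMergeParcels:
    def test_qualifying_pair_merges(self, toy_parcellation, rng):
        profiles = {rid: rng.normal(0, 1, 30) for rid in range(1, 7)}
        profiles[2] = profiles[1] + rng.normal(0, 0.1, 30)  # corr >> 0.7
        retest = _retest_tables(rng, range(1, 7))
        # anti-correlated visit noise: the summed counts are noise-free, so
        # the merge strictly raises the mean fiber-count ICC
        subj = rng.normal(0, 3.0, 40)
        noise = rng.normal(0, 2.0, (40, 2))
        retest[1] = 100 + subj[:, None] + noise
        retest[2] = 100 + subj[:, None] - noise
        merged, log = merge_parcels(toy_parcellation, profiles, retest)
        merged_pairs = [e["pair"] for e in log if e["merged"]]
        assert (1, 2) in merged_pairs
        assert 2 not in merged.region_ids

    def test_low_correlation_pair_not_merged(self, toy_parcellation, rng):
        profiles = {rid: rng.normal(0, 1, 200) for rid in range(1, 7)}
        retest = _retest_tables(rng, range(1, 7))
        merged, log = merge_parcels(toy_parcellation, profiles, retest)
        for e in log:
            if e["profile_corr"] < 0.7:
                assert not e["merged"]

    def test_cross_network_pair_never_merged(self, toy_parcellation, rng):
        profiles = {rid: rng.normal(0, 1, 30) for rid in range(1, 7)}
        profiles[3] = profiles[2] * 1.0  # perfectly correlated but DMN vs FPN
        retest = _retest_tables(rng, range(1, 7))
        _, log = merge_parcels(toy_parcellation, profiles, retest)
        e23 = [e for e in log if e["pair"] == (2, 3)]
        assert e23 and not e23[0]["merged"]

    def test_mean_icc_never_decreases(self, toy_parcellation, rng):
        from tractometry.atlas import _mean_icc

        profiles = {rid: rng.normal(0, 1, 30) for rid in range(1, 7)}
        profiles[2] = profiles[1] + rng.normal(0, 0.05, 30)
        profiles[6] = profiles[5] + rng.normal(0, 0.05, 30)
        retest = _retest_tables(rng, range(1, 7))
        merged, log = merge_parcels(toy_parcellation, profiles, retest)
        for e in log:
            if e["merged"]:
                assert e["icc_after"] >= e["icc_before"]

    def test_missing_profile_raises(self, toy_parcellation, rng):
        retest = _retest_tables(rng, range(1, 7))
        with pytest.raises(KeyError):
            merge_parcels(toy_parcellation, {1: np.ones(5)}, retest)


class TestQCFilters:
    def test_strict_threshold_boundary(self):
        groups = {("a",): [1], ("b",): [2]}
        rel = {("a",): 0.39, ("b",): 0.40}
        kept, removed = filter_pre_clustering(groups, rel)
        assert list(kept) == [("b",)] and removed == [("a",)]

    def test_all_reliable_nothing_removed(self):
        groups = {i: [i] for i in range(5)}
        kept, removed = filter_pre_clustering(groups, {i: 1.0 for i in range(5)})
        assert len(kept) == 5 and removed == []

    def test_survivor_count_matches_scan(self, rng):
        groups = {i: [i] for i in range(100)}
        rel = {i: float(rng.uniform(0, 1)) for i in range(100)}
        kept, _ = filter_pre_clustering(groups, rel)
        assert len(kept) == sum(1 for v in rel.values() if v >= 0.4)

    def test_post_clustering_size_and_reliability(self, rng):
        clusters = [(i, int(rng.integers(1, 20))) for i in range(50)]
        rel = {i: float(rng.uniform(0, 1)) for i in range(50)}
        kept, removed = filter_post_clustering(clusters, rel, min_size=5)
        want = [(k, s) for k, s in clusters if s >= 5 and rel[k] >= 0.4]
        assert kept == want
        assert len(kept) + len(removed) == 50


class TestAssemble:
    def _centroid(self, i):
        return make_line(float(i))

    def test_network_pair_classification(self, toy_parcellation):
        atlas = assemble_atlas(
            [(self._centroid(0), (1, 2), 10), (self._centroid(1), (2, 3), 5)],
            toy_parcellation,
        )
        assert atlas.entries[0].network_pair == ("DMN", "DMN")
        assert atlas.entries[1].network_pair == ("DMN", "FPN")
        assert atlas.within_network_count() == 1
        assert atlas.between_network_count() == 1

    def test_unknown_roi_pair_raises(self, toy_parcellation):
        with pytest.raises(KeyError):
            assemble_atlas([(self._centroid(0), (1, 99), 3)], toy_parcellation)

    def test_round_trip_save_load(self, toy_parcellation, tmp_path):
        atlas = assemble_atlas(
            [(self._centroid(i), (1, 2), 5 + i) for i in range(3)],
            toy_parcellation,
            provenance={"config_hash": "abc"},
        )
        atlas.save(tmp_path / "atlas")
        loaded = atlas.load(tmp_path / "atlas")
        assert len(loaded) == 3
        for a, b in zip(atlas.entries, loaded.entries):
            assert a.roi_pair == b.roi_pair
            assert a.network_pair == b.network_pair
            assert a.n_members == b.n_members
            assert np.allclose(a.centroid.points, b.centroid.points, atol=1e-4)

    def test_relabeling_invariance(self, toy_parcellation):
        # renaming region ids (adding 100) preserves network-pair structure
        shifted = Parcellation(
            regions=[(rid + 100, n, net) for rid, n, net in toy_parcellation.regions],
            adjacency={frozenset(x + 100 for x in p) for p in toy_parcellation.adjacency},
        )
        a1 = assemble_atlas(
            [(self._centroid(0), (1, 3), 2)], toy_parcellation
        )
        a2 = assemble_atlas(
            [(self._centroid(0), (101, 103), 2)], shifted
        )
        assert a1.entries[0].network_pair == a2.entries[0].network_pair
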
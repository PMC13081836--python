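import numpy as np
import pandas as pd
import pytest

from tractometry.atlas import Parcellation, assemble_atlas
from tractometry.metrics import (
    BAGRecord,
    PredictionSet,
    avgcorr,
    avgrank,
    bag_bias_correct,
    network_sc_matrix,
    sc_fc_contribution,
    signed_decomposition,
    trait_association_scan,
)

from .conftest import make_line


def brute_avgcorr(obs, pred, mu):
    rs = []
    for s in range(obs.shape[0]):
        a, b = obs[s] - mu, pred[s] - mu
        rs.append(np.corrcoef(a, b)[0, 1])
    return np.mean(rs)


def brute_avgrank(obs, pred):
    n = obs.shape[0]
    total = 0.0
    for s in range(n):
        self_r = np.corrcoef(obs[s], pred[s])[0, 1]
        count = 0
        for a in range(n):
            if a == s:
                continue
            if np.corrcoef(obs[s], pred[a])[0, 1] < self_r:
                count += 1
        total += count / n
    return total / n


class TestAvgCorr:
    def test_perfect_prediction(self, rng):
        obs = rng.normal(0, 1, (5, 8))
        mu = rng.normal(0, 1, 8)
        p = PredictionSet(observed=obs, predicted=obs.copy(), mu_tr=mu)
        assert avgcorr(p) == pytest.approx(1.0)

    def test_anticorrelated_prediction(self, rng):
        obs = rng.normal(0, 1, (5, 8))
        mu = rng.normal(0, 1, 8)
        pred = -(obs - mu) + mu
        p = PredictionSet(observed=obs, predicted=pred, mu_tr=mu)
        assert avgcorr(p) == pytest.approx(-1.0)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n, e = int(rng.integers(2, 11)), int(rng.integers(3, 21))
            obs = rng.normal(0, 1, (n, e))
            pred = rng.normal(0, 1, (n, e))
            mu = rng.normal(0, 1, e)
            p = PredictionSet(observed=obs, predicted=pred, mu_tr=mu)
            assert avgcorr(p) == pytest.approx(brute_avgcorr(obs, pred, mu), abs=1e-12)


class TestAvgRank:
    def test_perfect_identification_bound(self, rng):
        # orthogonal observed rows; predicted == observed: every
        # self-correlation is strictly largest, giving (n-1)/n
        n = 4
        obs = np.eye(n, 8) + 0.01 * rng.normal(0, 1, (n, 8))
        p = PredictionSet(observed=obs, predicted=obs.copy(), mu_tr=np.zeros(8))
        assert avgrank(p) == pytest.approx((n - 1) / n)

    def test_identical_predictions_zero(self, rng):
        obs = rng.normal(0, 1, (5, 10))
        pred = np.tile(rng.normal(0, 1, 10), (5, 1))
        p = PredictionSet(observed=obs, predicted=pred, mu_tr=np.zeros(10))
        assert avgrank(p) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            n, e = int(rng.integers(2, 11)), int(rng.integers(3, 21))
            obs = rng.normal(0, 1, (n, e))
            pred = rng.normal(0, 1, (n, e))
            p = PredictionSet(observed=obs, predicted=pred, mu_tr=np.zeros(e))
            assert avgrank(p) == pytest.approx(brute_avgrank(obs, pred), abs=1e-12)

    def test_upper_bound_holds(self, rng):
        for _ in range(50):
            n = int(rng.integers(2, 9))
            obs = rng.normal(0, 1, (n, 12))
            pred = rng.normal(0, 1, (n, 12))
            p = PredictionSet(observed=obs, predicted=pred, mu_tr=np.zeros(12))
            assert avgrank(p) <= (n - 1) / n + 1e-12

    def test_normalization_switch(self, rng):
        n = 4
        obs = np.eye(n, 8) + 0.01 * rng.normal(0, 1, (n, 8))
        p = PredictionSet(observed=obs, predicted=obs.copy(), mu_tr=np.zeros(8))
        assert avgrank(p, normalization="n-1") == pytest.approx(1.0)


class TestContribution:
    def test_exact_edge_gives_one(self, rng):
        fa = rng.normal(0.5, 0.05, 30)
        fc = np.column_stack([fa, rng.normal(0, 1, 30)])
        assert sc_fc_contribution(fa, fc) == pytest.approx(1.0)

    def test_constructed_mixture_levels(self, rng):
        n = 20000
        fa = rng.normal(0, 1, n)
        e1 = 0.3 * fa + np.sqrt(1 - 0.09) * rng.normal(0, 1, n)
        e2 = 0.8 * fa + np.sqrt(1 - 0.64) * rng.normal(0, 1, n)
        got = sc_fc_contribution(fa, np.column_stack([e1, e2]))
        assert got == pytest.approx(0.8, abs=0.02)

    def test_max_of_null_is_positively_biased(self, rng):
        n, m = 2000, 30
        fa = rng.normal(0, 1, n)
        fc = rng.normal(0, 1, (n, m))
        got = sc_fc_contribution(fa, fc)
        # expected max of m null correlations ~ sqrt(2 log m / n) > 0
        assert 0 < got < 3 * np.sqrt(2 * np.log(m) / n)

    def test_zero_variance_columns_skipped(self, rng):
        fa = rng.normal(0, 1, 10)
        fc = np.column_stack([np.full(10, 2.0), fa])
        assert sc_fc_contribution(fa, fc) == pytest.approx(1.0)


class TestNetworkSC:
    @pytest.fixture
    def atlas(self):
        parc = Parcellation(
            regions=[(1, "a", "A"), (2, "b", "B"), (3, "c", "A"), (4, "d", "C")]
        )
        entries = [
            (make_line(0.0), (1, 2), 3),  # A-B
            (make_line(1.0), (2, 3), 3),  # A-B again
            (make_line(2.0), (1, 3), 3),  # A-A
        ]
        return assemble_atlas(entries, parc)

    def test_mean_over_pathways(self, atlas):
        sc = network_sc_matrix({0: 0.4, 1: 0.6, 2: 0.5}, atlas, ["A", "B", "C"])
        assert sc.loc["A", "B"] == pytest.approx(0.5)
        assert sc.loc["A", "A"] == pytest.approx(0.5)

    def test_absent_pair_is_zero(self, atlas):
        sc = network_sc_matrix({0: 0.4, 1: 0.6, 2: 0.5}, atlas, ["A", "B", "C"])
        assert sc.loc["A", "C"] == 0.0
        assert sc.loc["C", "C"] == 0.0

    def test_symmetric(self, atlas):
        sc = network_sc_matrix({0: 0.4, 1: 0.6, 2: 0.5}, atlas, ["A", "B", "C"])
        assert np.allclose(sc.values, sc.values.T)


class TestSignedDecomposition:
    def test_hand_example(self):
        pos, neg = signed_decomposition([2.0, -1.0], [[1.0, 1.0]])
        assert pos[0] == 2.0 and neg[0] == -1.0

    def test_all_positive_weights(self, rng):
        w = np.abs(rng.normal(0, 1, 5))
        X = rng.normal(0, 1, (10, 5))
        pos, neg = signed_decomposition(w, X)
        assert np.allclose(neg, 0.0)

    def test_conservation(self, rng):
        for _ in range(20):
            w = rng.normal(0, 1, 8)
            X = rng.normal(0, 1, (15, 8))
            pos, neg = signed_decomposition(w, X)
            assert np.allclose(pos + neg, X @ w, atol=1e-12)


class TestBAGCorrection:
    def _records(self, rng, n, slope=0.6, intercept=20.0, noise=2.0):
        ages = rng.uniform(45, 80, n)
        pred = slope * ages + intercept + rng.normal(0, noise, n)
        return [
            BAGRecord(i, float(a), float(p)) for i, (a, p) in enumerate(zip(ages, pred))
        ]

    def test_linear_bias_removed(self, rng):
        recs = bag_bias_correct(self._records(rng, 2000), seed=3)
        ages = np.array([r.age for r in recs])
        cbag = np.array([r.corrected_bag for r in recs])
        assert abs(np.corrcoef(cbag, ages)[0, 1]) <= 0.05

    def test_unbiased_bag_unchanged(self, rng):
        ages = rng.uniform(45, 80, 500)
        pred = ages + rng.normal(0, 3, 500)  # slope 1: raw BAG age-free
        recs = bag_bias_correct(
            [BAGRecord(i, float(a), float(p)) for i, (a, p) in enumerate(zip(ages, pred))],
            seed=0,
        )
        raw = np.array([r.raw_bag for r in recs])
        cor = np.array([r.corrected_bag for r in recs])
        assert np.corrcoef(raw, cor)[0, 1] > 0.98

    def test_correction_is_cross_fitted(self, rng):
        # a record's own half must not influence its correction: changing
        # fold-1 records only must leave fold-1 corrections' fitted trend
        # (derived from fold 0) unchanged
        base = self._records(rng, 200)
        out1 = bag_bias_correct(base, seed=5)
        fold_of = {r.subject_id: r.fold for r in out1}
        modified = [
            BAGRecord(r.subject_id, r.age, r.predicted_age + (5.0 if fold_of[r.subject_id] == 1 else 0.0))
            for r in base
        ]
        out2 = bag_bias_correct(modified, seed=5)
        for r1, r2 in zip(out1, out2):
            if r1.fold == 1:
                # raw shifted by 5; correction trend unchanged
                assert r2.corrected_bag - r1.corrected_bag == pytest.approx(5.0, abs=1e-9)

    def test_raw_bag_definition_enforced(self):
        with pytest.raises(ValueError):
            BAGRecord("s", 50.0, 55.0, raw_bag=3.0)

    def test_too_few_records(self, rng):
        with pytest.raises(ValueError):
            bag_bias_correct(self._records(rng, 10))


class TestTraitScan:
    def test_self_trait_coefficient_one(self, rng):
        bag = rng.normal(0, 2, 300)
        traits = pd.DataFrame({"self": bag})
        res = trait_association_scan(bag, traits, n_traits=1)
        assert res.loc[0, "beta"] == pytest.approx(1.0, abs=1e-9)
        assert res.loc[0, "p"] < 1e-100

    def test_null_false_positive_rate(self, rng):
        # 200 independent null traits: Bonferroni keeps FWE near alpha
        n = 300
        bag = rng.normal(0, 1, n)
        traits = pd.DataFrame(
            {f"t{i}": rng.normal(0, 1, n) for i in range(200)}
        )
        res = trait_association_scan(bag, traits, alpha=0.05)
        assert res["bonferroni_sig"].sum() <= 2

    def test_injected_effect_detected(self, rng):
        n = 5000
        trait = rng.normal(0, 1, n)
        bag = 0.2 * trait + rng.normal(0, 1, n)
        traits = pd.DataFrame({"hit": trait})
        res = trait_association_scan(bag, traits, n_traits=96)
        assert bool(res.loc[0, "bonferroni_sig"])

    def test_collinear_covariate_skipped(self, rng):
        n = 100
        bag = rng.normal(0, 1, n)
        x = rng.normal(0, 1, n)
        traits = pd.DataFrame({"t": x})
        cov = pd.DataFrame({"c1": x * 2.0})  # collinear with the trait
        res = trait_association_scan(bag, traits, covariates=cov)
        assert res.loc[0, "note"] == "collinear covariates"

    def test_matching_covariate_dropped_for_own_trait(self, rng):
        n = 200
        sex = rng.integers(0, 2, n).astype(float)
        bag = 0.5 * sex + rng.normal(0, 1, n)
        traits = pd.DataFrame({"sex": sex})
        cov = pd.DataFrame({"sex": sex})
        res = trait_association_scan(bag, traits, covariates=cov, n_traits=1)
        assert res.loc[0, "note"] == ""
        assert np.isfinite(res.loc[0, "beta"])
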
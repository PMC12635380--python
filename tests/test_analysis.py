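"""Group-statistics, classification, importance and network-map tests."""

import numpy as np
import pandas as pd
import pytest

import hopfbif as hb
from hopfbif.analysis import (
    NetworkMap,
    classify_cohorts_svm,
    default_network_map,
    network_activation,
    node_mean,
    pairwise_mwu_bh,
    permutation_importance,
    significance_band,
)
from hopfbif.inference import CohortPredictions


def _preds(a_hat, labels=None):
    a_hat = np.asarray(a_hat, dtype=float)
    labels = labels or tuple(f"c{i}" for i in range(a_hat.shape[0]))
    return CohortPredictions(a_hat, tuple(labels), tuple(range(a_hat.shape[1])))


def bh_stepup(p):
    """Hand implementation of the Benjamini-Hochberg step-up adjustment."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestNodeMean:
    def test_constant_array(self):
        preds = _preds(np.full((2, 3, 4), 0.3))
        assert np.allclose(node_mean(preds), 0.3)

    def test_single_node_identity(self, rng):
        a = rng.uniform(-1, 1, size=(2, 5, 1))
        assert np.allclose(node_mean(_preds(a)), a[:, :, 0])

    def test_matches_bruteforce_loop(self, rng):
        a = rng.uniform(-1, 1, size=(3, 4, 6))
        out = node_mean(_preds(a))
        for c in range(3):
            for s in range(4):
                assert out[c, s] == pytest.approx(sum(a[c, s]) / 6)


class TestPairwiseMwuBh:
    def test_identical_cohorts_not_significant(self, rng):
        x = rng.uniform(size=30)
        table = pairwise_mwu_bh(np.vstack([x, x]))
        assert table["p_adj"].iloc[0] > 0.9
        assert table["significance"].iloc[0] == "ns"

    def test_bh_adjustment_matches_stepup_formula(self, rng):
        # worked example: {0.01, 0.02, 0.03, 0.04} -> all 0.04
        assert np.allclose(bh_stepup([0.01, 0.02, 0.03, 0.04]), 0.04)
        from statsmodels.stats.multitest import multipletests

        for _ in range(5):
            p = rng.uniform(size=10)
            assert np.allclose(multipletests(p, method="fdr_bh")[1], bh_stepup(p))

    def test_shifted_uniform_cohorts_strongly_significant(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, size=100)
        b = rng.uniform(0, 1, size=100) + 1.0
        table = pairwise_mwu_bh(np.vstack([a, b]))
        assert table["p_adj"].iloc[0] < 1e-10
        # oracle: exact U statistic by pair counting (disjoint supports)
        u_brute = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert table["U"].iloc[0] == pytest.approx(u_brute)

    def test_all_pairs_tested_and_jointly_corrected(self, rng):
        values = rng.uniform(size=(4, 20))
        table = pairwise_mwu_bh(values)
        assert len(table) == 6
        assert np.allclose(table["p_adj"], bh_stepup(table["p_raw"]))

    def test_adjusted_never_below_raw_and_monotone(self, rng):
        values = rng.uniform(size=(5, 15))
        table = pairwise_mwu_bh(values).sort_values("p_raw")
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-15)
        assert np.all(np.diff(table["p_adj"]) >= -1e-15)

    def test_significance_bands(self):
        assert significance_band(5e-5) == "****"
        assert significance_band(5e-4) == "***"
        assert significance_band(5e-3) == "**"
        assert significance_band(0.03) == "*"
        assert significance_band(0.2) == "ns"


class TestSvmClassification:
    def test_wellseparated_clusters_fully_classified(self, rng):
        a = rng.normal(0, 1, size=(60, 5))
        b = rng.normal(10, 1, size=(60, 5))
        res = classify_cohorts_svm(np.vstack([a, b]), ["a"] * 60 + ["b"] * 60)
        assert res.test_accuracy == 1.0

    def test_shuffled_labels_hit_chance_level(self, rng):
        # 8 balanced classes, labels independent of features -> 12.5% chance
        n_per = 40
        X = rng.normal(size=(8 * n_per, 6))
        y = np.repeat(np.arange(8), n_per)
        res = classify_cohorts_svm(X, y, seed=0)
        n_test = len(res.y_test)
        sigma = np.sqrt(0.125 * 0.875 / n_test)
        assert abs(res.test_accuracy - 0.125) < 3 * sigma

    def test_confusion_rows_sum_to_class_counts(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 4)), rng.normal(3, 1, (30, 4))])
        y = ["a"] * 30 + ["b"] * 30
        res = classify_cohorts_svm(X, y)
        counts = {c: (res.y_test == c).sum() for c in res.classes}
        for i, c in enumerate(res.classes):
            assert res.confusion[i].sum() == counts[c]

    def test_separated_pseudocohort_truth_beats_chance(self, connectome10):
        # generator invariant: cohort-mean separation 3x the spread yields
        # individual-level accuracy far above chance
        spread = 0.05
        cohorts = hb.generate_pseudo_cohorts(
            2, 150, connectome10, 1.0, hb.SimulationConfig(seed=41, n_discard=2),
            cohort_a_means=np.array([-0.1, 0.05]), a_spread=spread, T_range=(3, 5),
        )
        C, S, N = cohorts.truth.shape
        res = classify_cohorts_svm(
            cohorts.truth.reshape(C * S, N), np.repeat(["rest", "task"], S), seed=0
        )
        n_test = len(res.y_test)
        assert res.test_accuracy > 0.5 + 5 * np.sqrt(0.25 / n_test)

    def test_small_class_rejected(self, rng):
        X = rng.normal(size=(12, 3))
        y = ["a"] * 6 + ["b"] * 6
        with pytest.raises(ValueError, match="cv_folds"):
            classify_cohorts_svm(X, y, cv_folds=10)


class TestPermutationImportance:
    def _toy_model(self, rng, n=200):
        # one perfectly informative binary column, the rest noise
        y = rng.integers(0, 2, size=n)
        X = rng.normal(size=(n, 4))
        X[:, 2] = y * 2.0 - 1.0
        X[:, 0] = 0.7  # constant column
        res = classify_cohorts_svm(X, y, cv_folds=5, seed=1)
        return res

    def test_constant_feature_has_exactly_zero_drop(self, rng):
        res = self._toy_model(rng)
        imp = permutation_importance(res.model, res.X_test, res.y_test, seed=2)
        assert imp.loc[0, "mean_drop"] == 0.0

    def test_informative_feature_dominates(self, rng):
        res = self._toy_model(rng)
        imp = permutation_importance(res.model, res.X_test, res.y_test, seed=2)
        drops = imp["mean_drop"].to_numpy()
        assert np.argmax(drops) == 2
        assert drops[2] > 0.3  # baseline ~1.0 vs chance ~0.5
        assert np.all(np.abs(np.delete(drops, 2)) < 0.15)

    def test_seeded_determinism(self, rng):
        res = self._toy_model(rng)
        a = permutation_importance(res.model, res.X_test, res.y_test, seed=3)
        b = permutation_importance(res.model, res.X_test, res.y_test, seed=3)
        assert np.array_equal(a["mean_drop"], b["mean_drop"])

    def test_single_repeat_rejected(self, rng):
        res = self._toy_model(rng)
        with pytest.raises(ValueError, match="n_repeats"):
            permutation_importance(res.model, res.X_test, res.y_test, n_repeats=1)


class TestNetworkActivation:
    def _map4(self):
        return NetworkMap(
            {"r0": "visual", "r1": "visual", "r2": "limbic", "r3": "limbic"},
            ("visual", "limbic"),
        )

    def test_task_equal_to_rest_gives_zeros(self, rng):
        a = np.tile(rng.uniform(-1, 1, size=(1, 5, 4)), (2, 1, 1))
        preds = _preds(a, ("rest", "task"))
        out = network_activation(preds, self._map4(), "rest",
                                 region_names=["r0", "r1", "r2", "r3"])
        assert np.allclose(out.to_numpy(), 0.0)

    def test_uniform_offset_propagates_to_every_network(self, rng):
        rest = rng.uniform(-1, 1, size=(5, 4))
        a = np.stack([rest, rest + 0.1])
        preds = _preds(a, ("rest", "task"))
        out = network_activation(preds, self._map4(), "rest",
                                 region_names=["r0", "r1", "r2", "r3"])
        assert np.allclose(out.to_numpy(), 0.1)

    def test_hand_computed_four_node_example(self):
        rest = np.array([[0.0, 0.0, 0.0, 0.0]])
        task = np.array([[0.2, 0.4, -0.1, 0.3]])
        preds = _preds(np.stack([rest, task]), ("rest", "task"))
        out = network_activation(preds, self._map4(), "rest",
                                 region_names=["r0", "r1", "r2", "r3"])
        assert out.loc["task", "visual"] == pytest.approx((0.2 + 0.4) / 2)
        assert out.loc["task", "limbic"] == pytest.approx((-0.1 + 0.3) / 2)

    def test_network_relabeling_equivariance(self, rng):
        a = rng.uniform(-1, 1, size=(2, 6, 4))
        preds = _preds(a, ("rest", "task"))
        names = ["r0", "r1", "r2", "r3"]
        fwd = network_activation(preds, self._map4(), "rest", region_names=names)
        swapped = NetworkMap(
            {"r0": "B", "r1": "B", "r2": "A", "r3": "A"}, ("A", "B")
        )
        rev = network_activation(preds, swapped, "rest", region_names=names)
        assert np.allclose(fwd["visual"], rev["B"])
        assert np.allclose(fwd["limbic"], rev["A"])

    def test_unmapped_region_rejected(self, rng):
        preds = _preds(rng.uniform(size=(2, 3, 4)), ("rest", "task"))
        with pytest.raises(ValueError, match="not mapped"):
            network_activation(preds, self._map4(), "rest",
                               region_names=["r0", "r1", "r2", "zz"])

    def test_missing_rest_cohort_rejected(self, rng):
        preds = _preds(rng.uniform(size=(2, 3, 4)), ("a", "b"))
        with pytest.raises(ValueError, match="rest"):
            network_activation(preds, self._map4(), "rest",
                               region_names=["r0", "r1", "r2", "r3"])


class TestDefaultNetworkMap:
    def test_dk80_table_well_formed(self):
        nmap = default_network_map()
        assert len(nmap.region_to_network) == 80
        assert len(nmap.networks) == 8
        assert "Subcortical" in nmap.networks
        counts = pd.Series(list(nmap.region_to_network.values())).value_counts()
        assert counts["Subcortical"] == 18
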
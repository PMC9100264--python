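"""Null-importance scoring, threshold and redundancy pruning."""

import numpy as np
import pandas as pd
import pytest

from hrvfatigue.selection import (NullImportanceSelector, correlation_matrix,
                                  drop_unimportant, feature_score,
                                  gini_importance,
                                  null_importance_distribution,
                                  remove_redundant, select_features)
from hrvfatigue.simulate import planted_feature_table

FAST_RF = dict(n_estimators=50)


class TestGiniImportance:
    def test_planted_signal_dominates(self):
        # y is a threshold function of one feature; over 10 seeds that
        # feature always carries the largest importance
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.normal(size=(500, 5)),
                             columns=list("abcde"))
            y = (X["c"] > 0).astype(int)
            imp = gini_importance(X, y, rf_params=FAST_RF, seed=seed)
            assert max(imp, key=imp.get) == "c"

    def test_constant_feature_zero_importance(self, rng):
        X = pd.DataFrame({"sig": rng.normal(size=200),
                          "const": np.zeros(200)})
        y = (X["sig"] > 0).astype(int)
        imp = gini_importance(X, y, rf_params=FAST_RF, seed=0)
        assert imp["const"] == 0.0

    def test_duplicated_columns_share_credit(self):
        # the summed importance of two identical informative columns is
        # close to the importance the single column earns alone
        totals, singles = [], []
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            base = rng.normal(size=600)
            noise = rng.normal(size=(600, 3))
            y = (base > 0).astype(int)
            Xd = pd.DataFrame(np.column_stack([base, base, noise]),
                              columns=["a1", "a2", "n1", "n2", "n3"])
            Xs = pd.DataFrame(np.column_stack([base, noise]),
                              columns=["a1", "n1", "n2", "n3"])
            d = gini_importance(Xd, y, rf_params=FAST_RF, seed=seed)
            s = gini_importance(Xs, y, rf_params=FAST_RF, seed=seed)
            totals.append(d["a1"] + d["a2"])
            singles.append(s["a1"])
        assert np.mean(totals) == pytest.approx(np.mean(singles), rel=0.25)

    def test_single_class_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)))
        with pytest.raises(ValueError, match="class"):
            gini_importance(X, np.zeros(50))


class TestNullDistribution:
    def test_shapes_and_determinism(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        y = rng.integers(0, 3, 60)
        d1 = null_importance_distribution(X, y, n_permutations=3,
                                          rf_params=FAST_RF, seed=5)
        d2 = null_importance_distribution(X, y, n_permutations=3,
                                          rf_params=FAST_RF, seed=5)
        assert all(len(v) == 3 for v in d1.values())
        for f in d1:
            np.testing.assert_array_equal(d1[f], d2[f])

    def test_shuffling_destroys_planted_association(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X = pd.DataFrame({"sig": rng.normal(size=300),
                              "noise": rng.normal(size=300)})
            y = (X["sig"] > 0).astype(int)
            actual = gini_importance(X, y, rf_params=FAST_RF, seed=seed)
            null = null_importance_distribution(
                X, y, n_permutations=5, rf_params=FAST_RF, seed=seed)
            assert np.mean(null["sig"]) < actual["sig"]

    def test_invalid_t_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 2)))
        with pytest.raises(ValueError, match="permutations"):
            null_importance_distribution(X, rng.integers(0, 2, 30),
                                         n_permutations=0)


class TestFeatureScore:
    @pytest.mark.parametrize("actual,null,expected", [
        (5.0, [1, 2, 3, 4], 100.0),
        (0.5, [1, 2, 3, 4], 0.0),
        (2.0, [1, 2, 3, 4], 25.0),  # tie at 2 counts against the feature
        (2.5, [1, 2, 3, 4], 50.0),
    ])
    def test_edge_cases(self, actual, null, expected):
        assert feature_score(actual, np.array(null)) == expected

    def test_invariant_under_null_permutation(self, rng):
        null = rng.normal(size=100)
        s = feature_score(0.3, null)
        assert feature_score(0.3, rng.permutation(null)) == s


class TestDropUnimportant:
    def test_zero_threshold_uses_lte(self):
        assert drop_unimportant({"a": 0.0, "b": 50.0, "c": 100.0}, 0) == ["a"]

    def test_all_perfect_scores_drop_nothing(self):
        assert drop_unimportant({"a": 100.0, "b": 100.0}, 0) == []

    def test_intermediate_threshold(self):
        assert drop_unimportant({"a": 10.0, "b": 20.0}, 15.0) == ["a"]


class TestCorrelationMatrix:
    def test_exact_linear_relations(self):
        X = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6],
                          "z": [-2.0, -4, -6]})
        c = correlation_matrix(X)
        assert c.loc["x", "x"] == 1.0
        assert c.loc["x", "y"] == pytest.approx(1.0)
        assert c.loc["x", "z"] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(31)  # documented seed
        X = pd.DataFrame(rng.normal(size=(10000, 2)), columns=["a", "b"])
        assert abs(correlation_matrix(X).loc["a", "b"]) < 0.05

    def test_zero_variance_column_reports_zero(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=50), "k": np.ones(50)})
        c = correlation_matrix(X)
        assert c.loc["a", "k"] == 0.0
        assert c.loc["k", "k"] == 1.0


class TestRemoveRedundant:
    @staticmethod
    def _corr(names, entries):
        c = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in entries:
            c.loc[a, b] = c.loc[b, a] = r
        return c

    def test_duplicate_drops_less_important(self):
        c = self._corr(["A", "B"], [("A", "B", 1.0)])
        assert remove_redundant(c, {"A": 5.0, "B": 1.0}) == ["B"]

    def test_no_pairs_above_threshold(self):
        c = self._corr(["A", "B"], [("A", "B", 0.5)])
        assert remove_redundant(c, {"A": 5.0, "B": 1.0}) == []

    def test_paper_style_three_pairs(self):
        # meanNN~meanHR, NN50~pNN50, SDNN~SD2 above threshold; the less
        # important member of each pair is removed
        names = ["meanNN", "meanHR", "SDNN", "NN50", "pNN50", "SD2"]
        c = self._corr(names, [("meanNN", "meanHR", -0.99),
                               ("NN50", "pNN50", 0.97),
                               ("SDNN", "SD2", 0.95)])
        imp = {"meanNN": 1.0, "meanHR": 3.0, "SDNN": 1.5, "NN50": 2.5,
               "pNN50": 2.0, "SD2": 2.2}
        assert remove_redundant(c, imp) == ["meanNN", "SDNN", "pNN50"]

    def test_chained_correlation_skips_removed(self):
        # A~B and B~C: after B is removed for the stronger pair, C must not
        # be removed for correlating with the already-removed B
        c = self._corr(["A", "B", "C"], [("A", "B", 0.99), ("B", "C", 0.95)])
        imp = {"A": 3.0, "B": 1.0, "C": 0.5}
        assert remove_redundant(c, imp) == ["B"]

    def test_importance_tie_drops_later_feature(self):
        c = self._corr(["A", "B"], [("A", "B", 0.95)])
        assert remove_redundant(c, {"A": 2.0, "B": 2.0}) == ["B"]


class TestSelectFeatures:
    def test_partition_invariant_and_determinism(self):
        X, y = planted_feature_table(n=300, k_informative=2, k_duplicated=1,
                                     k_noise=3, seed=9)
        r1 = select_features(X, y, n_permutations=10, rf_params=FAST_RF,
                             seed=11)
        r2 = select_features(X, y, n_permutations=10, rf_params=FAST_RF,
                             seed=11)
        all_feats = sorted(X.columns)
        assert sorted(r1.selected + r1.phi1_dropped + r1.phi2_dropped) == all_feats
        assert not (set(r1.phi1_dropped) & set(r1.phi2_dropped))
        assert r1.selected == r2.selected
        assert r1.report.scores == r2.report.scores

    def test_r1_100_drops_everything(self):
        X, y = planted_feature_table(n=200, k_informative=1, k_duplicated=0,
                                     k_noise=2, seed=3)
        res = select_features(X, y, r1=100.0, n_permutations=5,
                              rf_params=FAST_RF, seed=3)
        assert res.selected == []

    def test_planted_recovery_over_seeds(self):
        # per duplicated pair exactly one member survives to the selected
        # set; whenever both members pass the importance stage, the
        # redundancy stage prunes exactly one of them
        n_ok_inf = 0
        n_seeds = 20
        for seed in range(n_seeds):
            X, y = planted_feature_table(n=1000, k_informative=3,
                                         k_duplicated=3, k_noise=3,
                                         effect_size=2.0, seed=seed)
            res = select_features(X, y, n_permutations=15,
                                  rf_params=FAST_RF, seed=seed)
            n_ok_inf += sum(1 for i in range(3)
                            if f"inf{i}" in res.selected
                            or f"dup{i}" in res.selected)
            for i in range(3):
                pair = {f"inf{i}", f"dup{i}"}
                assert len(pair & set(res.selected)) == 1
                if not pair & set(res.phi1_dropped):
                    assert len(pair & set(res.phi2_dropped)) == 1
        assert n_ok_inf >= 0.9 * 3 * n_seeds

    def test_nonfinite_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            select_features(X, rng.integers(0, 2, 60), n_permutations=2)


class TestSklearnInterface:
    def test_selector_transform_and_support(self):
        X, y = planted_feature_table(n=300, k_informative=2, k_duplicated=1,
                                     k_noise=2, seed=21)
        sel = NullImportanceSelector(n_permutations=10, rf_params=FAST_RF,
                                     random_state=21).fit(X, y)
        mask = sel.get_support()
        assert mask.sum() == len(sel.selected_features_)
        Xt = sel.transform(X)
        assert Xt.shape == (300, mask.sum())

    def test_get_set_params_roundtrip(self):
        sel = NullImportanceSelector(r1=5.0, n_permutations=7)
        params = sel.get_params()
        clone = NullImportanceSelector().set_params(**params)
        assert clone.r1 == 5.0 and clone.n_permutations == 7
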
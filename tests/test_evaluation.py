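import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaboruta import (
    ComparisonSpec,
    bonferroni_flag,
    delta_percent,
    evaluate_comparison,
    mwu_test,
    rf_evaluate,
    roc_auc,
    within_group_correlations,
)
from metaboruta.adjust import ResidualMatrix


def brute_force_u(x, y):
    """Independent U oracle: count pairs x > y, ties 1/2."""
    u = 0.0
    for a in x:
        for b in y:
            u += 1.0 if a > b else (0.5 if a == b else 0.0)
    return u


def exact_two_sided_p(x, y):
    """Permutation-exact two-sided MWU p by full enumeration (no ties)."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = brute_force_u(x, y)
    mu = n1 * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        g1 = [pooled[i] for i in idx]
        g2 = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = brute_force_u(g1, g2)
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestDeltaPercent:
    def test_equal_means_zero(self):
        assert delta_percent([2.0, 2.0], [2.0, 2.0]) == 0.0

    def test_worked_values_symmetric_mean_denominator(self):
        assert delta_percent([2.0], [1.0]) == pytest.approx(-66.6667, abs=1e-3)
        assert delta_percent([1.0], [3.0]) == pytest.approx(100.0)

    def test_magnitude_can_exceed_100(self):
        # strongly divergent means: |delta| in (100, 200)
        assert abs(delta_percent([10.0], [1.0])) > 100

    @given(
        m1=st.floats(0.01, 1e3),
        m2=st.floats(0.01, 1e3),
    )
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetry(self, m1, m2):
        d12 = delta_percent([m1], [m2])
        d21 = delta_percent([m2], [m1])
        assert d12 == pytest.approx(-d21, rel=1e-9)

    def test_nonpositive_denominator_gives_na(self):
        with pytest.warns(UserWarning):
            assert np.isnan(delta_percent([0.0], [0.0]))


class TestMWU:
    def test_separated_groups_exact_enumeration(self):
        # g1=[1,2,3] vs g2=[4,5,6]: U=0; exact two-sided p = 0.1
        res = mwu_test([1, 2, 3], [4, 5, 6])
        assert res.U == 0.0
        assert res.method == "exact"
        assert res.p == pytest.approx(exact_two_sided_p([1, 2, 3], [4, 5, 6]))
        assert res.p == pytest.approx(0.1)

    def test_interleaved_groups_u_oracle(self):
        # pairs (1,2)(1,4)(3,2)(3,4) -> only 3>2 counts
        res = mwu_test([1, 3], [2, 4])
        assert res.U == brute_force_u([1, 3], [2, 4]) == 1.0

    def test_identical_multisets_half_u(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = mwu_test(vals, vals)
        assert res.U == len(vals) ** 2 / 2

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=25)
    def test_u_matches_brute_force_on_random_input(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=rng.integers(2, 8))
        y = rng.normal(size=rng.integers(2, 8))
        assert mwu_test(x, y).U == pytest.approx(brute_force_u(x, y))

    def test_p_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=10), rng.normal(1.0, 1.0, size=12)
        base = mwu_test(x, y)
        trans = mwu_test(np.exp(x), np.exp(y))
        assert base.p == pytest.approx(trans.p)
        assert base.U == pytest.approx(trans.U)

    def test_ties_switch_to_asymptotic(self):
        res = mwu_test([1, 1, 2] * 2, [2, 3, 3] * 2)
        assert res.method == "asymptotic"
        assert 0 < res.p <= 1


class TestROCAUC:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3], [7, 8, 9]) == 1.0

    def test_interleaved_pairs(self):
        # 3 of 4 pairs favor g2
        assert roc_auc([1, 3], [2, 4]) == 0.75

    def test_identical_groups_chance(self):
        assert roc_auc([5, 5, 5], [5, 5, 5]) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=50)
    def test_auc_u_identity(self, seed):
        """AUC * n1 * n2 equals max(U, n1*n2 - U) exactly."""
        rng = np.random.default_rng(seed)
        x = rng.choice(10, size=rng.integers(1, 7)).astype(float)
        y = rng.choice(10, size=rng.integers(1, 7)).astype(float)
        u = brute_force_u(x, y)
        n = len(x) * len(y)
        assert roc_auc(x, y) * n == pytest.approx(max(u, n - u))

    def test_orientation_always_at_least_half(self):
        assert roc_auc([10, 11], [1, 2]) == 1.0  # direction-free


class TestBonferroni:
    def test_p_one_never_significant(self):
        assert not bonferroni_flag(1.0, 1)

    def test_threshold_for_181_tests(self):
        # alpha/n = 0.05/181 = 2.7624e-4
        assert bonferroni_flag(1.5e-6, 181)
        assert not bonferroni_flag(2.8e-4, 181)
        assert bonferroni_flag(2.7e-4, 181)

    def test_depends_only_on_p_n_alpha(self):
        assert bonferroni_flag(0.01, 4, alpha=0.05) == (0.01 < 0.05 / 4)


class TestRandomForestEvaluation:
    def _xy(self, seed, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(24, 5))
        x[:12, :3] += shift
        y = np.array(["A"] * 12 + ["B"] * 12)
        return pd.DataFrame(x, index=[f"s{i}" for i in range(24)]), y

    def test_strong_signal_low_oob(self):
        errs = []
        for seed in range(10):
            X, y = self._xy(seed, shift=5.0)
            _, oob, _ = rf_evaluate(X, y, n_trees=300, seed=seed)
            errs.append(oob)
        assert np.mean(errs) <= 0.05

    def test_permuted_labels_chance_oob(self):
        errs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X, y = self._xy(seed, shift=0.0)
            _, oob, _ = rf_evaluate(X, rng.permutation(y), n_trees=300, seed=seed)
            errs.append(oob)
        assert abs(np.mean(errs) - 0.5) <= 0.15

    def test_misclassified_ids_consistent_with_oob(self):
        X, y = self._xy(0, shift=2.0)
        _, oob, bad = rf_evaluate(X, y, n_trees=500, seed=0)
        assert oob == pytest.approx(len(bad) / len(X))
        assert all(b in X.index for b in bad)

    def test_mdg_positive_for_informative_feature(self):
        X, y = self._xy(1, shift=5.0)
        mdg, _, _ = rf_evaluate(X, y, n_trees=300, seed=1)
        assert mdg.iloc[:3].min() > mdg.iloc[3:].max()


def residuals_fixture(n=8, n_met=4, seed=0):
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"s{i}" for i in range(2 * n)], name="sample_id")
    x = rng.normal(size=(2 * n, n_met))
    smeta = pd.DataFrame(
        {"group": ["A"] * n + ["B"] * n, "sex": ["M", "F"] * n,
         "carcass_weight": 120.0, "is_qc": False},
        index=ids,
    )
    return ResidualMatrix(
        residuals=pd.DataFrame(x, index=ids, columns=[f"m{j}" for j in range(n_met)]),
        coefficients=pd.DataFrame(),
        sample_meta=smeta,
        sex_coding={"F": 0, "M": 1},
    )


class TestWithinGroupCorrelations:
    def test_unit_diagonal_and_symmetry(self):
        res = residuals_fixture()
        corr, flags = within_group_correlations(res, ["m0", "m1", "m2"], "A")
        np.testing.assert_allclose(np.diag(corr), 1.0)
        pd.testing.assert_frame_equal(corr, corr.T)
        assert not np.diag(flags).any()

    def test_exact_linear_dependence_flagged(self):
        res = residuals_fixture()
        res.residuals["m1"] = 2.0 * res.residuals["m0"]
        corr, flags = within_group_correlations(res, ["m0", "m1"], "A")
        assert corr.loc["m0", "m1"] == pytest.approx(1.0)
        assert flags.loc["m0", "m1"]

    def test_planted_anticorrelation_flagged(self):
        rng = np.random.default_rng(0)
        res = residuals_fixture(n=200)
        base = rng.normal(size=400)
        res.residuals["m0"] = base + 0.4 * rng.normal(size=400)
        res.residuals["m1"] = -base + 0.4 * rng.normal(size=400)
        corr, flags = within_group_correlations(res, ["m0", "m1"], "A")
        assert corr.loc["m0", "m1"] < -0.5
        assert flags.loc["m0", "m1"]

    def test_constant_metabolite_gives_na_row(self):
        res = residuals_fixture()
        res.residuals["m3"] = 1.0
        corr, _ = within_group_correlations(res, ["m0", "m3"], "A")
        assert np.isnan(corr.loc["m3", "m0"])

    def test_too_few_samples_raise(self):
        res = residuals_fixture(n=2)
        with pytest.raises(ValueError, match="fewer than 3"):
            within_group_correlations(res, ["m0"], "A")


class TestEvaluateComparison:
    def test_full_table_schema_and_model_stats(self, strong_signal,
                                               strong_signal_residuals):
        panel, truth = strong_signal
        res = strong_signal_residuals
        g = panel.groups()
        spec = ComparisonSpec.pairwise(g[0], g[1])
        selected = sorted(truth.discriminants_for(g[0], g[1]))[:4]
        table = evaluate_comparison(panel, res, spec, selected,
                                    n_tests=len(res.metabolites),
                                    n_trees=300, seed=0)
        assert set(table.metabolites.index) == set(selected)
        assert {"delta_percent", "mdg", "auc", "mwu_U", "mwu_p",
                "bonferroni_significant"} <= set(table.metabolites.columns)
        assert (table.metabolites["auc"] >= 0.5).all()
        assert 0 <= table.oob_error <= 1
        assert table.oob_error == pytest.approx(
            len(table.misclassified) / 24
        )

    def test_planted_metabolites_score_high_auc(self, strong_signal,
                                                strong_signal_residuals):
        panel, truth = strong_signal
        res = strong_signal_residuals
        g = panel.groups()
        spec = ComparisonSpec.pairwise(g[0], g[1])
        selected = sorted(truth.discriminants_for(g[0], g[1]))
        table = evaluate_comparison(panel, res, spec, selected,
                                    n_tests=len(res.metabolites),
                                    n_trees=300, seed=0)
        assert table.metabolites["auc"].median() >= 0.8
        assert (table.metabolites["mwu_p"] < 0.05).mean() >= 0.8
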
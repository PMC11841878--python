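import numpy as np
import pandas as pd
import pytest

from canopyhsm.maxent import FeatureSpec, FitConfig, fit_maxent
from canopyhsm.model_selection import (CorrelationReport, advance_covariates,
                                       bootstrap_aic_compare,
                                       correlation_screen, cramers_v,
                                       enumerate_uncorrelated_models,
                                       jackknife_gains, percent_contribution,
                                       permutation_importance, rm_sweep)

LQ = FeatureSpec(classes=("linear", "quadratic"))
FAST = FitConfig(rm=2.0, replicates=5, seed=0)


def shifted_data(seed=0, n_a=800, n_u=160, shift=(1.5, 0.0)):
    """Background N(0, I); used tilted along the first covariate only."""
    rng = np.random.default_rng(seed)
    A = rng.normal(0, 1, (n_a, len(shift)))
    z = A @ np.asarray(shift)
    w = np.exp(z - z.max())
    idx = rng.choice(n_a, n_u, replace=True, p=w / w.sum())
    return A[idx], A


class TestCorrelationScreen:
    def test_duplicated_covariate_full_r2_same_group(self, rng):
        x = rng.normal(0, 1, 500)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 500)})
        rep = correlation_screen(df)
        assert rep.matrix[0, 1] == pytest.approx(1.0)
        assert ["a", "b"] in rep.groups and ["c"] in rep.groups

    def test_perfect_2x2_association_gives_v_one(self):
        a = np.repeat([0, 1], 20)
        b = np.repeat([0, 1], 20)
        assert cramers_v(a, b) == pytest.approx(1.0)

    def test_independent_covariates_near_zero(self, rng):
        X = rng.normal(0, 1, (10_000, 4))
        rep = correlation_screen(pd.DataFrame(X, columns=list("abcd")))
        off = rep.matrix[~np.eye(4, dtype=bool)]
        assert off.max() < 0.01
        assert len(rep.groups) == 4  # all singletons

    def test_groups_invariant_to_covariate_order(self, rng):
        x = rng.normal(0, 1, 400)
        y = rng.normal(0, 1, 400)
        d1 = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.1, 400), "c": y})
        d2 = d1[["c", "b", "a"]]
        g1 = {frozenset(g) for g in correlation_screen(d1).groups}
        g2 = {frozenset(g) for g in correlation_screen(d2).groups}
        assert g1 == g2

    def test_mixed_pair_uses_binned_v(self, rng):
        cont = rng.normal(0, 1, 2000)
        cat = (cont > 0).astype(float)  # strongly associated
        rep = correlation_screen(pd.DataFrame({"x": cont, "g": cat}),
                                 kinds=["continuous", "categorical"])
        assert rep.matrix[0, 1] > 0.65

    def test_constant_column_warns_r2_zero(self, rng):
        df = pd.DataFrame({"a": rng.normal(0, 1, 100), "b": np.ones(100)})
        with pytest.warns(UserWarning, match="constant"):
            rep = correlation_screen(df)
        assert rep.matrix[0, 1] == 0.0


class TestImportanceMeasures:
    def test_zero_coefficient_covariate_scores_zero(self):
        U, A = shifted_data(shift=(2.0, 0.0))
        m = fit_maxent(U, A, ["signal", "noise"], FitConfig(rm=30.0),
                       FeatureSpec(classes=("linear",)))
        assert m.beta[1] == 0.0
        imp = permutation_importance(m, U, A, seed=1)
        pc = percent_contribution(m)
        assert imp["noise"] == 0.0
        assert pc["noise"] == 0.0

    def test_single_covariate_scores_hundred(self):
        U, A = shifted_data(shift=(1.5,))
        m = fit_maxent(U, A, ["x"], FitConfig(rm=2.0), LQ)
        assert permutation_importance(m, U, A)["x"] == pytest.approx(100.0)
        assert percent_contribution(m)["x"] == pytest.approx(100.0)

    def test_noise_scores_below_signal(self):
        U, A = shifted_data(shift=(1.5, 0.0))
        m = fit_maxent(U, A, ["signal", "noise"], FitConfig(rm=1.0), LQ)
        imp = permutation_importance(m, U, A, n_permutations=10, seed=2)
        assert imp["noise"] < imp["signal"]

    def test_contributions_sum_to_hundred(self):
        U, A = shifted_data(shift=(1.0, -0.8))
        m = fit_maxent(U, A, ["a", "b"], FitConfig(rm=1.0), LQ)
        assert sum(percent_contribution(m).values()) == pytest.approx(100.0, abs=1e-6)


class TestJackknife:
    def test_noise_only_gain_near_zero_and_redundant_without_gain(self):
        rng = np.random.default_rng(4)
        A = rng.normal(0, 1, (1000, 3))
        A[:, 1] = A[:, 0] + rng.normal(0, 0.05, 1000)  # duplicate of signal
        z = 1.5 * A[:, 0]
        w = np.exp(z - z.max())
        U = A[rng.choice(1000, 200, replace=True, p=w / w.sum())]
        jack = jackknife_gains(["signal", "dup", "noise"], U, A,
                               FitConfig(rm=2.0, seed=0), LQ)
        assert abs(jack.only_train_gain["noise"]) < 0.15
        # dropping a duplicated informative covariate barely moves the gain
        assert jack.without_train_gain["dup"] == pytest.approx(
            jack.full_train_gain, abs=0.1)

    def test_advancement_rule_thresholds(self):
        jack_like = type("J", (), {})()
        contribution = {"a": 60.0, "b": 5.0}
        importance = {"a": 55.0, "b": 30.0}
        jack = type("R", (), {"only_train_gain": {"a": 3.0, "b": 1.0},
                              "only_test_gain": {"a": 2.8, "b": 0.9}})()
        assert advance_covariates(contribution, importance, jack) == ["a"]


class TestEnumerate:
    def report(self, names, groups):
        d = len(names)
        return CorrelationReport(names, np.eye(d), 0.65, groups)

    def test_no_correlation_single_full_model(self):
        rep = self.report(list("abc"), [["a"], ["b"], ["c"]])
        assert enumerate_uncorrelated_models(list("abc"), rep) == [("a", "b", "c")]

    def test_one_pair_two_models(self):
        rep = self.report(list("abcde"), [["a", "b"], ["c"], ["d"], ["e"]])
        models = enumerate_uncorrelated_models(list("abcde"), rep)
        assert models == [("a", "c", "d", "e"), ("b", "c", "d", "e")]

    def test_five_covariates_four_triples(self):
        # two correlated pairs + one singleton -> 2 x 2 x 1 = 4 triples
        rep = self.report(list("abcde"), [["a", "b"], ["c", "d"], ["e"]])
        models = enumerate_uncorrelated_models(list("abcde"), rep)
        assert len(models) == 4
        assert all(len(m) == 3 for m in models)


class TestAicComparison:
    def test_single_candidate_ranked_first(self):
        U, A = shifted_data()
        r = bootstrap_aic_compare([("signal",)], ["signal", "noise"], U, A,
                                  FAST, LQ)
        assert r.best == ("signal",)

    def test_true_model_beats_noise_augmented(self):
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            A = rng.normal(0, 1, (600, 4))
            z = 1.5 * A[:, 0]
            w = np.exp(z - z.max())
            U = A[rng.choice(600, 120, replace=True, p=w / w.sum())]
            names = ["signal", "n1", "n2", "n3"]
            r = bootstrap_aic_compare(
                [("signal",), ("signal", "n1", "n2", "n3")], names,
                U, A, FitConfig(rm=2.0, replicates=10, seed=seed), LQ)
            wins += r.best == ("signal",)
        assert wins >= 8

    def test_identical_candidates_identical_streams(self):
        U, A = shifted_data()
        r = bootstrap_aic_compare([("signal",), ("signal",)],
                                  ["signal", "noise"], U, A, FAST, LQ)
        np.testing.assert_array_equal(r.aics[0], r.aics[1])


class TestRmSweep:
    def test_default_grid_rows_and_identity(self):
        U, A = shifted_data(shift=(1.5, 0.5))
        sw = rm_sweep(("signal", "noise"), ["signal", "noise"], U, A,
                      FitConfig(replicates=3, seed=0), LQ)
        assert len(sw.table) == 9
        err = (sw.table.mean_aic
               - (2 * sw.table.mean_k - 2 * sw.table.mean_lnl)).abs().max()
        assert err < 1e-9
        assert sw.table.delta_aic.min() == 0.0
        assert sw.best_rm in sw.table.rm.values
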
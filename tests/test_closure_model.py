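"""Logistic closure model: MLE, GVIF, BH, stepwise AIC, linearity, LOWESS."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from _oracles import bh_step_up, grid_search_max_loglik, logistic_log_likelihood
from obstaccess.closure_model import (
    LogisticFitError,
    RegressionSpec,
    Term,
    backward_stepwise_aic,
    bh_adjust,
    check_logit_linearity,
    fit_logistic,
    gvif,
    lowess_curve,
    model_fit_stats,
    screen_multicollinearity,
)


def spec_of(*terms: Term, response: str = "y") -> RegressionSpec:
    return RegressionSpec(response=response, terms=tuple(terms))


def cont(name: str) -> Term:
    return Term(name, "continuous")


class TestLogisticMLE:
    def test_intercept_only_symmetric_outcome(self):
        df = pd.DataFrame({"y": [0, 1, 0, 1]})
        res = fit_logistic(df, spec_of())
        assert res.table.loc[0, "coef"] == pytest.approx(0.0, abs=1e-10)
        assert res.table.loc[0, "odds_ratio"] == pytest.approx(1.0, abs=1e-10)

    def test_two_by_two_odds_ratio_closed_form(self):
        # counts: (y=1|x=1)=10, (y=0|x=1)=5, (y=1|x=0)=5, (y=0|x=0)=10
        y = [1] * 10 + [0] * 5 + [1] * 5 + [0] * 10
        x = [1.0] * 15 + [0.0] * 15
        res = fit_logistic(pd.DataFrame({"y": y, "x": x}), spec_of(cont("x")))
        row = res.table.set_index("column").loc["x"]
        assert row["odds_ratio"] == pytest.approx(4.0, abs=1e-6)  # (10*10)/(5*5)
        assert row["ci_low"] < 4.0 < row["ci_high"]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mle_beats_exhaustive_grid(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 9))
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.integers(0, 2, n).astype(float)
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        X = np.column_stack([np.ones(n), x1, x2])
        if np.linalg.matrix_rank(X) < 3:
            x2[0] = 1 - x2[0]
            df["x2"] = x2
            X = np.column_stack([np.ones(n), x1, x2])
        try:
            res = fit_logistic(df, spec_of(cont("x1"), cont("x2")))
        except LogisticFitError:
            return  # separated draw: MLE does not exist, nothing to compare
        grid_best = grid_search_max_loglik(X, y, lo=-4, hi=4, step=0.2)
        assert res.log_likelihood >= grid_best - 1e-4

    def test_score_is_stationary_at_solution(self):
        rng = np.random.default_rng(42)
        n = 400
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(0.3 + 0.8 * x)).astype(int)
        res = fit_logistic(pd.DataFrame({"y": y, "x": x}), spec_of(cont("x")))
        beta = res.params.to_numpy()
        X = np.column_stack([np.ones(n), x])
        p = expit(X @ beta)
        assert np.max(np.abs(X.T @ (y - p))) < 1e-8

    def test_perfect_separation_reported_with_covariate(self):
        df = pd.DataFrame({"y": [0, 0, 0, 1, 1, 1], "x": [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]})
        with pytest.raises(LogisticFitError, match="x"):
            fit_logistic(df, spec_of(cont("x")))

    def test_rank_deficiency_lists_aliased_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        y = rng.integers(0, 2, 50)
        df = pd.DataFrame({"y": y, "x1": x, "x2": x})  # aliased copy
        with pytest.raises(LogisticFitError, match="rank deficient"):
            fit_logistic(df, spec_of(cont("x1"), cont("x2")))

    def test_log_likelihood_matches_direct_summation(self):
        df = pd.DataFrame({"y": [0, 1, 1, 0, 1, 0], "x": [0.5, 1.5, 0.7, 1.2, 1.8, 0.9]})
        res = fit_logistic(df, spec_of(cont("x")))
        X = np.column_stack([np.ones(6), df["x"]])
        ll = logistic_log_likelihood(X, df["y"].to_numpy(), res.params.to_numpy())
        assert res.log_likelihood == pytest.approx(ll, abs=1e-8)

    def test_ci_brackets_odds_ratio_everywhere(self):
        rng = np.random.default_rng(1)
        n = 300
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, n),
                "a": rng.normal(size=n),
                "b": rng.choice(["u", "v", "w"], n),
            }
        )
        res = fit_logistic(
            df, spec_of(cont("a"), Term("b", "categorical", reference="u", levels=("v", "w")))
        )
        tab = res.table
        assert (tab["ci_low"] < tab["odds_ratio"]).all()
        assert (tab["odds_ratio"] < tab["ci_high"]).all()
        assert (tab["odds_ratio"] > 0).all()


class TestGVIF:
    def test_orthogonal_predictors_have_unit_gvif(self):
        # Balanced ±1 design: exactly orthogonal columns.
        x1 = np.array([1, 1, -1, -1] * 10, float)
        x2 = np.array([1, -1, 1, -1] * 10, float)
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.integers(0, 2, 40), "x1": x1, "x2": x2})
        res = fit_logistic(df, spec_of(cont("x1"), cont("x2")))
        assert gvif(res, "x1") == pytest.approx(1.0, abs=1e-12)
        assert gvif(res, "x2") == pytest.approx(1.0, abs=1e-12)

    def test_correlated_pair_matches_closed_form(self):
        rng = np.random.default_rng(3)
        n = 200
        z1 = rng.normal(size=n)
        z2 = rng.normal(size=n)
        # Gram-Schmidt so the sample correlation is exactly 0.8.
        z1 = (z1 - z1.mean()) / z1.std()
        z2 = z2 - z2.mean()
        z2 -= z1 * (z1 @ z2) / (z1 @ z1)
        z2 /= z2.std()
        x2 = 0.8 * z1 + math.sqrt(1 - 0.64) * z2
        df = pd.DataFrame({"y": rng.integers(0, 2, n), "x1": z1, "x2": x2})
        res = fit_logistic(df, spec_of(cont("x1"), cont("x2")))
        assert gvif(res, "x1") == pytest.approx(1.0 / (1.0 - 0.64), rel=1e-9)

    def test_single_term_model_has_unit_gvif(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.integers(0, 2, 60), "x": rng.normal(size=60)})
        res = fit_logistic(df, spec_of(cont("x")))
        assert gvif(res, "x") == 1.0

    def test_unknown_term_rejected(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame({"y": rng.integers(0, 2, 60), "x": rng.normal(size=60)})
        res = fit_logistic(df, spec_of(cont("x")))
        with pytest.raises(KeyError):
            gvif(res, "nope")

    def test_screen_flags_near_duplicates(self):
        rng = np.random.default_rng(5)
        n = 300
        x1 = rng.normal(size=n)
        x2 = x1 + rng.normal(scale=0.05, size=n)  # r ~ 0.999 -> huge VIF
        df = pd.DataFrame({"y": rng.integers(0, 2, n), "x1": x1, "x2": x2})
        res = fit_logistic(df, spec_of(cont("x1"), cont("x2")))
        assert set(screen_multicollinearity(res)) == {"x1", "x2"}


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.03], [0.03]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.05, 0.05], [0.05, 0.05]),
            ([0.01, 0.04, 0.03, 0.005], [0.02, 0.04, 0.04, 0.02]),
        ],
    )
    def test_printed_examples_match_step_up_formula(self, p, expected):
        got = bh_adjust(p)
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(bh_step_up(p), abs=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=25)
    )
    @settings(max_examples=200, deadline=None)
    def test_step_up_properties(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-15)  # adjusted >= raw
        assert np.all(adj <= 1.0)
        # order invariance
        perm = np.random.default_rng(0).permutation(len(p))
        assert bh_adjust(np.asarray(p)[perm]) == pytest.approx(adj[perm], abs=1e-15)
        # monotone in ranks: sorting p sorts the adjusted values
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)
        # independent step-up enumeration agrees
        assert adj == pytest.approx(bh_step_up(p), abs=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [math.nan]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestFitStatistics:
    def _fit(self):
        rng = np.random.default_rng(6)
        n = 200
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-1.0 + 0.7 * x)).astype(int)
        return fit_logistic(pd.DataFrame({"y": y, "x": x}), spec_of(cont("x")))

    def test_aic_identity(self):
        res = self._fit()
        assert res.aic == pytest.approx(-2 * res.log_likelihood + 2 * res.n_params, abs=1e-9)
        assert res.bic == pytest.approx(
            -2 * res.log_likelihood + math.log(res.n_obs) * res.n_params, abs=1e-9
        )

    def test_deviance_never_exceeds_null_deviance(self):
        res = self._fit()
        assert res.deviance <= res.null_deviance + 1e-9

    def test_intercept_only_mcfadden_is_nonpositive(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"y": rng.integers(0, 2, 100)})
        res = fit_logistic(df, spec_of())
        assert res.mcfadden_adjusted_r2 <= 1e-12

    def test_stats_accessor(self):
        res = self._fit()
        stats = model_fit_stats(res)
        assert stats["AIC"] == res.aic and stats["BIC"] == res.bic
        assert stats["mcfadden_adjusted_r2"] == res.mcfadden_adjusted_r2


class TestBackwardStepwise:
    def test_noise_term_dropped_strong_term_kept(self):
        kept_strong = 0
        dropped_noise = 0
        runs = 100
        for seed in range(runs):
            rng = np.random.default_rng(seed)
            n = 1000
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            y = (rng.random(n) < expit(-1.0 + 1.2 * x)).astype(int)
            df = pd.DataFrame({"y": y, "x": x, "noise": noise})
            final, _ = backward_stepwise_aic(df, spec_of(cont("x"), cont("noise")))
            if "x" in final.term_names:
                kept_strong += 1
            if "noise" not in final.term_names:
                dropped_noise += 1
        assert kept_strong >= 0.8 * runs
        assert dropped_noise >= 0.8 * runs

    def test_single_informative_term_retained(self):
        rng = np.random.default_rng(8)
        n = 600
        x = rng.normal(size=n)
        y = (rng.random(n) < expit(-0.5 + 1.5 * x)).astype(int)
        final, trace = backward_stepwise_aic(pd.DataFrame({"y": y, "x": x}), spec_of(cont("x")))
        assert final.term_names == ["x"]
        assert trace == [{"step": 0, "dropped": None, "aic": pytest.approx(final.aic)}]

    def test_final_aic_never_worse_and_trace_decreasing(self):
        rng = np.random.default_rng(9)
        n = 400
        df = pd.DataFrame(
            {
                "y": rng.integers(0, 2, n),
                "a": rng.normal(size=n),
                "b": rng.normal(size=n),
                "c": rng.normal(size=n),
            }
        )
        spec = spec_of(cont("a"), cont("b"), cont("c"))
        full = fit_logistic(df, spec)
        final, trace = backward_stepwise_aic(df, spec)
        assert final.aic <= full.aic + 1e-9
        aics = [t["aic"] for t in trace]
        assert all(b < a for a, b in zip(aics, aics[1:]))

    def test_categorical_block_dropped_whole(self):
        rng = np.random.default_rng(10)
        n = 500
        x = rng.normal(size=n)
        group = rng.choice(["a", "b", "c"], n)  # pure noise, 2 columns
        y = (rng.random(n) < expit(-0.5 + 1.3 * x)).astype(int)
        df = pd.DataFrame({"y": y, "x": x, "group": group})
        final, _ = backward_stepwise_aic(
            df,
            spec_of(cont("x"), Term("group", "categorical", reference="a", levels=("b", "c"))),
        )
        if "group" not in final.term_names:
            assert not any(col.startswith("group[") for col in final.table["column"])


class TestLogitLinearity:
    def test_null_linear_logit_rarely_rejected(self):
        rejections = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(100 + seed)
            n = 800
            x = rng.uniform(1.0, 10.0, n)
            y = (rng.random(n) < expit(-2.0 + 0.4 * x)).astype(int)
            diag = check_logit_linearity(pd.DataFrame({"closed_by_followup": y, "x": x}), "x")
            if not diag.passed:
                rejections += 1
        assert rejections <= 0.1 * runs + 1  # type-I band around alpha=0.05

    def test_quadratic_logit_detected(self):
        rejections = 0
        runs = 20
        for seed in range(runs):
            rng = np.random.default_rng(200 + seed)
            n = 2000
            x = rng.uniform(0.5, 6.0, n)
            y = (rng.random(n) < expit(0.9 * (x - 3.0) ** 2 - 2.5)).astype(int)  # U-shaped logit
            diag = check_logit_linearity(pd.DataFrame({"closed_by_followup": y, "x": x}), "x")
            if not diag.passed:
                rejections += 1
        assert rejections >= 0.9 * runs

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame({"closed_by_followup": [0, 1] * 20, "x": [2.0] * 40})
        with pytest.raises(ValueError, match="distinct values"):
            check_logit_linearity(df, "x")

    def test_nonpositive_values_shift_documented(self):
        rng = np.random.default_rng(11)
        n = 600
        x = rng.uniform(-3.0, 8.0, n)
        y = (rng.random(n) < expit(0.2 * x)).astype(int)
        diag = check_logit_linearity(pd.DataFrame({"closed_by_followup": y, "x": x}), "x")
        assert diag.shift == pytest.approx(1.0 - x.min())


class TestLowess:
    def _cohort(self, x, y, ped=None):
        return pd.DataFrame(
            {
                "live_births": x,
                "closed_by_followup": y,
                "has_pediatrics": ped if ped is not None else [False] * len(x),
            }
        )

    def test_all_zero_outcome_gives_zero_curve(self):
        x = np.linspace(10, 1000, 60)
        curves = lowess_curve(self._cohort(x, np.zeros(60)), stratify_by_pediatrics=False)
        assert np.allclose(curves["all"].y, 0.0, atol=1e-12)

    def test_step_function_plateaus_recovered(self):
        rng = np.random.default_rng(12)
        x = np.sort(rng.uniform(0, 100, 800))
        y = (x > 50).astype(float)  # step with wide plateaus
        curves = lowess_curve(
            self._cohort(x, y), stratify_by_pediatrics=False, span=0.2,
            grid=np.linspace(5, 95, 50),
        )
        c = curves["all"]
        far_low = c.x < 30
        far_high = c.x > 70
        assert np.all(np.abs(c.y[far_low] - 0.0) < 0.05)
        assert np.all(np.abs(c.y[far_high] - 1.0) < 0.05)

    def test_stratified_curves_and_small_stratum_skipped(self):
        rng = np.random.default_rng(13)
        n = 120
        x = rng.uniform(50, 2000, n)
        ped = np.array([True] * 10 + [False] * (n - 10))  # pediatrics stratum too small
        y = rng.integers(0, 2, n).astype(float)
        with pytest.warns(UserWarning, match="pediatrics"):
            curves = lowess_curve(self._cohort(x, y, ped))
        assert set(curves) == {"no_pediatrics"}

    def test_deterministic(self):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 1000, 300)
        y = rng.integers(0, 2, 300).astype(float)
        a = lowess_curve(self._cohort(x, y), stratify_by_pediatrics=False)
        b = lowess_curve(self._cohort(x, y), stratify_by_pediatrics=False)
        assert np.array_equal(a["all"].y, b["all"].y)
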
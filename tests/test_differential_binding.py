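import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from pbmkit.differential_binding import (
    DesignSpec,
    ModerationModel,
    bh_adjust,
    differential_pipeline,
    fit_group_model,
    moderate_variances,
    moderated_t_test,
    select_bound,
    select_differential,
)
from pbmkit.errors import ContractError


def _matrix(values, ids=None, slides=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    ids = ids or [f"seq{i}" for i in range(values.shape[0])]
    slides = slides or [f"sl{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=ids, columns=slides)


class TestFitGroupModel:
    def test_one_group_constant(self):
        fit = fit_group_model(_matrix([[1.0, 1.0, 1.0]]), DesignSpec(groups=("g",) * 3))
        row = fit.iloc[0]
        assert row["effect"] == 1.0
        assert row["s2"] == 0.0
        assert row["df"] == 2.0

    def test_two_group_difference(self):
        design = DesignSpec(groups=("a", "a", "b", "b"), contrast=("a", "b"))
        fit = fit_group_model(_matrix([[2.0, 2.0, 1.0, 1.0]]), design)
        row = fit.iloc[0]
        assert row["effect"] == 1.0
        assert row["s2"] == 0.0
        assert row["df"] == 2.0

    def test_matches_closed_form_ols_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 8))
        design = DesignSpec(groups=("a",) * 4 + ("b",) * 4, contrast=("a", "b"))
        fit = fit_group_model(_matrix(X), design)
        for i in range(50):
            g1, g2 = X[i, :4], X[i, 4:]
            assert fit["effect"].iloc[i] == pytest.approx(g1.mean() - g2.mean())
            pooled = (3 * g1.var(ddof=1) + 3 * g2.var(ddof=1)) / 6
            assert fit["s2"].iloc[i] == pytest.approx(pooled)

    def test_single_slide_group_rejected(self):
        design = DesignSpec(groups=("a", "a", "b"), contrast=("a", "b"))
        with pytest.raises(ContractError):
            fit_group_model(_matrix([[1.0, 2.0, 3.0]]), design)


def _f_marginal_mle(s2, df):
    """Numerical MLE of (d0, s0_sq) under s2/s0_sq ~ F(df, d0)."""

    def nll(theta):
        log_d0, log_s0 = theta
        d0, s0 = np.exp(log_d0), np.exp(log_s0)
        return -np.sum(stats.f.logpdf(s2 / s0, df, d0) - np.log(s0))

    res = optimize.minimize(nll, x0=[np.log(4.0), np.log(0.25)], method="Nelder-Mead")
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


class TestModerateVariances:
    def test_all_equal_is_degenerate_full_shrinkage(self):
        model, post = moderate_variances(np.full(100, 4.0), df=3)
        assert np.isinf(model.d0)
        assert model.s0_sq == pytest.approx(4.0)
        np.testing.assert_allclose(post, 4.0)
        assert "degenerate" in model.method

    def test_prior_df_zero_disables_moderation(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(3, 200) / 3
        model, post = moderate_variances(s2, df=3, prior_df=0)
        assert model.d0 == 0.0
        np.testing.assert_array_equal(post, s2)

    def test_posterior_between_prior_and_sample(self):
        rng = np.random.default_rng(2)
        s2 = 0.25 * rng.chisquare(4, 500) / 4
        model, post = moderate_variances(s2, df=4)
        lo = np.minimum(s2, model.s0_sq)
        hi = np.maximum(s2, model.s0_sq)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_hyperparameter_recovery_vs_truth_and_mle(self):
        """Moment matching recovers (d0, s0^2) from hierarchical draws; the
        numerical MLE on the same draws serves as the independent oracle."""
        rng = np.random.default_rng(3)
        d0_true, s0_true, df, n = 4.0, 0.25, 6, 5000
        sigma2 = s0_true * d0_true / rng.chisquare(d0_true, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        model, _ = moderate_variances(s2, df=df)
        assert model.d0 == pytest.approx(d0_true, rel=0.25)
        assert model.s0_sq == pytest.approx(s0_true, rel=0.10)
        d0_mle, s0_mle = _f_marginal_mle(s2, df)
        assert model.d0 == pytest.approx(d0_mle, rel=0.25)
        assert model.s0_sq == pytest.approx(s0_mle, rel=0.10)


class TestModeratedT:
    def test_zero_effect_gives_p_one(self):
        fit = pd.DataFrame(
            {"effect": [0.0], "A": [0.0], "s2": [1.0], "df": [3.0], "c": [0.5]}
        )
        out = moderated_t_test(fit, ModerationModel(d0=4.0, s0_sq=1.0))
        assert out["t_mod"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_zero_variance_zero_effect_gets_p_one_not_nan(self):
        fit = pd.DataFrame(
            {"effect": [0.0], "A": [0.0], "s2": [0.0], "df": [3.0], "c": [0.5]}
        )
        out = moderated_t_test(fit, ModerationModel(d0=0.0, s0_sq=1.0))
        assert out["p"].iloc[0] == 1.0

    def test_d0_zero_reduces_to_classical_t(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 8))
        design = DesignSpec(groups=("a",) * 4 + ("b",) * 4, contrast=("a", "b"))
        records = differential_pipeline(_matrix(X), design, prior_df=0)
        classical = stats.ttest_ind(X[:, :4], X[:, 4:], axis=1).pvalue
        np.testing.assert_allclose(records["p"].to_numpy(), classical, atol=1e-12)

    def test_t_monotone_decreasing_in_s2(self):
        fit = pd.DataFrame(
            {
                "effect": [1.0, 1.0, 1.0],
                "A": [0.0] * 3,
                "s2": [0.5, 1.0, 2.0],
                "df": [3.0] * 3,
                "c": [0.5] * 3,
            }
        )
        out = moderated_t_test(fit, ModerationModel(d0=2.0, s0_sq=1.0))
        t = out["t_mod"].to_numpy()
        assert t[0] > t[1] > t[2]

    def test_null_type_i_error_calibrated(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.3, size=(2000, 8))
        design = DesignSpec(groups=("a",) * 4 + ("b",) * 4, contrast=("a", "b"))
        records = differential_pipeline(_matrix(X), design)
        frac = (records["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07
        ks = stats.kstest(records["p"], "uniform")
        assert ks.pvalue > 0.01
        assert (records["q"] < 0.05).sum() <= 2


class TestBhAdjust:
    def test_step_up_oracle(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.5])), [0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ContractError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30)
    )
    def test_bounds_and_order_preserved(self, p_list):
        p = np.array(p_list)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all() and (q <= 1.0 + 1e-15).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestSelection:
    def _records(self, effect, p, q=None):
        n = len(effect)
        return pd.DataFrame(
            {
                "effect": effect,
                "A": np.zeros(n),
                "p": p,
                "q": q if q is not None else p,
            },
            index=[f"seq{i}" for i in range(n)],
        )

    def test_all_insignificant_selects_nothing(self):
        records = self._records([2.0, 3.0], [1.0, 1.0])
        assert select_bound(records) == set()

    def test_significant_positive_effect_selected(self):
        records = self._records([2.0, -2.0], [0.001, 0.001])
        assert select_bound(records, alpha=0.05) == {"seq0"}

    def test_differential_cutoff_rule(self):
        records = self._records([0.5, 1.2, -1.5], [0.001] * 3)
        selected, fold_only = select_differential(records, m_cutoff=1.0, alpha=0.05)
        assert selected == {"seq1", "seq2"}
        assert fold_only == {"seq1", "seq2"}

    def test_zero_effects_select_nothing(self):
        records = self._records([0.0, 0.0], [0.001, 0.001])
        selected, fold_only = select_differential(records)
        assert selected == set() and fold_only == set()

    def test_monotone_in_effect_size(self):
        records = self._records([1.1, 1.5], [0.01, 0.01])
        before, _ = select_differential(records)
        records.loc["seq0", "effect"] = 2.0
        after, _ = select_differential(records)
        assert before <= after
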
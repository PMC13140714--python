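"""Linear fits, empirical-Bayes moderation, moderated t, BH, B-statistic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betacross import diffmeth
from betacross.diffmeth import (
    DesignError,
    ModerationError,
    ModerationParams,
    adjust_bh,
    b_statistic,
    estimate_moderation,
    fit_linear,
    moderated_t,
    posterior_s2,
)
from conftest import make_matrix, make_sheet


class TestFitLinear:
    def test_constant_groups_give_exact_logfc_and_zero_variance(self):
        m, sheet = make_matrix({"p": [0.0, 0.0, 1.0, 1.0]}, 2, 2)
        fits = fit_linear(m, sheet)
        assert fits.loc["p", "logFC"] == 1.0
        assert fits.loc["p", "s2"] == 0.0
        assert fits.loc["p", "df_residual"] == 2
        assert fits.loc["p", "stdev_unscaled"] == pytest.approx(1.0)

    def test_pooled_variance_hand_example(self):
        # control {1, -1}, case {2, 0}: each group variance 2 -> pooled 2
        m, sheet = make_matrix({"p": [1.0, -1.0, 2.0, 0.0]}, 2, 2)
        fits = fit_linear(m, sheet)
        assert fits.loc["p", "logFC"] == pytest.approx(1.0)
        assert fits.loc["p", "s2"] == pytest.approx(2.0)
        assert fits.loc["p", "df_residual"] == 2

    def test_swapping_group_labels_negates_logfc(self):
        m, sheet = make_matrix({"p": [0.1, 0.4, 0.9, 0.3], "q": [1, 2, 3, 4.0]}, 2, 2)
        swapped = sheet.copy()
        swapped["group"] = list(sheet["group"][::-1])
        f1 = fit_linear(m, sheet)
        f2 = fit_linear(m, swapped)
        assert np.allclose(f1["logFC"], -f2["logFC"])
        assert np.allclose(f1["s2"], f2["s2"])

    def test_probes_with_sparse_groups_excluded(self):
        m, sheet = make_matrix(
            {"ok": [0.1, 0.2, 0.3, 0.4, 0.5, 0.6], "thin": [0.1, np.nan, np.nan, 0.4, 0.5, 0.6]},
            3,
            3,
        )
        fits = fit_linear(m, sheet)
        assert list(fits.index) == ["ok"]

    def test_missing_aware_counts(self):
        m, sheet = make_matrix({"p": [0.1, 0.2, np.nan, 0.4, 0.5, 0.6]}, 3, 3)
        fits = fit_linear(m, sheet)
        assert fits.loc["p", "df_residual"] == 3
        assert fits.loc["p", "stdev_unscaled"] == pytest.approx(math.sqrt(1 / 2 + 1 / 3))

    def test_absent_group_raises(self):
        m, sheet = make_matrix({"p": [0.1, 0.2, 0.3, 0.4]}, 4, 0)
        with pytest.raises(DesignError, match="Periodontitis"):
            fit_linear(m, sheet)


def _fits_frame(s2, df=10, logfc=None):
    s2 = np.asarray(s2, float)
    return pd.DataFrame(
        {
            "s2": s2,
            "df_residual": df,
            "logFC": np.zeros_like(s2) if logfc is None else logfc,
            "stdev_unscaled": 1.0,
        }
    )


class TestModeration:
    def test_identical_variances_give_infinite_prior_df(self):
        fits = _fits_frame([2.0] * 100)
        params = estimate_moderation(fits)
        assert math.isinf(params.d0)
        assert params.s0_squared == pytest.approx(2.0)

    def test_recovers_planted_prior_from_scaled_model(self):
        rng = np.random.default_rng(0)
        d0, s0, df, n = 4.0, 1.0, 10, 50_000
        sigma2 = s0 * d0 / rng.chisquare(d0, n)
        s2 = sigma2 * rng.chisquare(df, n) / df
        params = estimate_moderation(_fits_frame(s2, df=df))
        assert params.d0 == pytest.approx(d0, rel=0.15)
        assert params.s0_squared == pytest.approx(s0, rel=0.05)

    def test_posterior_variance_is_convex_combination(self):
        rng = np.random.default_rng(1)
        s2 = rng.chisquare(8, 500) / 8
        fits = _fits_frame(s2, df=8)
        params = estimate_moderation(fits)
        post = posterior_s2(fits, params)
        lo = np.minimum(s2, params.s0_squared)
        hi = np.maximum(s2, params.s0_squared)
        assert ((post >= lo - 1e-12) & (post <= hi + 1e-12)).all()

    def test_all_zero_variances_raise_with_guidance(self):
        with pytest.raises(ModerationError, match="zero"):
            estimate_moderation(_fits_frame([0.0] * 10))


class TestModeratedT:
    def test_zero_logfc_gives_t_zero_p_one(self):
        fits = _fits_frame([1.0, 2.0], logfc=[0.0, 0.0])
        out = moderated_t(fits, ModerationParams(d0=4.0, s0_squared=1.0))
        assert (out["t"] == 0).all()
        assert (out["p"] == 1).all()

    def test_small_prior_df_limit_equals_ordinary_pooled_t(self):
        m, sheet = make_matrix({"p": [0.1, 0.5, 0.2, 0.9, 1.1, 0.7]}, 3, 3)
        fits = fit_linear(m, sheet)
        out = moderated_t(fits, ModerationParams(d0=1e-12, s0_squared=5.0))
        from scipy import stats

        ctrl, case = [0.1, 0.5, 0.2], [0.9, 1.1, 0.7]
        expected = stats.ttest_ind(case, ctrl, equal_var=True)
        assert out.loc["p", "t"] == pytest.approx(expected.statistic, rel=1e-6)

    def test_infinite_prior_df_refers_to_normal(self):
        fits = _fits_frame([1.0], logfc=[2.0])
        out = moderated_t(fits, ModerationParams(d0=math.inf, s0_squared=1.0))
        from scipy import stats

        assert out["t"].iloc[0] == pytest.approx(2.0)
        assert out["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(2.0))

    def test_null_type_i_error_calibrated(self):
        """Moderated-t p-values are uniform enough under the null: the
        rejection rate at 0.05 stays near nominal (small-scale version of the
        pooled calibration check)."""
        rng = np.random.default_rng(7)
        n, n1 = 5000, 10
        m = pd.DataFrame(
            rng.normal(size=(n, 2 * n1)),
            index=[f"p{i}" for i in range(n)],
            columns=[f"s{i}" for i in range(2 * n1)],
        )
        sheet = make_sheet(n1, n1)
        sheet["sample_id"] = list(m.columns)
        fits = fit_linear(m, sheet)
        out = moderated_t(fits, estimate_moderation(fits))
        rate = (out["p"] < 0.05).mean()
        assert 0.04 < rate < 0.06


class TestAdjustBH:
    def test_hand_computed_step_up(self):
        assert np.allclose(adjust_bh([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @pytest.mark.parametrize("p,expected", [([0.2], [0.2]), ([1.0, 1.0, 1.0], [1.0] * 3)])
    def test_degenerate_inputs(self, p, expected):
        assert np.allclose(adjust_bh(p), expected)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        p = rng.uniform(size=500)
        _, ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adjust_bh(p), ref)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance_and_bounds(self, p):
        p = np.array(p)
        q = adjust_bh(p)
        assert ((q >= p - 1e-12) & (q <= 1.0)).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(adjust_bh(p[perm]), q[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_bh([0.5, 1.2])


class TestBStatistic:
    def _params(self):
        return ModerationParams(d0=4.0, s0_squared=1.0, b_proportion=0.01, var_prior_fc=4.0)

    def test_even_in_t_and_minimal_at_zero(self):
        fits = _fits_frame([1.0] * 3, df=20, logfc=[-2.0, 0.0, 2.0])
        b = b_statistic(fits, self._params())
        assert b.iloc[0] == pytest.approx(b.iloc[2], rel=1e-12)
        assert b.iloc[1] < b.iloc[0]

    def test_large_t_gives_positive_log_odds(self):
        # |t| = 10 at df 20: differential odds must dominate the 1% prior
        fits = _fits_frame([1.0], df=20, logfc=[10.0 * math.sqrt((4 * 1 + 20 * 1) / 24)])
        b = b_statistic(fits, self._params())
        assert b.iloc[0] > 0

    def test_monotone_in_absolute_t(self):
        logfc = np.linspace(0, 5, 11)
        fits = _fits_frame([1.0] * 11, df=20, logfc=logfc)
        b = b_statistic(fits, self._params())
        assert (np.diff(b.to_numpy()) > 0).all()


def test_realized_fdr_controlled_on_planted_data():
    """At effect 2 with n = 30 + 30, the realized FDR of adj.P < 0.05 calls
    stays at or below about twice the nominal level across seeds."""
    from betacross import preprocess, synthetic
    from betacross.config import SimulationConfig

    fdrs = []
    for seed in range(10):
        cfg = SimulationConfig(n_probes=2000, n_control=30, n_case=30, seed=seed)
        man = synthetic.generate_manifest(cfg)
        beta, sheet, truth = synthetic.generate_beta(man, cfg)
        m = preprocess.beta_to_m(preprocess.filter_missing(beta)[0])
        dmps = diffmeth.run_dmp(m, sheet)
        truth = truth.set_index("probe_id")
        called = dmps.loc[dmps["significant"], "probe_id"]
        false = (~truth.loc[called, "is_dmp"]).sum()
        fdrs.append(false / max(len(called), 1))
    assert np.mean(fdrs) <= 0.10
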
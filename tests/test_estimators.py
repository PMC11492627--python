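"""GLS IVW/Egger fits, influence pruning, model selection, reporting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import mrtriangle as mt
from mrtriangle.estimators import EGGER, IVW, Z_95


def make_instrument_set(beta_x, beta_y, se_y, ld=None, outcome_type="binary"):
    n = len(beta_x)
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{i:03d}" for i in range(n)],
            "chromosome": "1",
            "position": np.arange(n) * 1000,
            "beta_exposure": beta_x,
            "se_exposure": 0.01,
            "p_value_exposure": 1e-10,
            "beta_outcome": beta_y,
            "se_outcome": se_y,
        }
    )
    return mt.InstrumentSet(
        variants=variants,
        ld=np.eye(n) if ld is None else ld,
        outcome_type=outcome_type,
    )


def random_instance(seed, n=8):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0.05, 0.4, n) * rng.choice([-1, 1], n)
    se = rng.uniform(0.01, 0.05, n)
    ld = mt.simulate_ld_matrix(n, block_size=4, rho=0.6).to_numpy()
    y = 0.5 * x + se * rng.standard_normal(n)
    return x, y, se, ld


def brute_force_gls(x, y, se, ld, with_intercept, ridge=1e-8):
    """Normal equations by explicit matrix inversion (independent route)."""
    n = len(x)
    omega = np.diag(se) @ (ld + ridge * np.eye(n)) @ np.diag(se)
    W = np.linalg.inv(omega)
    X = np.column_stack([np.ones(n), x]) if with_intercept else x[:, None]
    cov = np.linalg.inv(X.T @ W @ X)
    theta = cov @ X.T @ W @ y
    resid = y - X @ theta
    q = float(resid @ W @ resid)
    return theta, np.sqrt(np.diag(cov)), q


class TestGLSFit:
    def test_exact_linear_data_recovers_slope_with_zero_q(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        instr = make_instrument_set(x, 2 * x, np.full(4, 0.05))
        fit = mt.fit_gls(instr)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.q_statistic == pytest.approx(0.0, abs=1e-18)
        assert fit.df == 3

    def test_exact_affine_data_recovers_intercept_and_slope(self):
        x = np.array([0.1, 0.2, 0.3, 0.4])
        instr = make_instrument_set(x, 0.1 + 2 * x, np.full(4, 0.05))
        fit = mt.fit_gls(instr, with_intercept=True)
        assert fit.intercept == pytest.approx(0.1, abs=1e-12)
        assert fit.slope == pytest.approx(2.0, abs=1e-12)
        assert fit.q_statistic == pytest.approx(0.0, abs=1e-18)
        assert fit.df == 2

    @pytest.mark.parametrize("with_intercept", [False, True])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_normal_equations(self, seed, with_intercept):
        x, y, se, ld = random_instance(seed)
        fit = mt.fit_gls(make_instrument_set(x, y, se, ld), with_intercept)
        theta, ses, q = brute_force_gls(x, y, se, ld, with_intercept)
        slope_idx = 1 if with_intercept else 0
        assert fit.slope == pytest.approx(theta[slope_idx], rel=1e-10)
        assert fit.slope_se == pytest.approx(ses[slope_idx], rel=1e-10)
        assert fit.q_statistic == pytest.approx(q, rel=1e-8)

    def test_identity_ld_equals_textbook_ivw(self):
        x, y, se, _ = random_instance(4)
        fit = mt.fit_gls(make_instrument_set(x, y, se), ridge=0.0)
        w = 1.0 / se**2
        assert fit.slope == pytest.approx(np.sum(w * x * y) / np.sum(w * x**2), rel=1e-10)
        assert fit.slope_se == pytest.approx(1.0 / np.sqrt(np.sum(w * x**2)), rel=1e-10)

    def test_leverage_and_outlier_decompositions(self):
        x, y, se, ld = random_instance(5)
        for with_intercept, n_params in ((False, 1), (True, 2)):
            fit = mt.fit_gls(make_instrument_set(x, y, se, ld), with_intercept)
            assert fit.leverage.sum() == pytest.approx(n_params, rel=1e-10)
            assert ((fit.leverage >= -1e-12) & (fit.leverage <= 1 + 1e-12)).all()
            assert fit.outlier_stats.sum() == pytest.approx(fit.q_statistic, rel=1e-10)

    def test_singular_ld_fails_loudly(self):
        ld = np.ones((4, 4))  # rank one even after the default ridge? no: ridge fixes it
        x = np.array([0.1, 0.2, 0.3, 0.4])
        instr = make_instrument_set(x, 2 * x, np.full(4, 0.05), ld)
        with pytest.raises(mt.IllConditionedLDError):
            mt.fit_gls(instr, ridge=-1e-3)  # force a non-PD covariance

    def test_too_few_variants_rejected(self):
        x = np.array([0.1, 0.2])
        instr = make_instrument_set(x, 2 * x, np.full(2, 0.05))
        with pytest.raises(ValueError):
            mt.fit_gls(instr, with_intercept=True)

    @given(st.integers(min_value=0, max_value=40))
    def test_sign_equivariance(self, seed):
        """Negating exposure betas negates the slope and leaves |slope|/se,
        Q, leverage and outlier statistics unchanged."""
        x, y, se, ld = random_instance(seed)
        a = mt.fit_gls(make_instrument_set(x, y, se, ld))
        b = mt.fit_gls(make_instrument_set(-x, y, se, ld))
        assert b.slope == pytest.approx(-a.slope, rel=1e-10)
        assert b.slope_se == pytest.approx(a.slope_se, rel=1e-10)
        assert b.q_statistic == pytest.approx(a.q_statistic, rel=1e-10)
        np.testing.assert_allclose(b.leverage, a.leverage, rtol=1e-10)
        np.testing.assert_allclose(b.outlier_stats, a.outlier_stats, rtol=1e-8)

    @given(st.integers(min_value=0, max_value=40))
    def test_q_ivw_dominates_q_egger(self, seed):
        """Adding the Egger intercept can only reduce heterogeneity."""
        x, y, se, ld = random_instance(seed)
        instr = make_instrument_set(x, y, se, ld)
        q_ivw = mt.fit_gls(instr).q_statistic
        q_egger = mt.fit_gls(instr, with_intercept=True).q_statistic
        assert q_ivw >= q_egger - 1e-9


class TestSklearnSurface:
    def test_estimator_params_and_predict(self):
        x, y, se, ld = random_instance(3)
        est = mt.IVWEstimator(ridge=1e-8)
        assert est.get_params() == {"ridge": 1e-8}
        est.fit(x[:, None], y, outcome_se=se, ld=ld)
        assert est.slope_ == pytest.approx(est.coef_[0])
        np.testing.assert_allclose(est.predict(x[:, None]), x * est.slope_)
        egger = mt.EggerEstimator().fit(x[:, None], y, outcome_se=se, ld=ld)
        assert egger.intercept_se_ > 0

    def test_clone_compatible(self):
        from sklearn.base import clone

        est = clone(mt.EggerEstimator(ridge=1e-6))
        assert est.ridge == 1e-6
        assert est.fit_intercept is True


class TestPruning:
    def test_clean_balanced_design_removes_nothing(self):
        x = np.array([0.1, -0.1, 0.1, -0.1, 0.1, -0.1])
        instr = make_instrument_set(x, 2 * x, np.full(6, 0.05))
        fit = mt.fit_gls(instr)
        pruned = mt.prune_variants(instr, fit)
        assert pruned.n_variants == 6

    def test_constructed_outlier_removed(self):
        x = np.full(8, 0.2)
        y = 2 * x.copy()
        se = np.full(8, 0.05)
        y[3] += 5 * se[3]  # standardised squared residual around 25 > 10.83
        instr = make_instrument_set(x, y, se)
        fit = mt.fit_gls(instr)
        assert fit.outlier_stats[3] > 10.83
        pruned = mt.prune_variants(instr, fit)
        assert "v003" not in pruned.variant_ids

    def test_high_leverage_variant_removed(self):
        x = np.array([0.1] * 7 + [1.0])  # one exposure beta 10x the others
        rngy = np.random.default_rng(0)
        y = 2 * x + 0.01 * rngy.standard_normal(8)
        instr = make_instrument_set(x, y, np.full(8, 0.05))
        fit = mt.fit_gls(instr)
        # oracle hat diagonal for weighted regression through the origin
        hat = x**2 / np.sum(x**2)
        np.testing.assert_allclose(fit.leverage, hat, rtol=1e-8)
        assert hat[7] > 3 * hat.mean()
        pruned = mt.prune_variants(instr, fit)
        assert "v007" not in pruned.variant_ids


class TestRuckerSelection:
    def make_fit(self, q):
        return mt.MRFit(
            estimator=IVW, slope=0.1, slope_se=0.05, intercept=0.0, intercept_se=0.0,
            q_statistic=q, df=5, n_variants_used=6,
            leverage=np.zeros(6), outlier_stats=np.zeros(6),
        )

    @pytest.mark.parametrize(
        "q_ivw, q_egger, expected",
        [(12.0, 12.0, IVW), (20.0, 10.0, EGGER), (13.0, 10.0, IVW)],
    )
    def test_q_difference_rule(self, q_ivw, q_egger, expected):
        assert mt.rucker_select(self.make_fit(q_ivw), self.make_fit(q_egger)) == expected

    def test_threshold_is_chi2_quantile(self):
        crit = stats.chi2.ppf(0.95, 1)  # 3.841
        assert mt.rucker_select(self.make_fit(10 + crit + 0.01), self.make_fit(10.0)) == EGGER
        assert mt.rucker_select(self.make_fit(10 + crit - 0.01), self.make_fit(10.0)) == IVW

    def test_inconsistent_fits_raise(self):
        with pytest.raises(ValueError):
            mt.rucker_select(self.make_fit(5.0), self.make_fit(9.0))


class TestReportedEffect:
    def test_null_slope_gives_unit_or(self):
        est, lo, hi = mt.to_reported_effect(0.0, 0.1, "binary")
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    @pytest.mark.parametrize(
        "slope, se, expected",
        [
            (0.412, 0.0855, (1.51, 1.28, 1.79)),
            (-0.734, 0.117, (0.48, 0.38, 0.60)),
        ],
    )
    def test_printed_interval_round_trips(self, slope, se, expected):
        est, lo, hi = mt.to_reported_effect(slope, se, "binary")
        assert (round(est, 2), round(lo, 2), round(hi, 2)) == expected

    def test_continuous_outcomes_stay_on_identity_scale(self):
        est, lo, hi = mt.to_reported_effect(0.3, 0.1, "continuous")
        assert (est, lo, hi) == (0.3, 0.3 - Z_95 * 0.1, 0.3 + Z_95 * 0.1)

    def test_rejects_nonpositive_se(self):
        with pytest.raises(ValueError):
            mt.to_reported_effect(0.3, 0.0, "binary")


class TestRunMR:
    def test_fewer_than_six_variants_is_discarded(self):
        cfg = mt.SimConfig(n_variants=5, flip_fraction=0.0, seed=9)
        exp, out, ld, _ = mt.simulate_mr_dataset(cfg)
        res = mt.run_mr(exp, out, ld, f_min=0.0, maf_min=0.0)
        assert res.chosen_estimator == "discarded"
        assert np.isnan(res.estimate)

    def test_strong_signal_recovers_causal_slope(self):
        cfg = mt.SimConfig(
            n_variants=80, causal_effect=0.3, n_outcome=10**7, seed=21
        )
        exp, out, ld, _ = mt.simulate_mr_dataset(cfg)
        res = mt.run_mr(exp, out, ld, exposure_id="m", outcome_id="o")
        assert res.chosen_estimator in (IVW, EGGER)
        assert res.slope == pytest.approx(0.3, abs=0.02)
        assert res.ci_lower <= res.estimate <= res.ci_upper
        assert res.p_value < 1e-10

    def test_stage_counts_are_monotone(self):
        cfg = mt.SimConfig(n_variants=60, seed=2)
        exp, out, ld, _ = mt.simulate_mr_dataset(cfg)
        res = mt.run_mr(exp, out, ld)
        c = res.stage_counts
        assert c["input"] >= c["filtered"] >= c["harmonised"] >= c["clumped"] >= c["pruned"]

    def test_results_frame_schema(self):
        cfg = mt.SimConfig(n_variants=30, seed=4)
        exp, out, ld, _ = mt.simulate_mr_dataset(cfg)
        frame = mt.results_to_frame([mt.run_mr(exp, out, ld)])
        assert list(frame["exposure"]) == ["exposure"]
        assert {"slope", "q_ivw", "q_egger", "excluded_leverage"} <= set(frame.columns)
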
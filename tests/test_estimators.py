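"""MR estimators: IVW, MR-Egger, weighted medians, 2SLS, mediation."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from matmr import (
    SimulationConfig,
    draw_truth,
    exclude_and_reestimate,
    ivw,
    leave_one_out,
    mediation_expectation,
    mr_egger,
    penalized_weighted_median,
    sd_unit_conversion,
    simulate_summary_instruments,
    tsls,
    weighted_median,
)
from matmr.exceptions import EstimationError, ParameterError, WeakInstrumentError

from conftest import B_SBP_TO_BW


def pairs_frame(bx, by, sy, sx=None):
    bx = np.asarray(bx, dtype=float)
    return pd.DataFrame(
        {
            "rsid": [f"rs{i}" for i in range(len(bx))],
            "beta_x": bx,
            "se_x": np.full(len(bx), 0.01) if sx is None else np.asarray(sx, float),
            "beta_y": np.asarray(by, dtype=float),
            "se_y": np.asarray(sy, dtype=float),
            "eaf": 0.3,
            "flags": "",
        }
    )


def random_instance(rng, j=None):
    j = j or int(rng.integers(3, 30))
    bx = rng.normal(0, 0.1, j)
    by = rng.normal(0, 1.0, j)
    sy = rng.uniform(0.2, 2.0, j)
    return pairs_frame(bx, by, sy, sx=rng.uniform(0.005, 0.02, j))


class TestIvw:
    def test_single_snp_reduces_to_ratio(self):
        est = ivw(pairs_frame([0.5], [1.0], [0.3]))
        assert est.beta == pytest.approx(2.0)

    def test_equal_weight_mean(self):
        est = ivw(pairs_frame([1.0, 1.0], [1.0, 3.0], [1.0, 1.0]))
        assert est.beta == pytest.approx(2.0)

    def test_fixed_effect_se_formula(self):
        p = pairs_frame([1.0, 2.0], [1.0, 3.0], [0.5, 0.25])
        est = ivw(p)
        denom = 1.0 / 0.5**2 + 4.0 / 0.25**2
        assert est.se == pytest.approx(denom**-0.5)
        assert est.ci_low == pytest.approx(est.beta - 1.96 * est.se)

    def test_matches_zero_intercept_wls_oracle(self, rng):
        """IVW equals a generic zero-intercept WLS fit of beta_y on beta_x
        with weights 1/se_y^2 (100 random instances, 1e-10 relative)."""
        for _ in range(100):
            p = random_instance(rng)
            oracle = sm.WLS(
                p["beta_y"], p[["beta_x"]], weights=1.0 / p["se_y"] ** 2
            ).fit()
            est = ivw(p)
            assert est.beta == pytest.approx(oracle.params.iloc[0], rel=1e-10)

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(EstimationError):
            ivw(pairs_frame([], [], []))
        with pytest.raises(EstimationError):
            ivw(pairs_frame([0.0, 0.0], [1.0, 1.0], [1.0, 1.0]))


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(pairs_frame(bx, 0.5 * bx, np.ones(4)))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.intercept == pytest.approx(0.0, abs=1e-10)

    def test_exact_affine_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(pairs_frame(bx, 0.5 * bx + 0.1, np.ones(4)))
        assert est.intercept == pytest.approx(0.1, abs=1e-10)
        assert est.beta == pytest.approx(0.5, abs=1e-10)

    def test_minimum_instruments_named(self):
        with pytest.raises(EstimationError, match="3"):
            mr_egger(pairs_frame([0.1, 0.2], [0.1, 0.2], [1.0, 1.0]))

    def test_matches_wls_with_intercept_oracle(self, rng):
        """On orientation-fixed inputs Egger equals generic WLS with
        intercept — point estimates and standard errors."""
        for _ in range(100):
            p = random_instance(rng)
            p["beta_x"] = np.abs(p["beta_x"])  # already oriented
            X = sm.add_constant(p["beta_x"])
            oracle = sm.WLS(p["beta_y"], X, weights=1.0 / p["se_y"] ** 2).fit()
            est = mr_egger(p)
            assert est.beta == pytest.approx(oracle.params["beta_x"], rel=1e-10)
            assert est.intercept == pytest.approx(oracle.params["const"], rel=1e-10)
            assert est.se == pytest.approx(oracle.bse["beta_x"], rel=1e-10)
            assert est.intercept_se == pytest.approx(oracle.bse["const"], rel=1e-10)

    def test_directional_pleiotropy_biases_ivw_not_egger(self):
        """Directional pleiotropy (positive direct effects on the
        exposure-raising allele, magnitudes independent of instrument
        strength — InSIDE) biases IVW, while the Egger slope stays centred
        on the causal truth.  Truth is redrawn per replicate; the exposure
        GWAS is made very large because Egger's consistency additionally
        assumes (near-)noiseless exposure betas — with noisy betas,
        orientation flips of weak instruments re-introduce a small bias."""
        cfg = SimulationConfig(
            n_duos=10, b_sbp_to_bw=B_SBP_TO_BW, seed=77,
        )
        rng = np.random.default_rng(cfg.seed)
        n_rep = 500
        ivw_b, egger_b = [], []
        for _ in range(n_rep):
            truth = draw_truth(cfg, rng)
            truth.pleio = np.sign(truth.w_sd) * rng.normal(1.5, 1.0, truth.n_snps)
            pairs = simulate_summary_instruments(
                truth, cfg, n_exposure=20_000_000, n_outcome=100_000, rng=rng
            )
            ivw_b.append(ivw(pairs).beta)
            egger_b.append(mr_egger(pairs).beta)
        causal = -12.0
        egger_err = np.mean(egger_b) - causal
        ivw_err = np.mean(ivw_b) - causal
        assert abs(egger_err) < 3 * np.std(egger_b) / np.sqrt(n_rep)
        assert abs(ivw_err) > 10.0  # IVW absorbs the directional bias


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        est = weighted_median(
            pairs_frame([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [1.0, 1.0, 1.0]),
            n_boot=10, seed=0,
        )
        assert est.beta == pytest.approx(2.0)

    def test_dominant_weight_snp_wins(self):
        # weights ~ bx^2/sy^2: make SNP 1 carry ~98% of the weight
        bx = np.array([1.0, 1.0, 1.0])
        sy = np.array([0.1, 1.0, 1.0])  # weights 100, 1, 1
        est = weighted_median(
            pairs_frame(bx, bx * np.array([1.0, 2.0, 3.0]), sy), n_boot=10, seed=0
        )
        assert est.beta == pytest.approx(1.0, abs=0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=3, max_size=15))
    def test_equal_weights_matches_numpy_median_oddn(self, ratios):
        """With all-equal weights and odd J the weighted median equals the
        sample median of the ratios."""
        if len(ratios) % 2 == 0:
            ratios = ratios[:-1]
        bx = np.ones(len(ratios))
        est = weighted_median(
            pairs_frame(bx, np.array(ratios), np.ones(len(ratios))),
            n_boot=5, seed=0,
        )
        assert est.beta == pytest.approx(np.median(ratios), abs=1e-9)

    def test_bootstrap_se_is_seeded(self):
        p = pairs_frame([0.1, 0.2, 0.3, 0.4], [0.2, 0.3, 0.5, 0.9],
                        [0.1, 0.1, 0.2, 0.2])
        a = weighted_median(p, n_boot=200, seed=5)
        b = weighted_median(p, n_boot=200, seed=5)
        c = weighted_median(p, n_boot=200, seed=6)
        assert a.se == b.se
        assert a.se != c.se

    def test_robust_to_minority_invalid_instruments(self):
        """With 40% of instruments carrying large directional direct effects
        the weighted median stays near the truth while IVW shifts."""
        cfg = SimulationConfig(
            n_duos=10, b_sbp_to_bw=B_SBP_TO_BW, pleiotropy_frac=0.4,
            pleiotropy_mean=6.0, pleiotropy_sd=1.0, seed=55,
        )
        rng = np.random.default_rng(cfg.seed)
        truth = draw_truth(cfg, rng)
        pairs = simulate_summary_instruments(
            truth, cfg, n_exposure=300_000, n_outcome=300_000, rng=rng
        )
        causal = -12.0
        wm = weighted_median(pairs, n_boot=300, seed=1)
        est_ivw = ivw(pairs)
        assert abs(wm.beta - causal) < 2 * wm.se
        assert abs(est_ivw.beta - causal) > 2 * est_ivw.se


class TestPenalizedWeightedMedian:
    def test_no_outliers_equals_weighted_median_exactly(self):
        p = pairs_frame([0.1, 0.2, 0.3, 0.4], [0.05, 0.11, 0.14, 0.21],
                        [0.5, 0.5, 0.5, 0.5])
        wm = weighted_median(p, n_boot=50, seed=3)
        pwm = penalized_weighted_median(p, n_boot=50, seed=3)
        assert pwm.beta == wm.beta

    def test_gross_outlier_downweighted(self):
        """9 concordant SNPs + 1 gross outlier: the penalized estimate moves
        toward the weighted median of the 9."""
        rng = np.random.default_rng(8)
        bx = rng.uniform(0.1, 0.3, 10)
        by = rng.uniform(0.45, 0.55, 10) * bx
        by[0] = 50.0 * bx[0]  # outlier ratio
        sy = np.full(10, 0.01)
        sy[0] = 0.004  # precise enough to drag the plain weighted median
        full = pairs_frame(bx, by, sy)
        clean = pairs_frame(bx[1:], by[1:], sy[1:])
        wm_clean = weighted_median(clean, n_boot=10, seed=0).beta
        wm_full = weighted_median(full, n_boot=10, seed=0).beta
        pwm_full = penalized_weighted_median(full, n_boot=10, seed=0).beta
        assert abs(pwm_full - wm_clean) < abs(wm_full - wm_clean)
        assert pwm_full == pytest.approx(wm_clean, rel=0.05)

    def test_zero_penalty_scale_keeps_best_fitting_snps(self):
        # penalty_scale -> 0 limit: weights ~ w_j * p_j, so the SNP(s) with
        # the largest heterogeneity p-value (here the ratio at the median)
        # determine the estimate
        p = pairs_frame([1.0, 1.0, 1.0], [1.0, 2.0, 4.0], [0.5, 0.5, 0.5])
        est = penalized_weighted_median(p, n_boot=10, seed=0, penalty_scale=0.0)
        assert est.beta == pytest.approx(2.0, abs=0.2)


class TestOrientationInvariance:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_estimators_invariant_to_per_snp_sign_flips(self, seed):
        rng = np.random.default_rng(seed)
        p = random_instance(rng, j=8)
        flip = rng.random(8) < 0.5
        s = np.where(flip, -1.0, 1.0)
        q = p.copy()
        q["beta_x"] *= s
        q["beta_y"] *= s
        assert ivw(q).beta == pytest.approx(ivw(p).beta, rel=1e-12)
        assert mr_egger(q).beta == pytest.approx(mr_egger(p).beta, rel=1e-12)
        wm_p = weighted_median(p, n_boot=5, seed=1).beta
        wm_q = weighted_median(q, n_boot=5, seed=1).beta
        assert wm_q == pytest.approx(wm_p, rel=1e-12)
        pwm_p = penalized_weighted_median(p, n_boot=5, seed=1).beta
        pwm_q = penalized_weighted_median(q, n_boot=5, seed=1).beta
        assert pwm_q == pytest.approx(pwm_p, rel=1e-12)


class TestSensitivityWrappers:
    def test_leave_one_out_two_snps_gives_ratios(self):
        p = pairs_frame([0.5, 0.25], [1.0, 1.0], [1.0, 1.0])
        folds = leave_one_out(p, ivw)
        assert [f.omitted for f in folds] == ["rs0", "rs1"]
        assert folds[0].beta == pytest.approx(4.0)  # rs0 omitted -> rs1 ratio
        assert folds[1].beta == pytest.approx(2.0)

    def test_homogeneous_instruments_all_folds_agree(self, rng):
        bx = rng.uniform(0.1, 0.3, 12)
        sy = np.full(12, 0.02)
        by = 0.5 * bx + rng.normal(0, 0.02, 12)
        folds = leave_one_out(pairs_frame(bx, by, sy), ivw)
        betas = np.array([f.beta for f in folds])
        for f in folds:
            assert np.all((betas > f.ci_low) & (betas < f.ci_high))

    def test_single_dominant_outlier_shifts_exactly_one_fold(self, rng):
        bx = np.full(10, 0.2)
        by = 0.5 * bx
        by[3] += 5.0
        sy = np.full(10, 0.1)
        folds = leave_one_out(pairs_frame(bx, by, sy), ivw)
        betas = np.array([f.beta for f in folds])
        med = np.median(betas)
        outlier_folds = np.flatnonzero(np.abs(betas - med) > 1.0)
        assert list(outlier_folds) == [3]

    def test_empty_exclusion_is_identity(self, rng):
        p = random_instance(rng)
        assert exclude_and_reestimate(p, set(), ivw).beta == ivw(p).beta

    def test_exclude_all_but_one_gives_ratio(self):
        p = pairs_frame([0.5, 0.25], [1.0, 1.0], [1.0, 1.0])
        est = exclude_and_reestimate(p, {"rs0"}, ivw)
        assert est.beta == pytest.approx(4.0)

    def test_unknown_rsids_warned_and_ignored(self, rng):
        p = random_instance(rng)
        with pytest.warns(UserWarning, match="non-instrument"):
            est = exclude_and_reestimate(p, {"nonexistent"}, ivw)
        assert est.beta == ivw(p).beta

    def test_excluding_everything_is_an_error(self):
        p = pairs_frame([0.5], [1.0], [1.0])
        with pytest.raises(EstimationError):
            exclude_and_reestimate(p, {"rs0"}, ivw)


class TestTsls:
    def test_noiseless_proportional_outcome(self, rng):
        x = rng.normal(size=200)
        z = x + rng.normal(size=200)
        est = tsls(x, 2.0 * x, z)
        assert est.beta == pytest.approx(2.0, abs=1e-10)
        assert est.se == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_instrument_raises_weak_instrument(self, rng):
        x = rng.normal(size=100)
        x = x - x.mean()
        z = rng.normal(size=100)
        z = z - z.mean()
        z = z - x * (z @ x) / (x @ x)  # exactly orthogonal in-sample
        with pytest.raises(WeakInstrumentError):
            tsls(x, x + 1.0, z)

    def test_confounded_exposure_ols_biased_tsls_not(self, rng):
        """Classic IV setting: z -> x, u -> (x, y), x -> y with beta 1.5.
        OLS absorbs the confounding path; 2SLS does not."""
        n = 50_000
        z = rng.normal(size=n)
        u = rng.normal(size=n)
        x = 0.5 * z + u + rng.normal(size=n)
        y = 1.5 * x + 2.0 * u + rng.normal(size=n)
        est = tsls(x, y, z)
        ols = np.polyfit(x, y, 1)[0]
        # OLS bias = cov(x,u)*2/var(x) = 2/2.25
        assert ols == pytest.approx(1.5 + 2.0 / 2.25, abs=0.05)
        assert abs(est.beta - 1.5) < 2 * est.se
        assert est.first_stage_f > 1000

    def test_first_stage_f_matches_regression_f(self, rng):
        x = rng.normal(size=500)
        z = 0.3 * x + rng.normal(size=500)
        est = tsls(x, x + rng.normal(size=500), z)
        fit = sm.OLS(x, sm.add_constant(z)).fit()
        assert est.first_stage_f == pytest.approx(fit.fvalue, rel=1e-8)


class TestUnitsAndMediation:
    def test_sd_conversion(self):
        assert sd_unit_conversion(0.0, 24.23) == 0.0
        assert sd_unit_conversion(24.23, 24.23) == pytest.approx(1.0)
        with pytest.raises(ParameterError):
            sd_unit_conversion(1.0, 0.0)

    def test_mediation_zero_path_gives_zero(self):
        med = mediation_expectation(0.0, 0.1, 5.0, 1.0)
        assert med.effect == 0.0

    def test_mediation_product_and_delta_se(self):
        med = mediation_expectation(2.0, 0.0, 3.0, 0.0)
        assert med.effect == pytest.approx(6.0)
        assert med.se == 0.0
        med2 = mediation_expectation(2.0, 0.1, 3.0, 0.2)
        assert med2.se == pytest.approx(np.sqrt(4 * 0.04 + 9 * 0.01))
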
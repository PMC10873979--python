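"""Estimator algebra against independent oracles, invariances, reductions."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from summstat_mr.estimators import (CollinearityError,
                                    InsufficientInstrumentsError, MRModel,
                                    ivw, mr_egger, mvmr_egger, mvmr_ivw,
                                    mvmr_median, to_odds_ratio, wald_ratio,
                                    weighted_median)
from summstat_mr.synthetic_data import SimConfig


class TestWaldRatio:
    def test_arithmetic(self):
        est = wald_ratio(beta_x=0.1, se_x=0.01, beta_y=0.05, se_y=0.01)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).beta == 0.0

    def test_second_order_se_never_smaller(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            bx, sx, by, sy = rng.uniform(0.01, 1, 4)
            first = wald_ratio(bx, sx, by, sy).se
            second = wald_ratio(bx, sx, by, sy, second_order=True).se
            assert second >= first

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


def _wls_oracle(frame, with_intercept):
    """statsmodels WLS as the independent closed-form reference."""
    sign = np.where(frame.beta_x[:, 0] >= 0, 1.0, -1.0) if with_intercept \
        else np.ones(frame.n_snp)
    X = frame.beta_x * sign[:, None]
    y = frame.beta_y * sign
    if with_intercept:
        X = sm.add_constant(X)
    res = sm.WLS(y, X, weights=1.0 / frame.se_y**2).fit()
    scale_sd = np.sqrt(res.scale)
    se_unscaled = res.bse / scale_sd
    return res.params, se_unscaled, scale_sd


class TestIVW:
    def test_equal_weight_mean_of_two_ratios(self, frame_from_arrays):
        model = frame_from_arrays(bx=[0.1, 0.1], se_x=[0.01, 0.01],
                                  by=[0.04, 0.06], se_y=[0.02, 0.02])
        assert ivw(model.frame).beta == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [5, 12, 50])
    def test_matches_wls_oracle(self, n, random_frame):
        rng = np.random.default_rng(n)
        frame = random_frame(rng, n).frame
        params, se_u, scale_sd = _wls_oracle(frame, with_intercept=False)
        fixed = ivw(frame, effects_model="fixed")
        assert fixed.beta == pytest.approx(params[0], abs=1e-10)
        assert fixed.se == pytest.approx(se_u[0], abs=1e-10)
        mre = ivw(frame)
        assert mre.se == pytest.approx(se_u[0] * max(1.0, scale_sd), abs=1e-10)

    def test_single_snp_falls_back_to_wald_ratio(self, frame_from_arrays):
        model = frame_from_arrays(bx=[0.1], se_x=[0.01], by=[0.05], se_y=[0.02])
        est = ivw(model.frame)
        assert est.beta == pytest.approx(0.5)
        assert est.extras.get("fallback") == "wald_ratio"

    def test_random_effects_never_narrower_than_fixed(self, random_frame):
        rng = np.random.default_rng(42)
        for _ in range(10):
            frame = random_frame(rng, 15).frame
            assert ivw(frame).se >= ivw(frame, effects_model="fixed").se


class TestMREgger:
    @pytest.mark.parametrize("n", [5, 20, 50])
    def test_matches_wls_oracle(self, n, random_frame):
        rng = np.random.default_rng(100 + n)
        frame = random_frame(rng, n).frame
        params, se_u, scale_sd = _wls_oracle(frame, with_intercept=True)
        est = mr_egger(frame)
        factor = max(1.0, scale_sd)
        assert est.beta == pytest.approx(params[1], abs=1e-10)
        assert est.se == pytest.approx(se_u[1] * factor, abs=1e-10)
        assert est.extras["intercept"] == pytest.approx(params[0], abs=1e-10)
        assert est.extras["intercept_se"] == pytest.approx(se_u[0] * factor,
                                                           abs=1e-10)

    def test_orientation_undoes_joint_row_negation(self, random_frame):
        rng = np.random.default_rng(7)
        frame = random_frame(rng, 10).frame
        sign = rng.choice([-1.0, 1.0], size=10)
        flipped = frame.subset(np.ones(10, dtype=bool))
        flipped.beta_x = frame.beta_x * sign[:, None]
        flipped.beta_y = frame.beta_y * sign
        base, alt = mr_egger(frame), mr_egger(flipped)
        assert alt.beta == pytest.approx(base.beta, abs=1e-12)
        assert alt.extras["intercept"] == pytest.approx(
            base.extras["intercept"], abs=1e-12)

    def test_too_few_instruments(self, frame_from_arrays):
        model = frame_from_arrays(bx=[0.1, 0.2], se_x=[0.01, 0.01],
                                  by=[0.01, 0.02], se_y=[0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(model.frame)


def _brute_force_weighted_median(ratios, weights):
    """Direct evaluation of the interpolated weighted-median definition."""
    order = sorted(range(len(ratios)), key=lambda i: ratios[i])
    v = [ratios[i] for i in order]
    w = [weights[i] / sum(weights) for i in order]
    s = []
    acc = 0.0
    for wi in w:
        s.append(acc + wi / 2.0)
        acc += wi
    if 0.5 <= s[0]:
        return v[0]
    for j in range(1, len(s)):
        if s[j] >= 0.5:
            t = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
            return v[j - 1] + t * (v[j] - v[j - 1])
    return v[-1]


class TestWeightedMedian:
    def test_middle_element_at_equal_weights(self, frame_from_arrays):
        model = frame_from_arrays(bx=[0.1, 0.1, 0.1], se_x=[0.01] * 3,
                                  by=[0.02, 0.05, 0.09], se_y=[0.01] * 3)
        est = weighted_median(model.frame, n_boot=50, seed=1)
        assert est.beta == pytest.approx(0.5)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_brute_force_oracle_up_to_seven_snps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 8))
        bx = rng.uniform(0.02, 0.2, n) * rng.choice([-1, 1], n)
        se_y = rng.uniform(0.005, 0.05, n)
        by = rng.normal(0.0, 0.1, n)
        df = pd.DataFrame({"beta_x": bx, "se_x": 0.01, "beta_y": by,
                           "se_y": se_y})
        frame = MRModel.from_dataframe(df).frame
        ratios = by / bx
        weights = (bx / se_y) ** 2
        est = weighted_median(frame, n_boot=10, seed=0)
        assert est.beta == pytest.approx(
            _brute_force_weighted_median(list(ratios), list(weights)), abs=1e-12)

    def test_deterministic_given_seed(self, random_frame):
        frame = random_frame(np.random.default_rng(3), 10).frame
        a = weighted_median(frame, n_boot=100, seed=5)
        b = weighted_median(frame, n_boot=100, seed=5)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestMultivariable:
    def test_k1_reduces_to_univariable_ivw(self, random_frame):
        frame = random_frame(np.random.default_rng(11), 20).frame
        uni, mv = ivw(frame), mvmr_ivw(frame)[0]
        assert mv.beta == pytest.approx(uni.beta, abs=1e-12)
        assert mv.se == pytest.approx(uni.se, abs=1e-12)

    def test_k1_reduces_to_univariable_egger(self, random_frame):
        frame = random_frame(np.random.default_rng(12), 20).frame
        uni, mv = mr_egger(frame), mvmr_egger(frame)[0]
        assert mv.beta == pytest.approx(uni.beta, abs=1e-12)
        assert mv.extras["intercept"] == pytest.approx(uni.extras["intercept"],
                                                       abs=1e-12)
        assert mv.extras["intercept_pvalue"] == pytest.approx(
            uni.extras["intercept_pvalue"], abs=1e-12)

    @pytest.mark.parametrize("K", [2, 3])
    def test_mvmr_ivw_matches_wls_oracle(self, K, random_frame):
        frame = random_frame(np.random.default_rng(20 + K), 30, K=K).frame
        res = sm.WLS(frame.beta_y, frame.beta_x,
                     weights=1.0 / frame.se_y**2).fit()
        ests = mvmr_ivw(frame)
        factor = max(1.0, np.sqrt(res.scale))
        for k in range(K):
            assert ests[k].beta == pytest.approx(res.params[k], abs=1e-10)
            assert ests[k].se == pytest.approx(
                res.bse[k] / np.sqrt(res.scale) * factor, abs=1e-10)

    def test_mvmr_median_matches_direct_lad_minimization(self, random_frame):
        from scipy.optimize import minimize

        frame = random_frame(np.random.default_rng(31), 40, K=2).frame
        w = 1.0 / frame.se_y**2

        def loss(b):
            return np.sum(w * np.abs(frame.beta_y - frame.beta_x @ b))

        ests = mvmr_median(frame, n_boot=10, seed=0)
        coef = np.array([e.beta for e in ests])
        direct = minimize(loss, x0=np.array([0.1, 0.1]), method="Nelder-Mead",
                          options={"xatol": 1e-10, "fatol": 1e-12,
                                   "maxiter": 5000})
        assert loss(coef) <= direct.fun * (1 + 1e-6) + 1e-12
        np.testing.assert_allclose(coef, direct.x, atol=5e-4)

    def test_mvmr_median_k1_consistent_with_weighted_median(self, instrument_frame):
        frame, _ = instrument_frame(SimConfig(seed=13, n_snps=120,
                                              n_instruments=20))
        uni = weighted_median(frame, n_boot=200, seed=2)
        mv = mvmr_median(frame, n_boot=200, seed=2)[0]
        assert abs(mv.beta - uni.beta) < 3 * max(uni.se, mv.se)

    def test_mvmr_median_deterministic_given_seed(self, random_frame):
        frame = random_frame(np.random.default_rng(33), 15, K=2).frame
        a = mvmr_median(frame, n_boot=30, seed=9)
        b = mvmr_median(frame, n_boot=30, seed=9)
        assert [e.beta for e in a] == [e.beta for e in b]
        assert [e.se for e in a] == [e.se for e in b]

    def test_collinearity_signal_names_exposures(self, frame_from_arrays):
        df = pd.DataFrame({"bx0": [0.1, 0.2, 0.3, 0.4],
                           "sx0": 0.01, "sx1": 0.01,
                           "beta_y": [0.01, 0.02, 0.03, 0.04], "se_y": 0.01})
        df["bx1"] = 2.0 * df["bx0"]
        model = MRModel.from_dataframe(df, beta_x=["bx0", "bx1"],
                                       se_x=["sx0", "sx1"])
        with pytest.raises(CollinearityError, match="bx0"):
            mvmr_ivw(model.frame)

    def test_too_few_snps_for_design(self, random_frame):
        frame = random_frame(np.random.default_rng(40), 3, K=3).frame
        with pytest.raises(InsufficientInstrumentsError):
            mvmr_ivw(frame)


class TestInvariances:
    def test_zero_heterogeneity_limit_all_methods_agree(self, frame_from_arrays):
        bx = np.array([0.05, 0.1, 0.2, 0.4])
        model = frame_from_arrays(bx=bx, se_x=[0.01] * 4, by=0.3 * bx,
                                  se_y=[0.01] * 4)
        frame = model.frame
        assert ivw(frame).beta == pytest.approx(0.3, abs=1e-12)
        assert mr_egger(frame).beta == pytest.approx(0.3, abs=1e-9)
        assert weighted_median(frame, n_boot=10, seed=0).beta == pytest.approx(
            0.3, abs=1e-12)

    def test_sign_equivariance(self, random_frame):
        frame = random_frame(np.random.default_rng(55), 25).frame
        neg_x = frame.subset(np.ones(25, dtype=bool))
        neg_x.beta_x = -frame.beta_x
        neg_y = frame.subset(np.ones(25, dtype=bool))
        neg_y.beta_y = -frame.beta_y
        for fit in (ivw, mr_egger,
                    lambda f: weighted_median(f, n_boot=10, seed=0)):
            base = fit(frame).beta
            assert fit(neg_x).beta == pytest.approx(-base, abs=1e-10)
            assert fit(neg_y).beta == pytest.approx(-base, abs=1e-10)


class TestOddsRatioView:
    def test_zero_beta_symmetric_around_one(self, frame_from_arrays):
        est = wald_ratio(0.1, 0.01, 0.0, 0.01)
        orv = to_odds_ratio(est)
        o, lo, hi = orv.or_scale
        assert o == 1.0
        assert lo * hi == pytest.approx(1.0)

    def test_published_shape_arithmetic(self):
        est = wald_ratio(1.0, 0.0, 0.1133, 0.0341)
        o, lo, hi = to_odds_ratio(est).or_scale
        assert o == pytest.approx(1.12, abs=0.005)
        assert lo == pytest.approx(1.05, abs=0.005)
        assert hi == pytest.approx(1.20, abs=0.005)

    def test_ci_bounds_monotone_in_se(self):
        widths = []
        for se in (0.01, 0.05, 0.1):
            _, lo, hi = to_odds_ratio(wald_ratio(1.0, 0.0, 0.1, se)).or_scale
            widths.append(hi - lo)
        assert widths == sorted(widths)

    def test_or_equals_exp_beta_to_machine_precision(self, random_frame):
        frame = random_frame(np.random.default_rng(60), 10).frame
        est = ivw(frame)
        assert est.or_scale[0] == pytest.approx(np.exp(est.beta), rel=1e-15)


class TestModelInterface:
    def test_fit_dispatch_and_summary(self, random_frame):
        model = random_frame(np.random.default_rng(70), 12)
        res = model.fit("ivw")
        assert res.beta == pytest.approx(ivw(model.frame).beta)
        assert "ivw" in res.summary()
        assert res.conf_int()[0] < res.beta < res.conf_int()[1]

    def test_fit_all_returns_one_row_per_method(self, random_frame):
        model = random_frame(np.random.default_rng(71), 12)
        table = model.fit_all(seed=0, n_boot=20)
        assert set(table["method"]) == {"ivw", "mr_egger", "weighted_median"}

    def test_unknown_method_rejected(self, random_frame):
        model = random_frame(np.random.default_rng(72), 12)
        with pytest.raises(ValueError, match="unknown method"):
            model.fit("mode")
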
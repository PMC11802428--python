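import numpy as np
import pytest

from psmcea import (
    DigitizedCurve,
    FitError,
    ParametricCurve,
    ParametricModel,
    PseudoIPD,
    fit_parametric,
    hybrid_curve,
    rank_models,
    survival_at,
)
from psmcea.survfit import FitDiagnostics, curve_median


class TestFitParametric:
    def test_exponential_closed_form(self):
        """Uncensored times {1,2,3,4}: MLE rate = events / total time = 0.4."""
        model, diag = fit_parametric(PseudoIPD([1, 2, 3, 4], [1, 1, 1, 1]), "exponential")
        assert model.params["rate"] == pytest.approx(0.4)
        assert diag.aic == pytest.approx(2 - 2 * diag.loglik)

    def test_exponential_consistency(self):
        # n chosen so the 2% band is ~4 sampling standard errors wide
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / 0.05, 40_000)
        model, _ = fit_parametric(PseudoIPD(t, np.ones_like(t)), "exponential")
        assert model.params["rate"] == pytest.approx(0.05, rel=0.02)

    def test_lognormal_recovery_with_censoring(self):
        rng = np.random.default_rng(3)
        n = 5000
        tev = rng.lognormal(2.0, 1.3, n)
        c = rng.exponential(60, n)
        t = np.minimum(tev, c)
        e = (tev <= c).astype(int)
        assert 0.1 < 1 - e.mean() < 0.3  # roughly 20% censoring
        model, diag = fit_parametric(PseudoIPD(t, e), "lognormal")
        assert model.params["meanlog"] == pytest.approx(2.0, rel=0.05)
        assert model.params["sdlog"] == pytest.approx(1.3, rel=0.05)
        assert diag.converged

    def test_zero_events_rejected(self):
        with pytest.raises(FitError):
            fit_parametric(PseudoIPD([1, 2, 3], [0, 0, 0]), "exponential")

    def test_uniform_weights_equal_unweighted(self):
        rng = np.random.default_rng(4)
        t = rng.weibull(1.5, 400) * 12
        ipd = PseudoIPD(t, np.ones_like(t))
        m1, _ = fit_parametric(ipd, "weibull")
        m2, _ = fit_parametric(ipd, "weibull", weights=np.full(400, 3.0))
        for k in m1.params:
            assert m1.params[k] == pytest.approx(m2.params[k], abs=1e-6)

    def test_integer_weights_equal_duplication(self):
        t = np.array([2.0, 5.0, 9.0, 14.0, 20.0])
        e = np.array([1, 1, 0, 1, 1])
        w = np.array([2.0, 1.0, 3.0, 1.0, 2.0])
        m1, _ = fit_parametric(PseudoIPD(t, e, w), "weibull")
        t_dup = np.repeat(t, w.astype(int))
        e_dup = np.repeat(e, w.astype(int))
        m2, _ = fit_parametric(PseudoIPD(t_dup, e_dup), "weibull")
        for k in m1.params:
            assert m1.params[k] == pytest.approx(m2.params[k], rel=1e-4)

    def test_matches_lifelines(self):
        from lifelines import LogNormalFitter, WeibullFitter

        rng = np.random.default_rng(5)
        tev = rng.lognormal(1.8, 1.1, 2000)
        c = rng.exponential(40, 2000)
        t, e = np.minimum(tev, c), (tev <= c).astype(int)
        ipd = PseudoIPD(t, e)

        m, d = fit_parametric(ipd, "weibull")
        wf = WeibullFitter().fit(t, e)
        assert m.params["scale"] == pytest.approx(wf.lambda_, rel=1e-4)
        assert m.params["shape"] == pytest.approx(wf.rho_, rel=1e-4)
        assert d.loglik == pytest.approx(wf.log_likelihood_, abs=1e-2)

        m, d = fit_parametric(ipd, "lognormal")
        lf = LogNormalFitter().fit(t, e)
        assert m.params["meanlog"] == pytest.approx(lf.mu_, rel=1e-4)
        assert m.params["sdlog"] == pytest.approx(lf.sigma_, rel=1e-4)

    def test_generalized_gamma_nests_lognormal(self):
        rng = np.random.default_rng(6)
        t = rng.lognormal(2.0, 1.3, 3000)
        model, _ = fit_parametric(PseudoIPD(t, np.ones_like(t)), "generalized_gamma")
        assert abs(model.params["Q"]) < 0.15
        assert model.params["mu"] == pytest.approx(2.0, abs=0.15)


class TestRanking:
    def test_single_candidate(self):
        d = FitDiagnostics("exponential", -10.0, 1, 100, True)
        assert rank_models([d]) == [d]

    def test_weibull_beats_exponential_on_weibull_data(self):
        rng = np.random.default_rng(7)
        t = rng.weibull(2.0, 5000) * 15
        ipd = PseudoIPD(t, np.ones_like(t))
        _, d_w = fit_parametric(ipd, "weibull")
        _, d_e = fit_parametric(ipd, "exponential")
        ranked = rank_models([d_e, d_w])
        assert ranked[0].family == "weibull"

    def test_fewer_parameters_break_ties(self):
        a = FitDiagnostics("weibull", -10.0, 2, 100, True)
        b = FitDiagnostics("exponential", -11.0, 1, 100, True)  # equal AIC = 24
        assert rank_models([a, b])[0].family == "exponential"

    def test_bic_identity(self):
        d = FitDiagnostics("weibull", -123.4, 2, 57.0, True)
        assert d.bic == pytest.approx(2 * np.log(57.0) + 2 * 123.4)


class TestSurvivalAt:
    def test_published_exponential_rate(self):
        m = ParametricModel("exponential", {"rate": 0.04397})
        assert survival_at(m, 12.0) == pytest.approx(np.exp(-0.52764), abs=1e-4)
        assert survival_at(m, 12.0) == pytest.approx(0.5900, abs=1e-4)

    def test_lognormal_median_property(self):
        m = ParametricModel("lognormal", {"meanlog": 2.029, "sdlog": 1.321})
        assert survival_at(m, float(np.exp(2.029))) == pytest.approx(0.5, abs=1e-9)
        assert m.median() == pytest.approx(np.exp(2.029), rel=1e-9)

    def test_time_zero(self):
        for fam, params in [
            ("exponential", {"rate": 0.1}),
            ("lognormal", {"meanlog": 1.0, "sdlog": 0.5}),
            ("generalized_gamma", {"mu": 1.0, "sigma": 0.5, "Q": -0.5}),
        ]:
            assert ParametricModel(fam, params).survival(0.0) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ParametricModel("exponential", {"rate": 0.1}).survival(-1.0)

    @pytest.mark.parametrize(
        "family,params",
        [
            ("exponential", {"rate": 0.05}),
            ("weibull", {"shape": 1.4, "scale": 18.0}),
            ("gompertz", {"shape": 0.03, "rate": 0.02}),
            ("loglogistic", {"shape": 1.8, "scale": 10.0}),
            ("lognormal", {"meanlog": 2.0, "sdlog": 1.2}),
            ("generalized_gamma", {"mu": 2.2, "sigma": 0.9, "Q": 0.7}),
        ],
    )
    def test_survival_function_shape(self, family, params):
        """S(0)=1, monotone non-increasing, vanishing in the far tail."""
        m = ParametricModel(family, params)
        grid = np.linspace(0, 600, 2000)
        s = m.survival(grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))
        assert s[-1] < 1e-3
        # inverse agrees with forward evaluation
        t_half = m.inverse_survival(0.5)
        assert m.survival(t_half) == pytest.approx(0.5, abs=1e-8)


class TestHybridCurve:
    def test_switch_zero_is_pure_parametric(self):
        km = DigitizedCurve([0, 12], [1.0, 0.6])
        m = ParametricModel("exponential", {"rate": 0.05})
        curve = hybrid_curve(km, m, 0.0)
        assert isinstance(curve, ParametricCurve)

    def test_continuity_at_switch(self):
        km = DigitizedCurve([0, 6, 12, 24], [1.0, 0.8, 0.7, 0.40])
        m = ParametricModel("exponential", {"rate": 0.04397})
        curve = hybrid_curve(km, m, 24.0)
        assert curve.survival(24.0) == pytest.approx(curve.survival(24.0 + 1e-9), abs=1e-8)

    def test_anchoring_formula(self):
        km = DigitizedCurve([0, 12, 24], [1.0, 0.7, 0.40])
        m = ParametricModel("exponential", {"rate": 0.04397})
        curve = hybrid_curve(km, m, 24.0)
        assert curve.survival(36.0) == pytest.approx(0.40 * np.exp(-0.04397 * 12), abs=1e-6)
        assert curve.survival(36.0) == pytest.approx(0.2360, abs=2e-4)

    def test_switch_outside_support_rejected(self):
        km = DigitizedCurve([0, 12], [1.0, 0.6])
        m = ParametricModel("exponential", {"rate": 0.05})
        with pytest.raises(ValueError):
            hybrid_curve(km, m, 30.0)

    def test_curve_median(self):
        m = ParametricModel("exponential", {"rate": 0.04397})
        med = curve_median(ParametricCurve(m))
        assert med == pytest.approx(np.log(2) / 0.04397, rel=1e-6)
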
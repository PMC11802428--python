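import numpy as np
import pytest

from psmcea import (
    AdverseEvent,
    ModelSettings,
    ParametricCurve,
    ParametricModel,
    StrategyConfig,
    accumulate,
    build_trace,
    compare,
    discount_factor,
    run_psm,
)
from psmcea.psm_engine import horizon_cycles


def exp_curve(rate):
    return ParametricCurve(ParametricModel("exponential", {"rate": rate}))


def plain_strategy(**kw):
    base = dict(
        name="arm",
        drug_cost_pfs_cycle=0.0,
        drug_cost_pd_cycle=0.0,
        utility_pfs=1.0,
        utility_pd=1.0,
        end_of_life_cost=0.0,
    )
    base.update(kw)
    return StrategyConfig(**base)


class TestDiscounting:
    @pytest.mark.parametrize(
        "t,r,expected",
        [(0.0, 0.05, 1.0), (12.0, 0.05, 1 / 1.05), (6.0, 0.05, 1.05**-0.5)],
    )
    def test_examples(self, t, r, expected):
        assert discount_factor(t, r) == pytest.approx(expected, abs=1e-6)


class TestTrace:
    def test_occupancy_conserved(self):
        os_c, pfs_c = exp_curve(0.04397), exp_curve(0.08)
        trace = build_trace(os_c, pfs_c, ModelSettings())
        np.testing.assert_allclose(trace.pfs + trace.pd + trace.dead, 1.0, atol=1e-12)
        assert np.all(np.diff(trace.dead) >= -1e-15)
        assert np.all(trace.pd >= 0)

    def test_identical_curves_leave_no_progressed_state(self):
        c = exp_curve(0.05)
        trace = build_trace(c, c, ModelSettings())
        np.testing.assert_allclose(trace.pd, 0.0, atol=1e-15)

    def test_dead_fraction_at_one_year(self):
        trace = build_trace(exp_curve(0.04397), exp_curve(0.08), ModelSettings())
        assert trace.dead[12] == pytest.approx(1 - 0.5900, abs=1e-4)

    def test_crossing_tails_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            trace = build_trace(exp_curve(0.08), exp_curve(0.04), ModelSettings())
        np.testing.assert_allclose(trace.pd, 0.0, atol=1e-15)

    def test_horizon_rule(self):
        # exponential 0.04397: S(t) <= 0.01 first at t = 105
        T = horizon_cycles([exp_curve(0.04397)], ModelSettings())
        assert T == 105
        T2 = horizon_cycles([exp_curve(0.04397), exp_curve(0.002)], ModelSettings(max_cycles=480))
        assert T2 == 480  # slow-dying arm hits the cap


class TestAccumulate:
    def test_geometric_series_life_years(self):
        """Undiscounted LYs for exponential OS equal the closed-form sum."""
        lam = 0.04397
        settings = ModelSettings(discount_rate=0.0)
        trace = build_trace(exp_curve(lam), exp_curve(lam), settings)
        res = accumulate(trace, plain_strategy(), settings)
        T = trace.n_cycles
        closed = (1 - np.exp(-lam * T)) / (12 * (1 - np.exp(-lam)))
        assert res.ly_undiscounted == pytest.approx(closed, abs=1e-12)
        assert closed == pytest.approx(1.92, abs=0.01)

    def test_qalys_equal_lys_when_utilities_one(self):
        settings = ModelSettings(discount_rate=0.0)
        trace = build_trace(exp_curve(0.05), exp_curve(0.09), settings)
        res = accumulate(trace, plain_strategy(), settings)
        assert res.qaly_discounted == pytest.approx(res.ly_undiscounted, abs=1e-12)

    def test_zero_discount_internal_validation(self):
        """With r = 0 discounted and undiscounted accumulators coincide."""
        settings = ModelSettings(discount_rate=0.0)
        trace = build_trace(exp_curve(0.05), exp_curve(0.09), settings)
        strat = plain_strategy(
            drug_cost_pfs_cycle=100.0, drug_cost_pd_cycle=50.0,
            end_of_life_cost=1000.0, utility_pfs=0.8, utility_pd=0.3,
        )
        res = accumulate(trace, strat, settings)
        assert res.ly_discounted == pytest.approx(res.ly_undiscounted, abs=1e-12)
        assert res.qaly_discounted == pytest.approx(res.qaly_undiscounted, abs=1e-12)
        for k in res.costs:
            assert res.costs[k] == pytest.approx(res.costs_undiscounted[k], abs=1e-9)

    def test_discounting_shrinks_every_category(self):
        settings = ModelSettings(discount_rate=0.05)
        trace = build_trace(exp_curve(0.05), exp_curve(0.09), settings)
        strat = plain_strategy(
            drug_cost_pfs_cycle=100.0, drug_cost_pd_cycle=50.0,
            end_of_life_cost=1000.0, pfs_management_cycle=5.0,
        )
        res = accumulate(trace, strat, settings)
        assert res.ly_discounted < res.ly_undiscounted
        for k in ("drug_pfs", "drug_pd", "management", "end_of_life"):
            assert res.costs[k] <= res.costs_undiscounted[k] + 1e-12

    def test_drug_cost_occupancy_identity(self):
        settings = ModelSettings()
        trace = build_trace(exp_curve(0.05), exp_curve(0.09), settings)
        strat = plain_strategy(drug_cost_pfs_cycle=2921.90)
        res = accumulate(trace, strat, settings)
        expected = 2921.90 * float(np.sum(trace.pfs * trace.discount))
        assert res.costs["drug_pfs"] == pytest.approx(expected, abs=1e-9)

    def test_end_of_life_cost(self):
        settings = ModelSettings()
        trace = build_trace(exp_curve(0.05), exp_curve(0.05), settings)
        strat = plain_strategy(end_of_life_cost=7554.01)
        res = accumulate(trace, strat, settings)
        expected = 7554.01 * float(np.sum(trace.incident_deaths * trace.discount))
        assert res.costs["end_of_life"] == pytest.approx(expected, abs=1e-9)

    def test_ae_burden_once_at_entry(self):
        settings = ModelSettings()
        trace = build_trace(exp_curve(0.05), exp_curve(0.09), settings)
        ae = AdverseEvent("anaemia", incidence=0.2, cost=30.0, disutility=0.1, duration_years=0.5)
        strat = plain_strategy(adverse_events=[ae], utility_pfs=0.8, utility_pd=0.3)
        res = accumulate(trace, strat, settings)
        assert res.costs["ae"] == pytest.approx(0.2 * 30.0)
        assert res.qaly_ae_decrement == pytest.approx(0.2 * 0.1 * 0.5)
        assert res.qaly_discounted == pytest.approx(
            res.qaly_pfs + res.qaly_pd - 0.01, abs=1e-12
        )


class TestCompare:
    def test_printed_increment_arithmetic(self):
        inc = compare(_FakeArm("a", 10_000 + 1893.0, 1.17), _FakeArm("b", 10_000.0, 1.07), 35007.0)
        assert inc.icer == pytest.approx(1893.0 / 0.10, rel=1e-9)

    def test_identical_arms_have_undefined_icer(self):
        inc = compare(_FakeArm("a", 5.0, 1.0), _FakeArm("b", 5.0, 1.0), 35007.0)
        assert inc.icer is None
        assert inc.nmb == 0.0

    def test_dominance_flag(self):
        inc = compare(_FakeArm("a", 900.0, 1.1), _FakeArm("b", 1000.0, 1.0), 35007.0)
        assert inc.dominant == "a"

    def test_nmb_sign_agrees_with_icer_threshold(self):
        wtp = 35007.0
        for d_cost, d_qaly in [(1893.0, 0.10), (5000.0, 0.10), (4000.0, 0.05)]:
            inc = compare(_FakeArm("a", d_cost, d_qaly), _FakeArm("b", 0.0, 0.0), wtp)
            assert (inc.nmb > 0) == (inc.icer < wtp)


class _FakeArm:
    def __init__(self, name, total_cost, qaly):
        self.strategy = name
        self.total_cost = total_cost
        self.qaly_discounted = qaly


class TestRunPsm:
    def test_common_horizon_and_incremental(self):
        curves = {
            "a": {"os": exp_curve(0.04397), "pfs": exp_curve(0.09)},
            "b": {"os": exp_curve(0.04427), "pfs": exp_curve(0.10)},
        }
        strats = [plain_strategy(name="a", drug_cost_pfs_cycle=10.0),
                  plain_strategy(name="b", drug_cost_pfs_cycle=12.0)]
        out = run_psm(curves, strats, ModelSettings())
        assert out["traces"]["a"].n_cycles == out["traces"]["b"].n_cycles
        assert out["incremental"].delta_cost == pytest.approx(
            out["arms"]["a"].total_cost - out["arms"]["b"].total_cost
        )
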
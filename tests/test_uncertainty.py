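import numpy as np
import pytest

from psmcea import (
    ParamRange,
    beta_moment_params,
    build_psa_spec,
    dose_mix_factor,
    draw_psa_params,
    gamma_moment_params,
    run_dsa,
    run_model,
    run_psa,
    run_scenarios,
)
from psmcea.config import get_param
from psmcea.uncertainty import PSAParam, run_distribution_sweep, run_horizon_scenario


class TestMomentMatching:
    def test_gamma_example(self):
        shape, scale = gamma_moment_params(2921.90, 292.19)
        assert shape == pytest.approx(100.0)
        assert scale == pytest.approx(29.219)

    def test_beta_example(self):
        a, b = beta_moment_params(0.804, 0.0804)
        assert a == pytest.approx(18.80, abs=0.01)
        assert b == pytest.approx(4.583, abs=0.01)

    def test_beta_infeasible_variance(self):
        with pytest.raises(ValueError, match="infeasible"):
            beta_moment_params(0.5, 0.6)

    def test_draws_reproduce_moments(self):
        rng = np.random.default_rng(0)
        spec = [
            PSAParam(("a",), "gamma", 100.0, 10.0),
            PSAParam(("b",), "beta", 0.3, 0.05),
        ]
        draws = draw_psa_params(spec, 100_000, rng)
        assert draws["a"].mean() == pytest.approx(100.0, rel=0.01)
        assert draws["a"].std() == pytest.approx(10.0, rel=0.02)
        assert draws["b"].mean() == pytest.approx(0.3, abs=0.002)
        assert draws["b"].std() == pytest.approx(0.05, rel=0.03)

    def test_zero_sd_degenerate(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="degenerate"):
            draws = draw_psa_params([PSAParam(("a",), "gamma", 5.0, 0.0)], 10, rng)
        assert (draws["a"] == 5.0).all()


class TestDSA:
    def test_zero_width_range_reproduces_base(self, base_config):
        base = run_model(base_config)["incremental"]
        v = get_param(base_config, "strategies.gumarontinib.drug_cost_pfs_cycle")
        table = run_dsa(
            base_config,
            [ParamRange(("strategies.gumarontinib.drug_cost_pfs_cycle",), v, v, "fixed")],
        )
        assert table.loc[0, "icer_low"] == pytest.approx(base.icer)
        assert table.loc[0, "icer_high"] == pytest.approx(base.icer)

    def test_utility_swing_matches_closed_form(self, base_config):
        """NMB is linear in a shared utility: swing = WTP * delta_u * d(person-years)."""
        delta = 0.05
        u = 0.804
        rng_ = ParamRange(
            ("strategies.gumarontinib.utility_pfs", "strategies.savolitinib.utility_pfs"),
            u - delta, u + delta, "u_pfs",
        )
        table = run_dsa(base_config, [rng_])
        res = run_model(base_config)
        tg = res["traces"]["gumarontinib"]
        ts = res["traces"]["savolitinib"]
        d_py = (np.sum(tg.pfs * tg.discount) - np.sum(ts.pfs * ts.discount)) / 12.0
        expected = 35007.0 * 2 * delta * d_py
        assert table.loc[0, "nmb_swing"] == pytest.approx(abs(expected), rel=1e-6)

    def test_drug_costs_and_utilities_dominate_tornado(self, base_config):
        table = run_dsa(base_config)
        top = set(table["parameter"].head(4))
        assert "Gumarontinib cycle cost (PFS)" in top
        assert "Savolitinib cycle cost (PFS)" in top
        assert "Utility PFS" in top

    def test_one_sided_cost_has_predictable_sign(self, base_config):
        """Raising only the intervention's drug price must lower its NMB."""
        table = run_dsa(
            base_config,
            [ParamRange(("strategies.gumarontinib.drug_cost_pfs_cycle",), 2377.37, 3352.38)],
        )
        assert table.loc[0, "nmb_high"] < table.loc[0, "nmb_low"]


class TestPSA:
    def test_fixed_seed_bit_reproducible(self, base_config):
        a = run_psa(base_config, n=50, seed=123)
        b = run_psa(base_config, n=50, seed=123)
        np.testing.assert_array_equal(a.delta_cost, b.delta_cost)
        np.testing.assert_array_equal(a.delta_qaly, b.delta_qaly)

    def test_zero_variance_collapses_to_base_case(self, base_config):
        base = run_model(base_config)["incremental"]
        spec = [
            PSAParam(p.paths, p.dist, p.mean, 0.0, p.label)
            for p in build_psa_spec(base_config)
        ]
        with pytest.warns(UserWarning, match="degenerate"):
            res = run_psa(base_config, spec=spec, n=20, seed=0)
        np.testing.assert_allclose(res.delta_cost, base.delta_cost, rtol=1e-12)
        np.testing.assert_allclose(res.delta_qaly, base.delta_qaly, rtol=1e-12)
        # CEAC is a step at the base-case ICER
        assert res.ceac_at(base.icer * 1.01) == 1.0
        assert res.ceac_at(base.icer * 0.99) == 0.0

    def test_ceac_limit_is_probability_of_qaly_gain(self, base_config):
        res = run_psa(base_config, n=200, seed=1)
        assert res.ceac_at(1e12) == pytest.approx(np.mean(res.delta_qaly > 0))

    def test_ceac_monotone_when_all_qalys_positive(self, base_config):
        res = run_psa(base_config, n=200, seed=2)
        if np.all(res.delta_qaly > 0):
            assert np.all(np.diff(res.ceac) >= 0)

    def test_mean_icer_varies_within_monte_carlo_error(self, base_config):
        res_a = run_psa(base_config, n=400, seed=10)
        res_b = run_psa(base_config, n=400, seed=11)
        pooled_se = np.std(res_a.delta_qaly) / np.sqrt(400)
        assert abs(res_a.mean_delta_qaly - res_b.mean_delta_qaly) < 5 * pooled_se


class TestScenarios:
    def test_dose_mix_factors(self):
        assert dose_mix_factor({300: 84, 200: 8}, 300) == pytest.approx(0.9710, abs=5e-5)
        assert dose_mix_factor({600: 62, 400: 8}, 600) == pytest.approx(0.9619, abs=5e-5)

    def test_dosage_scenario_scales_costs(self, base_config):
        base = run_model(base_config)
        out = run_scenarios(base_config, which=("dosage",))["dosage"]
        f = out["dose_factors"]["gumarontinib"]
        assert out["arms"]["gumarontinib"].costs["drug_pfs"] == pytest.approx(
            base["arms"]["gumarontinib"].costs["drug_pfs"] * f, rel=1e-9
        )

    def test_truncated_horizon_identical_curves_no_gain(self, base_config):
        cfg = base_config.copy()
        cfg.settings.discount_rate = 0.0
        cfg.curves["savolitinib"] = cfg.curves["gumarontinib"]
        # identical health inputs: same curves and same AE disutility burden
        cfg.strategies["savolitinib"].adverse_events = cfg.strategies[
            "gumarontinib"
        ].adverse_events
        out = run_horizon_scenario(cfg, horizon_months=30.0)
        assert out["n_cycles"] == 30
        assert out["incremental"].delta_qaly == pytest.approx(0.0, abs=1e-12)

    def test_horizon_scenario_labels_curve_kinds(self, hybrid_config):
        out = run_horizon_scenario(hybrid_config, horizon_months=30.0)
        assert "KM" in out["note"]

    def test_sweep_requires_all_families(self, base_config, fitted_families):
        incomplete = {
            k: {"os": dict(v["os"]), "pfs": dict(v["pfs"])}
            for k, v in fitted_families.items()
        }
        incomplete["gumarontinib"]["os"].pop("gompertz")
        with pytest.raises(ValueError, match="fitted alternatives"):
            run_distribution_sweep(base_config, incomplete)

    def test_sweep_enumerates_all_combinations(self, base_config, fitted_families):
        families = ("exponential", "lognormal")
        df, summary = run_distribution_sweep(
            base_config, fitted_families, families=families
        )
        assert summary["n_runs"] == len(families) ** 4
        assert len(df) == len(families) ** 4
        # every combination is distinct
        combo_cols = [c for c in df.columns if c.endswith(("_os", "_pfs"))]
        assert not df.duplicated(subset=combo_cols).any()
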
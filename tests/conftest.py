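import numpy as np
import pytest

from psmcea import TrialSpec, fit_all, make_fixture_config, simulate_trial
from psmcea.synthetic_data import hybrid_standin_config


@pytest.fixture
def base_config():
    """Base-case model configuration (pure parametric curves)."""
    return make_fixture_config()


@pytest.fixture(scope="session")
def hybrid_config():
    """Base-case configuration with KM-within-follow-up hybrid curves."""
    return hybrid_standin_config()


@pytest.fixture(scope="session")
def exp_trial():
    """A censored exponential trial used by several reconstruction tests."""
    spec = TrialSpec(
        n=200,
        baseline_family="exponential",
        baseline_params={"rate": 0.05},
        admin_cutoff_months=36.0,
        censor_rate=0.02,
        seed=7,
    )
    return simulate_trial(spec)


@pytest.fixture(scope="session")
def fitted_families():
    """All six parametric families fitted to two synthetic endpoints."""
    spec_os = TrialSpec(
        n=150, baseline_family="weibull",
        baseline_params={"shape": 1.1, "scale": 20.0},
        admin_cutoff_months=30.0, censor_rate=0.02, seed=5,
    )
    spec_pfs = TrialSpec(
        n=150, baseline_family="lognormal",
        baseline_params={"meanlog": 2.0, "sdlog": 1.2},
        admin_cutoff_months=30.0, censor_rate=0.02, seed=6,
    )
    ipd_os, _, _ = simulate_trial(spec_os)
    ipd_pfs, _, _ = simulate_trial(spec_pfs)
    fits_os = {f: m for f, (m, _) in fit_all(ipd_os).items()}
    fits_pfs = {f: m for f, (m, _) in fit_all(ipd_pfs).items()}
    return {
        name: {"os": dict(fits_os), "pfs": dict(fits_pfs)}
        for name in ("gumarontinib", "savolitinib")
    }
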
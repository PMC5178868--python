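import pytest

from metaconf import BeliefParams, GenerativeParams, simulate_trials
from metaconf.io import generate_fixtures


CANONICAL = GenerativeParams(sigma_act=1.0, sigma_conf=1.0, rho=0.6, theta=1.0)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """Bundled small trial tables, regenerated deterministically per session."""
    outdir = tmp_path_factory.mktemp("fixtures")
    return generate_fixtures(seed=20_000, outdir=outdir)


@pytest.fixture(scope="session")
def second_order_trials():
    """100k trials of the canonical second-order observer (well-calibrated)."""
    belief = BeliefParams.from_generative(CANONICAL, "second_order")
    return simulate_trials(CANONICAL, 1.0, 100_000, belief, seed=11)


@pytest.fixture(scope="session")
def first_order_trials():
    params = GenerativeParams(1.0, 1.0, 1.0, 1.0)
    belief = BeliefParams.from_generative(params, "first_order")
    return simulate_trials(params, 1.0, 100_000, belief, seed=12)
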
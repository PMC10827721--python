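import numpy as np
import pytest

from coexnet.synthetic import GeneratorParams, make_design, simulate_experiment


@pytest.fixture(scope="session")
def small_experiment():
    """A modest simulated experiment shared by read-only tests:
    27-sample default design, 300 genes, two planted modules."""
    design = make_design()
    params = GeneratorParams(
        n_genes=300,
        module_sizes=(40, 40),
        hub_per_module=4,
        de_fraction=0.3,
        seed=101,
    )
    return simulate_experiment(design, params)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
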
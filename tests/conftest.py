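import numpy as np
import pytest

from fermnet.pipeline import default_design, simulate_bundle
from fermnet.rates import phenotype_at
from fermnet.simulate import simulate_fermentation, simulate_metabolome


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """A full synthetic input bundle on disk (default design, seed 0)."""
    out = tmp_path_factory.mktemp("bundle")
    return simulate_bundle(None, out)


@pytest.fixture(scope="session")
def default_phenotype():
    tc = simulate_fermentation(seed=0)
    return phenotype_at(tc, [24.0, 48.0, 60.0, 80.0])


@pytest.fixture(scope="session")
def small_metabolome(default_phenotype):
    """20-sample x 97-metabolite table with planted effects (seed 0)."""
    design = default_design(seed=0)
    table, truth = simulate_metabolome(default_phenotype, design)
    return table, truth, design


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
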
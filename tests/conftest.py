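import numpy as np
import pytest

import ksubinfer as ks


@pytest.fixture(scope="session")
def design_5v3():
    return ks.make_design(5, 3)


@pytest.fixture(scope="session")
def small_experiment():
    """200 proteins x 5 sites, planted direct/indirect sites and protein shifts."""
    cfg = ks.SyntheticConfig(n_proteins=200, sites_per_protein=5,
                             frac_direct=0.02, frac_indirect_up=0.02,
                             frac_protein_shift=0.05, seed=42)
    phospho, proteins, design, truth = ks.generate_experiment(cfg)
    return cfg, phospho, proteins, design, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
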
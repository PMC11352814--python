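import numpy as np
import pytest

import protomort as pm


@pytest.fixture(scope="session")
def default_cohort():
    """The study-shaped cohort: 23/11 patients, 363 proteins, seed 46."""
    return pm.generate_cohort(pm.CohortSpec())


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast model tests: 60 proteins, same patients."""
    spec = pm.CohortSpec(n_proteins_lcms=50, n_proteins_mux=10,
                         n_quant_dap=8, n_qual_dap=6, seed=46)
    return pm.generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_small(small_cohort):
    m = pm.AbundanceMatrix(values=small_cohort.abundance,
                           groups=small_cohort.metadata["status"])
    return pm.impute_min95(pm.compute_coverage_and_route(m))


@pytest.fixture(scope="session")
def fast_config():
    """Reduced-ensemble config for tests whose property does not depend on
    forest size."""
    return pm.ModelConfig(n_trees=50, n_acp_models=5, k_best=5,
                          n_permutations=5, seed=46)


@pytest.fixture
def rng():
    return np.random.default_rng(46)
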
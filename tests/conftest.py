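import numpy as np
import pytest

import hapscan as hs


@pytest.fixture(scope="session")
def pool5():
    """Small 5-SNP pool shared across tests."""
    return hs.generate_haplotype_pool(5, 8, dirichlet_conc=1.0, seed=7)


@pytest.fixture(scope="session")
def null_cohort(pool5):
    """500-sample cohort with no haplotype effect."""
    return hs.generate_cohort(pool5, 250, 250, hs.DiseaseModel(), seed=11)


@pytest.fixture(scope="session")
def small_covariates(null_cohort):
    """A compact covariate table (age, study factor, two eigenvectors)."""
    return null_cohort.covariates[["age", "study", "pc1", "pc2"]]


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
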
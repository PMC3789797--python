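import numpy as np
import pytest

from cmsrf.model import ModelParams
from cmsrf.simulate import simulate_study


@pytest.fixture(scope="session")
def params():
    """The fitted study parameters: distorted transmission, 40% restoration."""
    return ModelParams(tau=0.575, r_r=0.4, r_n=0.4)


@pytest.fixture(scope="session")
def study():
    """One full simulated study shared across tests (fixed seed)."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def gene_matrix(study):
    from cmsrf.markers import combine_matrix_to_genes

    gene, _ = combine_matrix_to_genes(study.dataset.genotypes, study.dataset.snp_to_gene)
    return gene[study.map.panel_markers]
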
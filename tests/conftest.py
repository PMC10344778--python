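import numpy as np
import pytest

from poreselect import build_observation_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def model_hap():
    """Default haploid model with the deletion allele (5 genotypes, 5 symbols)."""
    return build_observation_matrix(0.05, (0.05, 0.1), ploidy=1)


@pytest.fixture
def model_snp_only():
    """Haploid SNP-only model (4 genotypes, 4 symbols)."""
    return build_observation_matrix(0.05, None, ploidy=1)


@pytest.fixture
def uniform_prior5():
    return np.full(5, 0.2)


def brute_force_posterior(counts, prior, model):
    """Independent product-and-normalize oracle in plain linear arithmetic."""
    counts = np.asarray(counts)
    vals = []
    for gi in range(len(prior)):
        p = float(prior[gi])
        for d in range(model.space.n_symbols):
            p *= float(model.phi[gi, d]) ** int(counts[d])
        vals.append(p)
    vals = np.array(vals)
    z = vals.sum()
    return vals / z, z
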
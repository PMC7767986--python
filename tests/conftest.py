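import numpy as np
import pytest

import crossgp as cg

SMALL_SIZES = {"H_bull": 30, "J_bull": 15, "H_cow": 50, "J_cow": 30,
               "75H25J_cow": 30, "50H50J_cow": 30, "25H75J_cow": 15}


@pytest.fixture(scope="session")
def small_config():
    return cg.SimConfig(seed=11, n_snp=600, n_qtl=50, group_sizes=dict(SMALL_SIZES))


@pytest.fixture(scope="session")
def small_population(small_config):
    return cg.simulate_population(small_config)


@pytest.fixture(scope="session")
def small_drp(small_population, small_config):
    return cg.simulate_drp(small_population, small_config, seed=12)


@pytest.fixture(scope="session")
def small_designs(small_population):
    designs, validation = cg.build_reference_designs(small_population, seed=13)
    return designs, validation


def two_breed_genotypes(seed=5, n_per=60, n_f1=0, m=1000, fst=0.1):
    """Convenience builder for a two-breed (+F1) genotype matrix."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.1, 0.9, m)
    pH, pJ = cg.draw_breed_allele_freqs(p, fst, seed + 1)
    sizes = {"H_cow": n_per, "J_cow": n_per}
    if n_f1:
        sizes["50H50J_cow"] = n_f1
    return cg.simulate_genotypes({"H": pH, "J": pJ}, sizes, seed + 2)
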
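import numpy as np
import pytest

from admiximpute import (AdmixtureConfig, ChromosomeSpec, SourcePopConfig,
                         simulate_admixed, simulate_sources)


@pytest.fixture(scope="session")
def toy_chrom():
    return ChromosomeSpec(5_000_000, rate_cM_per_Mb=1.0)


def make_sources(chrom, n_sites=400, n_haps=40, n_founders=10, seed=1,
                 flip=0.0, switch=30.0):
    pops = [SourcePopConfig("AFR", n_haps, n_founders, 0.08, switch, flip),
            SourcePopConfig("EUR", n_haps, n_founders, 0.06, switch, flip),
            SourcePopConfig("NAT", n_haps, n_founders, 0.12, switch, flip)]
    return simulate_sources(chrom, pops, n_sites, seed)


@pytest.fixture(scope="session")
def toy_sources(toy_chrom):
    return make_sources(toy_chrom)


@pytest.fixture(scope="session")
def toy_cohort(toy_chrom, toy_sources):
    cfg = AdmixtureConfig((1 / 6, 1 / 3, 1 / 2), 12, 20)
    return simulate_admixed(toy_sources, cfg, toy_chrom, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
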
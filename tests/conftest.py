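import warnings

import numpy as np
import pandas as pd
import pytest

from kelpshift.io_formats import GenotypeMatrix
from kelpshift.popgen import allele_frequencies
from kelpshift.synthdata import (
    GenotypeSimConfig,
    LandscapeConfig,
    generate_genotypes,
    generate_landscape,
    generate_sites,
)


@pytest.fixture(scope="session")
def landscape_cfg():
    return LandscapeConfig()


@pytest.fixture(scope="session")
def stacks(landscape_cfg):
    return generate_landscape(landscape_cfg)


@pytest.fixture(scope="session")
def sites(stacks, landscape_cfg):
    present, lgm = stacks
    return generate_sites(present, lgm, landscape_cfg, n_sites=30, seed=2)


@pytest.fixture(scope="session")
def genotypes(sites):
    cfg = GenotypeSimConfig(n_sites=30, individuals_per_site=15, seed=3)
    return generate_genotypes(cfg, sites)


@pytest.fixture(scope="session")
def freqs(genotypes):
    return allele_frequencies(genotypes)


@pytest.fixture
def toy_genotypes():
    """Two sites, two loci, four individuals; hand-checkable counts."""
    rows = []
    # site A: L1 genotypes (1,1), (1,2); L2 all (5,5)
    rows += [("A", "A_1", "L1", 1, 1), ("A", "A_2", "L1", 1, 2)]
    rows += [("A", "A_1", "L2", 5, 5), ("A", "A_2", "L2", 5, 5)]
    # site B: L1 (2,2), (2,3); L2 (5,6), (6,6)
    rows += [("B", "B_1", "L1", 2, 2), ("B", "B_2", "L1", 2, 3)]
    rows += [("B", "B_1", "L2", 5, 6), ("B", "B_2", "L2", 6, 6)]
    df = pd.DataFrame(rows, columns=["site", "individual", "locus", "allele1", "allele2"])
    return GenotypeMatrix(df, ["L1", "L2"])


def brute_force_jost_d(counts_a: dict, counts_b: dict) -> float:
    """Independent single-locus Jost's D oracle from allele-count dicts.

    Mirrors the two-group D_est definition from first principles: harmonic
    mean sample size, Nei-Chesser Hs/Ht, 2x multiplier, clamped at [0, 1].
    """
    alleles = sorted(set(counts_a) | set(counts_b))
    x1 = np.array([counts_a.get(a, 0) for a in alleles], dtype=float)
    x2 = np.array([counts_b.get(a, 0) for a in alleles], dtype=float)
    n1, n2 = x1.sum(), x2.sum()
    p1, p2 = x1 / n1, x2 / n2
    nh = 2.0 / (1.0 / n1 + 1.0 / n2)
    hs = nh / (nh - 1.0) * (1.0 - ((p1**2).sum() + (p2**2).sum()) / 2.0)
    pbar = (p1 + p2) / 2.0
    ht = 1.0 - (pbar**2).sum() + hs / (2.0 * nh)
    if 1.0 - hs <= 0:
        return np.nan
    return float(np.clip((ht - hs) / (1.0 - hs) * 2.0, 0.0, 1.0))


@pytest.fixture
def jost_oracle():
    return brute_force_jost_d


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    """Silence the generators' informational warnings inside tests."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*below rarefaction size.*")
        warnings.filterwarnings("ignore", message=".*autocorrelated up to the maximum.*")
        yield
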
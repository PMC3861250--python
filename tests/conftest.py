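import numpy as np
import pytest

from lrldscan.haplotype_io import GeneticMap, HaplotypeMatrix, Site
from lrldscan.synthetic import SimConfig, simulate


def make_panel(alleles, cms=None, bps=None, chrom="chr1"):
    """Small literal panel helper used across test modules."""
    alleles = np.asarray(alleles, dtype=np.int8)
    n_hap, n_site = alleles.shape
    if cms is None:
        cms = np.arange(n_site, dtype=float)
    if bps is None:
        bps = (np.asarray(cms) * 1_000_000 + 1).astype(int)
    sites = [Site(f"s{k}", int(bps[k]), float(cms[k])) for k in range(n_site)]
    return HaplotypeMatrix(alleles, sites, [f"H{k}" for k in range(n_hap)], chrom)


@pytest.fixture(scope="session")
def mosaic_panel():
    """Seeded 60x300 founder-mosaic background panel (no planted signal)."""
    return simulate(SimConfig(n_hap=60, n_snp=300, seed=11))


@pytest.fixture
def uniform_map():
    """Uniform 1 cM/Mb genetic map spanning 0-50 cM."""
    return GeneticMap(((1, 0.0), (50_000_001, 50.0)))
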
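import numpy as np
import pytest

from grud.haplotype_io import HaplotypePanel, MarkerManifest, VariantSite


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def build_panel(alleles, chrom="1", positions=None, sample_prefix="s"):
    """Construct a HaplotypePanel from a raw allele matrix, recomputing MAF."""
    alleles = np.asarray(alleles, dtype=np.uint8)
    n_hap, n_var = alleles.shape
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_var)]
    sites = []
    for j in range(n_var):
        ac = int(alleles[:, j].sum())
        maf = min(ac, n_hap - ac) / n_hap
        sites.append(VariantSite(chrom, positions[j], "A", "G", maf))
    sample_ids = [f"{sample_prefix}{k}" for k in range(n_hap // 2)]
    return HaplotypePanel(alleles, sites, sample_ids)


@pytest.fixture
def small_panel(rng):
    """10 samples x 12 sites, random but polymorphic."""
    while True:
        alleles = (rng.random((20, 12)) < rng.uniform(0.2, 0.8, 12)).astype(np.uint8)
        s = alleles.sum(axis=0)
        if ((s > 0) & (s < 20)).all():
            return build_panel(alleles)


def manifest_for(panel, observed_cols):
    return MarkerManifest([panel.sites[i].key for i in observed_cols])
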
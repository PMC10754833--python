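"""Synthetic phased panels with controllable LD and MAF spectrum.

Panels are founder mosaics: a small set of founder haplotypes is drawn
i.i.d. per site, and each panel haplotype copies a founder, switching to a
random other founder with `switch_rate` per site, then flipping alleles
with `mutation_rate`. Low switch/mutation rates give long shared segments
(strong LD); mutation_rate 0.5 destroys all signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import HaplotypePanel, MarkerManifest, VariantSite

_BASES = ("A", "C", "G", "T")


@dataclass
class SimConfig:
    n_founders: int = 8
    n_haplotypes: int = 200
    n_sites: int = 500
    switch_rate: float = 0.02
    mutation_rate: float = 0.001
    maf_floor: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even (phased pairs)")
        for name in ("switch_rate", "mutation_rate", "maf_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")


def _make_sites(alleles: np.ndarray, rng: np.random.Generator,
                chrom: str = "1", spacing: int = 100) -> list[VariantSite]:
    n_hap, n_var = alleles.shape
    positions = np.cumsum(rng.integers(1, 2 * spacing, size=n_var))
    sites = []
    for j in range(n_var):
        ref, alt = rng.choice(4, size=2, replace=False)
        ac = int(alleles[:, j].sum())
        maf = min(ac, n_hap - ac) / n_hap
        sites.append(VariantSite(chrom, int(positions[j]), _BASES[ref],
                                 _BASES[alt], maf))
    return sites


def simulate_panel(config: SimConfig, max_retries: int = 20) -> HaplotypePanel:
    """Generate a founder-mosaic HaplotypePanel.

    Founder allele frequencies are Uniform(maf_floor, 0.5); monomorphic
    columns are re-simulated up to `max_retries` sweeps.
    """
    rng = np.random.default_rng(config.seed)
    nf, nh, ns = config.n_founders, config.n_haplotypes, config.n_sites

    def draw_columns(n_cols, col_rng):
        freqs = col_rng.uniform(config.maf_floor, 0.5, size=n_cols)
        return (col_rng.random((nf, n_cols)) < freqs).astype(np.uint8)

    founders = draw_columns(ns, rng)

    # mosaic copying
    choice = np.empty((nh, ns), dtype=np.int64)
    choice[:, 0] = rng.integers(0, nf, size=nh)
    switches = rng.random((nh, ns)) < config.switch_rate
    jumps = rng.integers(1, nf, size=(nh, ns))  # nonzero offset => real switch
    for j in range(1, ns):
        stay = choice[:, j - 1]
        choice[:, j] = np.where(switches[:, j],
                                (stay + jumps[:, j]) % nf, stay)
    alleles = founders[choice, np.arange(ns)]
    flips = rng.random((nh, ns)) < config.mutation_rate
    alleles = (alleles ^ flips).astype(np.uint8)

    for _ in range(max_retries):
        mono = (alleles.sum(axis=0) == 0) | (alleles.sum(axis=0) == nh)
        if not mono.any():
            break
        cols = np.flatnonzero(mono)
        new_founders = draw_columns(len(cols), rng)
        redraw = new_founders[choice[:, cols], np.arange(len(cols))]
        flips = rng.random(redraw.shape) < config.mutation_rate
        alleles[:, cols] = (redraw ^ flips).astype(np.uint8)
    else:
        raise RuntimeError("could not produce a polymorphic panel; "
                           "raise maf_floor or n_haplotypes")

    sites = _make_sites(alleles, rng)
    sample_ids = [f"sim{k:04d}" for k in range(nh // 2)]
    return HaplotypePanel(alleles, sites, sample_ids)


def make_chip_manifest(panel: HaplotypePanel, fraction_observed: float,
                       strategy: str = "uniform", seed: int = 0) -> MarkerManifest:
    """Select floor(fraction * n_sites) panel sites as the observed markers.

    `maf_biased` weights selection by panel MAF (common sites first, as
    array designs do); `uniform` samples without replacement.
    """
    if not 0.0 < fraction_observed < 1.0:
        raise ValueError("fraction_observed must be in (0, 1)")
    if strategy not in ("uniform", "maf_biased"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    n_pick = int(fraction_observed * panel.n_sites)
    if n_pick == 0:
        raise ValueError("selection is empty; raise fraction_observed")
    if strategy == "uniform":
        idx = rng.choice(panel.n_sites, size=n_pick, replace=False)
    else:
        weights = panel.maf + 1e-6
        idx = rng.choice(panel.n_sites, size=n_pick, replace=False,
                         p=weights / weights.sum())
    idx = np.sort(idx)
    return MarkerManifest([panel.sites[i].key for i in idx])


def make_perfect_ld_fixture(n_haplotypes: int, n_blocks: int,
                            sites_per_block: int = 5, seed: int = 0,
                            ) -> tuple[HaplotypePanel, MarkerManifest]:
    """Blocks of one observed site plus `sites_per_block` unobserved sites
    that are exact copies or complements of it; an ideal imputer reaches
    per-variant R^2 = 1.
    """
    if n_blocks < 1:
        raise ValueError("need at least one block")
    rng = np.random.default_rng(seed)
    cols = []
    observed_cols = []
    col = 0
    for _ in range(n_blocks):
        base = (rng.random(n_haplotypes) < rng.uniform(0.2, 0.5)).astype(np.uint8)
        while base.sum() in (0, n_haplotypes):  # keep block polymorphic
            base = (rng.random(n_haplotypes) < 0.5).astype(np.uint8)
        cols.append(base)
        observed_cols.append(col)
        col += 1
        for _ in range(sites_per_block):
            if rng.random() < 0.5:
                cols.append(base.copy())
            else:
                cols.append((1 - base).astype(np.uint8))
            col += 1
    alleles = np.stack(cols, axis=1)
    sites = _make_sites(alleles, rng)
    sample_ids = [f"ld{k:04d}" for k in range(n_haplotypes // 2)]
    panel = HaplotypePanel(alleles, sites, sample_ids)
    manifest = MarkerManifest([panel.sites[i].key for i in observed_cols])
    return panel, manifest
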
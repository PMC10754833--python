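"""Phased VCF I/O, marker manifests, and imputation-region windowing.

Coordinate conventions: VCF positions are 1-based; every in-memory index is
0-based into the panel's site list. Variant identity is the exact
(chrom, pos, ref, alt) key -- allele-swapped records are never auto-flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]


class PhaseError(ValueError):
    """Unphased genotype encountered where phased input is required."""


class VcfParseError(ValueError):
    """The input could not be interpreted as a usable biallelic VCF."""


@dataclass(frozen=True)
class VariantSite:
    """One biallelic site. `maf` is the minor-allele fraction in [0, 0.5]."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    maf: float

    def __post_init__(self):
        if not 0.0 <= self.maf <= 0.5 + 1e-12:
            raise ValueError(f"MAF {self.maf} outside [0, 0.5] at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class HaplotypePanel:
    """Binary allele matrix (haplotypes x variants) with site metadata.

    Rows 2k and 2k+1 are the two phased haplotypes of sample k.
    """

    alleles: np.ndarray
    sites: list[VariantSite]
    sample_ids: list[str]

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-d")
        n_hap, n_var = self.alleles.shape
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError(f"{n_hap} haplotypes but {len(self.sample_ids)} samples")
        if n_var != len(self.sites):
            raise ValueError(f"{n_var} columns but {len(self.sites)} sites")
        if self.alleles.size and self.alleles.max() > 1:
            raise ValueError("allele matrix entries must be 0 or 1")
        keys = [(s.chrom, s.pos) for s in self.sites]
        if any(b <= a for a, b in zip(keys, keys[1:]) if a[0] == b[0]):
            raise ValueError("sites must be strictly sorted by (chrom, pos)")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def maf(self) -> np.ndarray:
        return np.array([s.maf for s in self.sites])

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites])

    def site_keys(self) -> list[VariantKey]:
        return [s.key for s in self.sites]

    def take_sites(self, idx: Sequence[int]) -> "HaplotypePanel":
        idx = list(idx)
        return HaplotypePanel(self.alleles[:, idx],
                              [self.sites[i] for i in idx], list(self.sample_ids))

    def take_samples(self, sample_idx: Sequence[int]) -> "HaplotypePanel":
        hap_idx = np.repeat(np.asarray(sample_idx) * 2, 2) + np.tile([0, 1], len(sample_idx))
        return HaplotypePanel(self.alleles[hap_idx, :], list(self.sites),
                              [self.sample_ids[i] for i in sample_idx])


@dataclass
class MarkerManifest:
    """Set of (chrom, pos, ref, alt) keys designating observed variants."""

    keys: list[VariantKey] = field(default_factory=list)

    def __post_init__(self):
        self._key_set = set(self.keys)

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._key_set

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MarkerManifest":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
        required = {"chrom", "pos", "ref", "alt"}
        if not required.issubset(df.columns):
            raise VcfParseError(f"manifest must have columns {sorted(required)}")
        keys = [(str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
                for r in df.itertuples(index=False)]
        return cls(keys)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.keys, columns=["chrom", "pos", "ref", "alt"]).to_csv(
            path, sep="\t", index=False)


@dataclass
class RegionSpec:
    """One imputation window: core observed sites, flanking observed sites,
    and the unobserved target sites, all as 0-based panel indices."""

    observed_idx: list[int]
    flank_before: list[int]
    flank_after: list[int]
    unobserved_idx: list[int]

    def __post_init__(self):
        for name in ("observed_idx", "flank_before", "flank_after", "unobserved_idx"):
            vals = getattr(self, name)
            if any(b <= a for a, b in zip(vals, vals[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if set(self.observed_idx) & set(self.unobserved_idx):
            raise ValueError("observed and unobserved indices overlap")

    @property
    def input_idx(self) -> list[int]:
        """Observed sites fed to the RNN, flanks included, in position order."""
        return self.flank_before + self.observed_idx + self.flank_after


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

def read_panel(vcf_path: str | Path, require_phased: bool = True,
               missing_policy: str = "error") -> HaplotypePanel:
    """Load a phased biallelic VCF into a HaplotypePanel.

    Multiallelic records are dropped (count logged). Missing genotypes
    either raise (``missing_policy='error'``, default) or drop the whole
    site (``'drop-site'``).
    """
    if missing_policy not in ("error", "drop-site"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad input
        raise VcfParseError(f"cannot open {vcf_path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise VcfParseError(f"{vcf_path} has no samples")

    columns: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str]] = []
    n_multi = n_missing_dropped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gts = np.asarray(var.genotype.array())
        if gts.shape[1] < 3:
            raise VcfParseError(f"record {var.CHROM}:{var.POS} lacks diploid GT")
        a = gts[:, :2]
        phased = gts[:, 2].astype(bool)
        if np.any(a < 0):
            if missing_policy == "error":
                raise VcfParseError(
                    f"missing genotype at {var.CHROM}:{var.POS}; "
                    "use missing_policy='drop-site' to skip such records")
            n_missing_dropped += 1
            continue
        if require_phased and not phased.all():
            raise PhaseError(f"unphased genotype at {var.CHROM}:{var.POS}")
        if a.max() > 1:
            n_multi += 1
            continue
        columns.append(a.reshape(-1).astype(np.uint8))
        meta.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        logger.warning("dropped %d non-biallelic records", n_multi)
    if n_missing_dropped:
        logger.warning("dropped %d records with missing genotypes", n_missing_dropped)
    if not columns:
        raise VcfParseError(f"no usable biallelic records in {vcf_path}")

    order = sorted(range(len(meta)), key=lambda i: (meta[i][0], meta[i][1]))
    alleles = np.stack([columns[i] for i in order], axis=1)
    n_hap = alleles.shape[0]
    sites = []
    for rank, i in enumerate(order):
        chrom, pos, ref, alt = meta[i]
        ac = int(alleles[:, rank].sum())
        maf = min(ac, n_hap - ac) / n_hap
        sites.append(VariantSite(chrom, pos, ref, alt, maf))
    return HaplotypePanel(alleles, sites, sample_ids)


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=grud
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def _open_text(path: str | Path, mode: str = "wt"):
    """Plain or gzip-compressed text handle, keyed on the .gz suffix.

    htslib (cyvcf2, bcftools) reads plain-gzip VCFs transparently.
    """
    if str(path).endswith(".gz"):
        import gzip
        return gzip.open(path, mode)
    return open(path, mode.rstrip("t"))


def write_panel_vcf(panel: HaplotypePanel, out_path: str | Path) -> None:
    """Serialize a panel as a phased VCF (GT only)."""
    chroms = sorted({s.chrom for s in panel.sites})
    with _open_text(out_path) as fh:
        fh.write(_VCF_HEADER)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j, site in enumerate(panel.sites):
            col = panel.alleles[:, j]
            gts = "\t".join(f"{col[2 * k]}|{col[2 * k + 1]}"
                            for k in range(panel.n_samples))
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t"
                     f"{site.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def write_imputed_vcf(sites: Sequence[VariantSite], probabilities: np.ndarray,
                      dosages: np.ndarray, sample_ids: Sequence[str],
                      out_path: str | Path, model_version: str = "0.1.0") -> None:
    """Write imputed targets with GT (per-haplotype argmax, phased),
    DS (dosage, 3 decimals) and GP (P(0/0), P(0/1), P(1/1))."""
    probabilities = np.asarray(probabilities, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    n_samples = len(sample_ids)
    n_sites = len(sites)
    if probabilities.shape != (2 * n_samples, n_sites, 2):
        raise ValueError(f"probabilities shape {probabilities.shape} inconsistent with "
                         f"{n_samples} samples x {n_sites} sites")
    if dosages.shape != (n_samples, n_sites):
        raise ValueError(f"dosage shape {dosages.shape} inconsistent")
    p_alt = probabilities[:, :, 1]
    chroms = sorted({s.chrom for s in sites})
    with _open_text(out_path) as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=grud {model_version}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                 '"Estimated alternate allele dosage">\n')
        fh.write('##FORMAT=<ID=GP,Number=G,Type=Float,Description='
                 '"Genotype probabilities for 0/0, 0/1, 1/1">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        for j, site in enumerate(sites):
            fields = []
            for k in range(n_samples):
                p1, p2 = p_alt[2 * k, j], p_alt[2 * k + 1, j]
                a1, a2 = int(p1 > 0.5), int(p2 > 0.5)  # tie (0.5) -> ref
                p00 = (1 - p1) * (1 - p2)
                p11 = p1 * p2
                p01 = p1 * (1 - p2) + (1 - p1) * p2
                fields.append(f"{a1}|{a2}:{dosages[k, j]:.3f}:"
                              f"{p00:.3f},{p01:.3f},{p11:.3f}")
            fh.write(f"{site.chrom}\t{site.pos}\t.\t{site.ref_allele}\t"
                     f"{site.alt_allele}\t.\tPASS\t.\tGT:DS:GP\t"
                     + "\t".join(fields) + "\n")


def read_dosages(vcf_path: str | Path) -> tuple[list[VariantSite], np.ndarray, list[str]]:
    """Read DS (or, failing that, GT-derived counts) from a VCF.

    Returns (sites, samples x sites dosage matrix, sample ids).
    """
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    sites: list[VariantSite] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            rows.append(np.asarray(ds, dtype=float).reshape(-1))
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            if np.any(gts < 0):
                raise VcfParseError(f"missing genotype at {var.CHROM}:{var.POS}")
            rows.append(gts.sum(axis=1).astype(float))
        sites.append(VariantSite(var.CHROM, var.POS, var.REF, var.ALT[0], 0.0))
    if not sites:
        raise VcfParseError(f"no biallelic records in {vcf_path}")
    return sites, np.stack(rows, axis=1), sample_ids


# ---------------------------------------------------------------------------
# Filtering, splitting, windowing
# ---------------------------------------------------------------------------

def filter_rare(panel: HaplotypePanel, min_maf: float) -> HaplotypePanel:
    """Drop sites with MAF strictly below `min_maf` (boundary retained)."""
    if not 0.0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    keep = [i for i, s in enumerate(panel.sites) if s.maf >= min_maf]
    return panel.take_sites(keep)


def split_observed_unobserved(panel: HaplotypePanel,
                              manifest: MarkerManifest) -> tuple[list[int], list[int]]:
    """Partition panel site indices into (observed, unobserved) by manifest
    membership on the exact (chrom, pos, ref, alt) key."""
    observed, unobserved = [], []
    panel_keys = set()
    for i, site in enumerate(panel.sites):
        panel_keys.add(site.key)
        (observed if site.key in manifest else unobserved).append(i)
    n_foreign = sum(1 for k in manifest.keys if k not in panel_keys)
    if n_foreign:
        logger.warning("%d manifest markers absent from panel (ignored)", n_foreign)
    if not observed:
        raise ValueError("no panel site matches the manifest: nothing to condition on")
    if not unobserved:
        raise ValueError("every panel site is observed: nothing to impute")
    return observed, unobserved


def make_regions(observed_idx: Sequence[int], unobserved_idx: Sequence[int],
                 region_size: int = 1000, flank_size: int = 100) -> list[RegionSpec]:
    """Window the chromosome into consecutive regions of ~`region_size`
    core observed variants each.

    An unobserved site belongs to the region whose first core observed index
    is the largest one <= it (sites before the first observed site go to the
    first region). Flanks extend each core by up to `flank_size` observed
    variants per side; terminal regions get truncated flanks.
    """
    if region_size < 1:
        raise ValueError("region_size must be >= 1")
    if flank_size < 0:
        raise ValueError("flank_size must be >= 0")
    obs = list(observed_idx)
    unobs = list(unobserved_idx)
    if not obs:
        raise ValueError("no observed variants")
    starts = list(range(0, len(obs), region_size))
    boundaries = [obs[s] for s in starts]  # first core index of each region
    regions: list[RegionSpec] = []
    for r, s in enumerate(starts):
        e = min(s + region_size, len(obs))
        core = obs[s:e]
        before = obs[max(0, s - flank_size):s]
        after = obs[e:e + flank_size]
        lo = boundaries[r]
        hi = boundaries[r + 1] if r + 1 < len(boundaries) else np.inf
        if r == 0:
            members = [u for u in unobs if u < hi]
        else:
            members = [u for u in unobs if lo <= u < hi]
        regions.append(RegionSpec(core, before, after, members))
    return regions
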
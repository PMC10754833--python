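"""Apply a trained checkpoint to new observed genotypes.

Inference is reference-free: everything needed (weights, observed-site
keys, target-site metadata) lives in the checkpoint. Regional outputs are
concatenated in genomic-position order and per-sample dosages assembled as
the sum of the two haplotypes' alternate-allele probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .haplotype_io import (HaplotypePanel, VariantSite, read_panel,
                           write_imputed_vcf)
from .model_core import one_hot_encode
from .training import Checkpoint


@dataclass
class DosageMatrix:
    """Expected alternate-allele counts, samples x sites, each in [0, 2]."""

    dosages: np.ndarray
    sites: list[VariantSite]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.sites):
            raise ValueError("dosage matrix misaligned with site metadata")
        if self.dosages.size and (self.dosages.min() < -1e-9
                                  or self.dosages.max() > 2 + 1e-9):
            raise ValueError("dosages must lie in [0, 2]")


@dataclass
class ImputationResult:
    sites: list[VariantSite]
    probabilities: np.ndarray  # (n_haplotypes, n_sites, 2)
    dosages: DosageMatrix
    sample_ids: list[str]

    def write_vcf(self, out_path: str | Path) -> None:
        write_imputed_vcf(self.sites, self.probabilities, self.dosages.dosages,
                          self.sample_ids, out_path)


def concat_regions(region_outputs: list[tuple[list[VariantSite], np.ndarray]],
                   ) -> tuple[list[VariantSite], np.ndarray]:
    """Merge per-region (sites, probabilities) into chromosome-wide output
    ordered by genomic position. Regions must cover disjoint site sets."""
    if not region_outputs:
        raise ValueError("no region outputs to concatenate")
    seen = set()
    for sites, _ in region_outputs:
        keys = {s.key for s in sites}
        if keys & seen:
            raise ValueError("regions overlap on unobserved sites")
        seen |= keys
    all_sites = [s for sites, _ in region_outputs for s in sites]
    probs = np.concatenate([p for _, p in region_outputs], axis=1)
    order = sorted(range(len(all_sites)),
                   key=lambda i: (all_sites[i].chrom, all_sites[i].pos))
    return [all_sites[i] for i in order], probs[:, order, :]


def _soft_observed(checkpoint: Checkpoint, target: HaplotypePanel,
                   missing_policy: str) -> np.ndarray:
    """Build the (n_haplotypes, n_observed, 2) soft one-hot input matrix,
    matching target columns to checkpoint observed keys exactly."""
    key_to_col = {s.key: j for j, s in enumerate(target.sites)}
    n_hap = target.n_haplotypes
    n_obs = len(checkpoint.observed_keys)
    enc = np.empty((n_hap, n_obs, 2), dtype=np.float64)
    missing = []
    for r, key in enumerate(checkpoint.observed_keys):
        col = key_to_col.get(key)
        if col is None:
            missing.append(key)
            freq = checkpoint.observed_freq[r]
            enc[:, r, 0] = 1.0 - freq
            enc[:, r, 1] = freq
        else:
            enc[:, r, :] = one_hot_encode(target.alleles[:, col])
    if missing and missing_policy == "error":
        preview = ", ".join(f"{c}:{p}" for c, p, *_ in missing[:5])
        raise ValueError(
            f"{len(missing)} checkpoint markers absent from target (e.g. {preview}); "
            "pass missing_policy='mean' to fill them with panel frequencies")
    return enc


def impute(checkpoint: Checkpoint, target: HaplotypePanel | str | Path,
           missing_policy: str = "error") -> ImputationResult:
    """Impute all checkpoint target sites for new samples.

    `target` is a phased panel (or VCF path) containing the observed
    markers; its variant keys must match the checkpoint's observed-site
    keys. Markers missing from the target are an error by default, or
    mean-imputed from training-panel frequencies with a warning
    (``missing_policy='mean'``).
    """
    if missing_policy not in ("error", "mean"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    if not isinstance(target, HaplotypePanel):
        target = read_panel(target)
    enc = _soft_observed(checkpoint, target, missing_policy)
    outputs = []
    with nn.no_grad():
        for rm in checkpoint.regions:
            rm.generator.eval()
            region_enc = enc[:, rm.input_obs_rank, :]
            probs = rm.generator.forward_encoded(region_enc)
            outputs.append((rm.target_sites, probs.data))
    sites, probs = concat_regions(outputs)
    p_alt = probs[:, :, 1]
    dosages = p_alt[0::2, :] + p_alt[1::2, :]
    return ImputationResult(sites, probs, DosageMatrix(dosages, sites),
                            list(target.sample_ids))
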
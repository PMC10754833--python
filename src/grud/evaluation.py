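"""Dosage R-squared evaluation: squared Pearson correlation between imputed
dosages and true genotype counts, in two aggregations plus MAF-binned
curves.

Overall R^2 pools every (sample, site) pair into one correlation; average
R^2 per variant scores each site's column separately and averages. Sites
whose truth or dosage column has zero variance have an undefined
correlation and are excluded from the per-variant average (the exclusion
count is reported, never silently folded in as 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_BIN_EDGES = (0.005, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5)


def r_squared(x, y) -> float:
    """Squared Pearson correlation; NaN sentinel when either input is
    constant (correlation undefined)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if (x == x[0]).all() or (y == y[0]).all():
        return float("nan")
    dx = x - x.mean()
    dy = y - y.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0 or syy == 0.0:
        return float("nan")
    sxy = float(dx @ dy)
    return (sxy * sxy) / (sxx * syy)


def overall_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """One pooled R^2 over all (sample, site) entries flattened."""
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dosages.shape != truth.shape:
        raise ValueError(f"shape mismatch: {dosages.shape} vs {truth.shape}")
    return r_squared(dosages.ravel(), truth.ravel())


def average_r2_per_variant(dosages: np.ndarray, truth: np.ndarray,
                           return_excluded: bool = False):
    """Mean of per-site R^2 over sites where it is defined.

    Zero-variance sites are excluded; their count is available via
    `return_excluded=True`. Raises if every site is excluded.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dosages.shape != truth.shape:
        raise ValueError(f"shape mismatch: {dosages.shape} vs {truth.shape}")
    if dosages.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    values = np.array([r_squared(dosages[:, j], truth[:, j])
                       for j in range(dosages.shape[1])])
    defined = ~np.isnan(values)
    if not defined.any():
        raise ValueError("per-variant R^2 undefined at every site")
    mean = float(values[defined].mean())
    n_excluded = int((~defined).sum())
    return (mean, n_excluded) if return_excluded else mean


@dataclass
class MafBin:
    low: float   # exclusive
    high: float  # inclusive
    r2: float | None
    n_variants: int


def maf_binned_r2(dosages: np.ndarray, truth: np.ndarray, panel_maf,
                  bin_edges=DEFAULT_BIN_EDGES) -> list[MafBin]:
    """Pooled R^2 per MAF bin, sites keyed by training-panel MAF.

    Bins are left-open, right-closed intervals between consecutive edges.
    Empty bins are recorded with n=0 and no R^2.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    panel_maf = np.asarray(panel_maf, dtype=float)
    if dosages.shape != truth.shape or dosages.shape[1] != panel_maf.size:
        raise ValueError("dosages, truth and panel_maf misaligned")
    edges = sorted(bin_edges)
    bins = []
    for low, high in zip(edges[:-1], edges[1:]):
        members = np.flatnonzero((panel_maf > low) & (panel_maf <= high))
        if members.size == 0:
            bins.append(MafBin(low, high, None, 0))
            continue
        r2 = r_squared(dosages[:, members].ravel(), truth[:, members].ravel())
        bins.append(MafBin(low, high, None if np.isnan(r2) else float(r2),
                           int(members.size)))
    return bins


@dataclass
class EvalReport:
    overall_r2: float
    average_r2_per_variant: float
    n_excluded_sites: int
    per_bin: list[MafBin]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("metric\tmaf_low\tmaf_high\tr2\tn_variants\n")
            fh.write(f"overall\t\t\t{self.overall_r2:.6f}\t\n")
            fh.write(f"average_per_variant\t\t\t{self.average_r2_per_variant:.6f}\t\n")
            fh.write(f"excluded_sites\t\t\t\t{self.n_excluded_sites}\n")
            for b in self.per_bin:
                r2 = "" if b.r2 is None else f"{b.r2:.6f}"
                fh.write(f"maf_bin\t{b.low}\t{b.high}\t{r2}\t{b.n_variants}\n")


def evaluate(dosages: np.ndarray, truth: np.ndarray, panel_maf,
             bin_edges=DEFAULT_BIN_EDGES) -> EvalReport:
    avg, n_excluded = average_r2_per_variant(dosages, truth, return_excluded=True)
    return EvalReport(
        overall_r2=overall_r2(dosages, truth),
        average_r2_per_variant=avg,
        n_excluded_sites=n_excluded,
        per_bin=maf_binned_r2(dosages, truth, panel_maf, bin_edges),
    )
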
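"""Generator and discriminator networks plus their loss functions.

The generator maps one-hot encoded observed haplotype alleles through a
sequential feature layer (linear -> LeakyReLU -> batch norm), a stack of
bidirectional GRU layers with residual skip-connections, and a per-target
2-class read-out followed by softmax. Each unobserved site sitting between
observed neighbours i and i+1 is predicted from the concatenation of the
forward output at i and the backward output at i+1.

The discriminator scores a vector of per-site alternate-allele
probabilities (one haplotype's worth of unobserved sites) with two stacked
linear layers and a softmax, returning the probability that the vector came
from a real panel haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.autograd import Tensor, as_tensor

#: probability clamp inside both cross-entropy losses (log(0) guard)
EPS_PROB = 1e-7


@dataclass(frozen=True)
class LossValue:
    """Joint loss decomposition; `total` is exactly the sum l_d + l_g."""

    l_g: float
    l_d: float

    @property
    def total(self) -> float:
        return self.l_d + self.l_g


@dataclass
class GeneratorConfig:
    hidden_units: int = 40
    num_layers: int = 8
    feature_size: int = 50
    leaky_slope: float = 0.01
    gamma: float = 0.0  # >0: favour high MAF; <0: favour low MAF; 0: no weighting

    def __post_init__(self):
        if self.hidden_units < 1 or self.num_layers < 1 or self.feature_size < 1:
            raise ValueError("hidden_units, num_layers and feature_size must be >= 1")


def one_hot_encode(haplotypes: np.ndarray) -> np.ndarray:
    """Encode binary alleles as 2-vectors: 0 -> (1,0), 1 -> (0,1).

    Works on any shape; the encoding axis is appended last.
    """
    arr = np.asarray(haplotypes)
    if arr.size and not np.isin(arr, (0, 1)).all():
        raise ValueError("haplotype alleles must be 0 or 1")
    out = np.zeros(arr.shape + (2,), dtype=np.float64)
    if arr.size:
        out[..., 0] = arr == 0
        out[..., 1] = arr == 1
    return out


def generator_softmax(logits):
    """Softmax over the final (2-class) axis, numerically stabilized."""
    t = nn.softmax(as_tensor(logits), axis=-1)
    return t if isinstance(logits, Tensor) else t.data


class Generator(nn.Module):
    """Region-level imputation network.

    Built for a fixed region geometry: `input_positions` are the genomic
    positions of the observed (core + flank) sites in order, and
    `target_positions` those of the unobserved sites to predict.
    """

    def __init__(self, input_positions, target_positions,
                 config: GeneratorConfig, rng: np.random.Generator):
        input_positions = np.asarray(input_positions)
        target_positions = np.asarray(target_positions)
        if len(input_positions) < 2:
            raise ValueError("a region needs at least 2 observed variants")
        if len(target_positions) == 0:
            raise ValueError("a region needs at least 1 unobserved variant")
        if np.any(np.diff(input_positions) <= 0):
            raise ValueError("input positions must be strictly increasing")
        self.config = config
        H, F = config.hidden_units, config.feature_size
        self.feature_linear = nn.Linear(2, F, rng)
        self.feature_norm = nn.BatchNorm1d(F)
        fwd, bwd = [], []
        for layer in range(config.num_layers):
            in_size = F if layer == 0 else 2 * H
            fwd.append(nn.GRULayer(in_size, H, rng))
            bwd.append(nn.GRULayer(in_size, H, rng))
        self.gru_forward = fwd
        self.gru_backward = bwd
        self.out_layer = nn.SiteLinear(len(target_positions), 2 * H, rng)
        # gap g for target u: largest observed index with pos < pos_u,
        # clamped so both a forward (g) and backward (g+1) output exist
        gaps = np.searchsorted(input_positions, target_positions) - 1
        self.target_gaps = np.clip(gaps, 0, len(input_positions) - 2)
        self.n_inputs = len(input_positions)
        self.n_targets = len(target_positions)

    # -- pipeline stages ---------------------------------------------------
    def sequential_features(self, encoded) -> Tensor:
        """Linear -> LeakyReLU -> batch norm, applied per variant position."""
        x = as_tensor(encoded)
        B, T, _ = x.shape
        flat = x.reshape((B * T, 2))
        flat = self.feature_linear(flat)
        flat = nn.leaky_relu(flat, self.config.leaky_slope)
        flat = self.feature_norm(flat)
        return flat.reshape((B, T, self.config.feature_size))

    def bigru_impute(self, features: Tensor) -> Tensor:
        """Stacked bidirectional GRU with residual skips, then the
        per-target linear read-out. Returns (batch, n_targets, 2) logits."""
        H = self.config.hidden_units
        state = features
        for layer, (f, b) in enumerate(zip(self.gru_forward, self.gru_backward)):
            out = nn.concat([f(state), b(state, reverse=True)], axis=2)
            state = out if layer == 0 else out + state  # residual skip (l > 1)
        fwd_half = state[:, :-1, :H]
        bwd_half = state[:, 1:, H:]
        pair_feats = nn.concat([fwd_half, bwd_half], axis=2)  # (B, T-1, 2H)
        gathered = pair_feats[:, self.target_gaps, :]
        return self.out_layer(gathered)

    def forward(self, hap_alleles: np.ndarray) -> Tensor:
        """Observed alleles (batch x n_inputs, binary) -> allele
        probabilities (batch x n_targets x 2)."""
        encoded = self.encode(hap_alleles)
        return self.forward_encoded(encoded)

    def encode(self, hap_alleles: np.ndarray) -> np.ndarray:
        arr = np.asarray(hap_alleles)
        if arr.ndim != 2 or arr.shape[1] != self.n_inputs:
            raise ValueError(f"expected (batch, {self.n_inputs}) observed alleles, "
                             f"got {arr.shape}")
        return one_hot_encode(arr)

    def forward_encoded(self, encoded) -> Tensor:
        feats = self.sequential_features(encoded)
        logits = self.bigru_impute(feats)
        return generator_softmax(logits)


class Discriminator(nn.Module):
    """Two stacked linear layers with a LeakyReLU between, then softmax."""

    def __init__(self, n_unobserved: int, rng: np.random.Generator,
                 hidden_units: int = 64, leaky_slope: float = 0.01):
        self.layer1 = nn.Linear(n_unobserved, hidden_units, rng)
        self.layer2 = nn.Linear(hidden_units, 2, rng)
        self.leaky_slope = leaky_slope
        self.n_unobserved = n_unobserved

    def forward(self, alt_probs) -> Tensor:
        """Alt-probability vectors (batch x n_unobserved) -> p(real), shape
        (batch,). Column 1 of the softmax is the "real" class."""
        x = as_tensor(alt_probs)
        if x.ndim != 2 or x.shape[1] != self.n_unobserved:
            raise ValueError(f"expected (batch, {self.n_unobserved}) input, got {x.shape}")
        h = nn.leaky_relu(self.layer1(x), self.leaky_slope)
        probs = nn.softmax(self.layer2(h), axis=-1)
        return probs[:, 1]


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _bce_terms(labels: np.ndarray, probs: Tensor) -> Tensor:
    p = nn.clip(probs, EPS_PROB, 1.0 - EPS_PROB)
    return labels * nn.log(p) + (1.0 - labels) * nn.log(1.0 - p)


def maf_weights(maf: np.ndarray, gamma: float,
                maf_floor: float | None = None) -> np.ndarray:
    """Per-site loss weights (2 * MAF)^gamma.

    With gamma < 0 a zero MAF gives an infinite weight; such sites must be
    filtered upstream or clipped via `maf_floor`.
    """
    maf = np.asarray(maf, dtype=float)
    if np.any(maf < 0) or np.any(maf > 0.5):
        raise ValueError("MAF values must lie in [0, 0.5]")
    if maf_floor is not None:
        maf = np.maximum(maf, maf_floor)
    if gamma < 0 and np.any(maf == 0):
        raise ValueError("gamma < 0 with MAF = 0 gives infinite weight; "
                         "filter rare sites or set maf_floor")
    return (2.0 * maf) ** gamma


def generator_loss(z, z_hat, maf, gamma: float = 0.0,
                   maf_floor: float | None = None):
    """MAF-weighted binary cross entropy over unobserved sites.

        L_G = -(1/N) sum_i (2 MAF_i)^gamma [z_i log zh_i + (1-z_i) log(1-zh_i)]

    averaged over the haplotypes in the batch. `z` are binary true alleles
    (batch x N), `z_hat` predicted alt probabilities (batch x N).
    """
    z = np.asarray(z, dtype=float)
    if z.size and not np.isin(z, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    zh = as_tensor(z_hat)
    if zh.shape != z.shape:
        raise ValueError(f"shape mismatch: labels {z.shape}, predictions {zh.shape}")
    w = maf_weights(maf, gamma, maf_floor)
    n_sites = z.shape[-1]
    terms = w * _bce_terms(z, zh)
    loss = -terms.sum() * (1.0 / (n_sites * max(z.size // n_sites, 1)))
    return loss if isinstance(z_hat, Tensor) else float(loss.data)


def discriminator_loss(p, p_hat):
    """Mean binary cross entropy of real/fake labels `p` against predicted
    real-probabilities `p_hat`."""
    p = np.asarray(p, dtype=float)
    if p.size and not np.isin(p, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    ph = as_tensor(p_hat)
    if ph.shape != p.shape:
        raise ValueError(f"shape mismatch: labels {p.shape}, predictions {ph.shape}")
    loss = -_bce_terms(p, ph).mean()
    return loss if isinstance(p_hat, Tensor) else float(loss.data)


def total_loss(l_g, l_d):
    """Joint objective: L = L_D + L_G."""
    if isinstance(l_g, Tensor) or isinstance(l_d, Tensor):
        return as_tensor(l_d) + as_tensor(l_g)
    return l_d + l_g
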
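"""Network layers built on the autograd engine.

The GRU layer and batch normalization are fused operations: a single graph
node whose backward pass is derived by hand and vectorized over the batch.
This keeps the tape short (one node per layer instead of one per timestep),
which is what makes CPU training of stacked bidirectional GRUs tractable.

GRU cell convention (update gate multiplies the candidate state):

    z_t = sigmoid(x_t W_z + a_{t-1} U_z + b_z)      # update gate
    r_t = sigmoid(x_t W_r + a_{t-1} U_r + b_r)      # reset gate
    n_t = tanh(x_t W_n + r_t * (a_{t-1} U_n) + b_n) # candidate state
    a_t = z_t * n_t + (1 - z_t) * a_{t-1}

so a zero update gate carries the hidden state through unchanged, and with
all weights and biases zero every gate evaluates to exactly 0.5.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, _node, grad_enabled


def _rng_uniform(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    return rng.uniform(-scale, scale, size=shape)


class Module:
    """Tiny container protocol: children found by attribute scan."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        params.append(item)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self.training = True
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train()

    def eval(self) -> None:
        self.training = False
        for value in vars(self).values():
            if isinstance(value, Module):
                value.eval()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.eval()

    # -- flat state for checkpointing --------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        """All arrays (parameters + buffers) in a stable order."""
        arrays: list[np.ndarray] = []
        for value in vars(self).values():
            if isinstance(value, Tensor):
                arrays.append(value.data)
            elif isinstance(value, Module):
                arrays.extend(value.state_arrays())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        arrays.extend(item.state_arrays())
                    elif isinstance(item, Tensor):
                        arrays.append(item.data)
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        slots = self.state_arrays()
        if len(slots) != len(arrays):
            raise ValueError(
                f"state mismatch: model has {len(slots)} arrays, checkpoint has {len(arrays)}")
        for slot, arr in zip(slots, arrays):
            if slot.shape != arr.shape:
                raise ValueError(f"array shape mismatch: {slot.shape} vs {arr.shape}")
            slot[...] = arr


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(_rng_uniform(rng, (in_features, out_features), scale),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm1d(Module):
    """Normalize each feature over axis 0 of a 2-d input.

    Training mode uses batch statistics (and requires >= 2 rows); eval mode
    uses exponential running statistics.
    """

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(num_features), requires_grad=True)
        self.beta = Tensor(np.zeros(num_features), requires_grad=True)
        self.running_mean = Tensor(np.zeros(num_features))
        self.running_var = Tensor(np.ones(num_features))
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 2:
            raise ValueError("BatchNorm1d expects a 2-d (rows x features) input")
        gamma, beta = self.gamma, self.beta
        if self.training:
            if x.shape[0] < 2:
                raise ValueError(
                    "batch normalization in training mode needs at least 2 rows")
            mu = x.data.mean(axis=0)
            var = x.data.var(axis=0)
            m = self.momentum
            self.running_mean.data[...] = (1 - m) * self.running_mean.data + m * mu
            # unbiased variance for the running estimate, as torch does
            n = x.shape[0]
            self.running_var.data[...] = (
                (1 - m) * self.running_var.data + m * var * n / max(n - 1, 1))
        else:
            mu = self.running_mean.data
            var = self.running_var.data
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mu) * inv_std
        out_data = gamma.data * xhat + beta.data
        training = self.training

        def backward(g):
            gamma._accumulate((g * xhat).sum(axis=0))
            beta._accumulate(g.sum(axis=0))
            if training:
                n_rows = g.shape[0]
                gy = g * gamma.data
                dx = (inv_std / n_rows) * (
                    n_rows * gy - gy.sum(axis=0) - xhat * (gy * xhat).sum(axis=0))
            else:
                dx = g * gamma.data * inv_std
            x._accumulate(dx)

        return _node(out_data, (x, gamma, beta), backward)


class GRULayer(Module):
    """One unidirectional GRU over a (batch, time, features) sequence.

    Forward caches gate activations; backward is classic BPTT with the
    per-timestep work reduced to one matmul plus pointwise ops, and all
    weight gradients accumulated in single batched matmuls at the end.
    Gate blocks in the fused weight matrices are ordered [z | r | n].
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(hidden_size)
        self.w_ih = Tensor(_rng_uniform(rng, (input_size, 3 * hidden_size), scale),
                           requires_grad=True)
        self.w_hh = Tensor(_rng_uniform(rng, (hidden_size, 3 * hidden_size), scale),
                           requires_grad=True)
        self.bias = Tensor(np.zeros(3 * hidden_size), requires_grad=True)
        self.hidden_size = hidden_size
        self.input_size = input_size

    def __call__(self, x: Tensor, reverse: bool = False) -> Tensor:
        """Run the recurrence; `reverse` scans time back-to-front.

        Output at position t is the hidden state after consuming position t
        (so in reverse mode it summarizes positions t..T-1).
        """
        H = self.hidden_size
        w_ih, w_hh, bias = self.w_ih, self.w_hh, self.bias
        data = x.data
        if reverse:
            data = data[:, ::-1, :]
        B, T, _ = data.shape

        xw = data.reshape(B * T, -1) @ w_ih.data + bias.data
        xw = xw.reshape(B, T, 3 * H)

        h = np.zeros((B, H), dtype=data.dtype)
        Z = np.empty((T, B, H), dtype=data.dtype)
        R = np.empty_like(Z)
        N = np.empty_like(Z)
        HU = np.empty_like(Z)     # a_{t-1} @ U_n, before reset gating
        Hprev = np.empty_like(Z)
        out = np.empty((B, T, H), dtype=data.dtype)
        U = w_hh.data
        for t in range(T):
            hu_all = h @ U                      # (B, 3H): [z | r | n] blocks
            pre = xw[:, t, :2 * H] + hu_all[:, :2 * H]
            zr = 1.0 / (1.0 + np.exp(-pre))
            z, r = zr[:, :H], zr[:, H:]
            hu = hu_all[:, 2 * H:]
            n = np.tanh(xw[:, t, 2 * H:] + r * hu)
            Hprev[t] = h
            h = z * n + (1.0 - z) * h
            Z[t], R[t], N[t], HU[t] = z, r, n, hu
            out[:, t, :] = h
        if reverse:
            out = out[:, ::-1, :]

        if not (grad_enabled() and (x.requires_grad or x._parents or w_ih.requires_grad)):
            return Tensor(out.copy() if reverse else out)

        def backward(g):
            gseq = g[:, ::-1, :] if reverse else g
            dh = np.zeros((B, H), dtype=data.dtype)
            dG = np.empty((T, B, 3 * H), dtype=data.dtype)   # d pre-act [z|r|n]
            dGU = np.empty_like(dG)                          # [dz|dr|dhu] for U path
            Ut = U.T
            for t in range(T - 1, -1, -1):
                dht = gseq[:, t, :] + dh
                z, r, n, hu, hp = Z[t], R[t], N[t], HU[t], Hprev[t]
                dz = dht * (n - hp) * z * (1.0 - z)
                dn = dht * z * (1.0 - n * n)
                dr = dn * hu * r * (1.0 - r)
                dhu = dn * r
                dG[t, :, :H], dG[t, :, H:2 * H], dG[t, :, 2 * H:] = dz, dr, dn
                dGU[t, :, :H], dGU[t, :, H:2 * H], dGU[t, :, 2 * H:] = dz, dr, dhu
                dh = dht * (1.0 - z) + dGU[t] @ Ut
            flatG = dG.transpose(1, 0, 2).reshape(B * T, 3 * H)
            w_ih._accumulate(data.reshape(B * T, -1).T @ flatG)
            bias._accumulate(flatG.sum(axis=0))
            w_hh._accumulate(
                Hprev.reshape(T * B, H).T @ dGU.reshape(T * B, 3 * H))
            dx = (flatG @ w_ih.data.T).reshape(B, T, -1)
            if reverse:
                dx = dx[:, ::-1, :]
            x._accumulate(np.ascontiguousarray(dx))

        return _node(out.copy() if reverse else out, (x, w_ih, w_hh, bias), backward)


class SiteLinear(Module):
    """Independent 2-class linear read-out per target site.

    logits[b, u, :] = features[b, u, :] @ weight[u] + bias[u]
    """

    def __init__(self, n_sites: int, in_features: int, rng: np.random.Generator):
        scale = 1.0 / np.sqrt(in_features)
        self.weight = Tensor(_rng_uniform(rng, (n_sites, in_features, 2), scale),
                             requires_grad=True)
        self.bias = Tensor(np.zeros((n_sites, 2)), requires_grad=True)
        self.n_sites = n_sites

    def __call__(self, feats: Tensor) -> Tensor:
        weight, bias = self.weight, self.bias
        out_data = np.einsum("buk,uko->buo", feats.data, weight.data) + bias.data

        def backward(g):
            weight._accumulate(np.einsum("buk,buo->uko", feats.data, g))
            bias._accumulate(g.sum(axis=0))
            feats._accumulate(np.einsum("buo,uko->buk", g, weight.data))

        return _node(out_data, (feats, weight, bias), backward)
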
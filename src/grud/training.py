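"""GAN-style training loop: alternating discriminator/generator updates per
batch of haplotypes, one generator+discriminator pair per imputation region.

Defaults: batch size 128, up to 100 epochs, Adam at 1e-3 with exponential
decay per epoch, early stopping. Early
stopping watches the validation generator loss (patience 10) on a held-out
sample split; the best-validation weights are restored into the returned
checkpoint. Every source of randomness (weight init, holdout split, batch
shuffling) derives from the single seed in TrainConfig.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .haplotype_io import (HaplotypePanel, MarkerManifest, RegionSpec, VariantSite,
                           make_regions, split_observed_unobserved)
from .model_core import (Discriminator, Generator, GeneratorConfig,
                         discriminator_loss, generator_loss, total_loss)

logger = logging.getLogger(__name__)

CHECKPOINT_VERSION = 1


def compute_maf(panel: HaplotypePanel) -> np.ndarray:
    """Per-site minor allele fraction: min(c, H - c) / H over H haplotypes."""
    if panel.n_sites == 0:
        raise ValueError("empty panel")
    counts = panel.alleles.sum(axis=0).astype(float)
    h = panel.n_haplotypes
    return np.minimum(counts, h - counts) / h


@dataclass
class TrainConfig:
    batch_size: int = 128
    max_epochs: int = 100
    learning_rate: float = 0.001
    lr_decay: float = 0.98
    early_stop_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0
    region_size: int = 1000
    flank_size: int = 100
    disc_hidden: int = 64
    adversarial_g_term: bool = False  # True: non-saturating GAN loss for G

    def __post_init__(self):
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must be in (0, 1]")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must be in [0, 1)")


@dataclass
class TrainState:
    epoch: int = 0
    g_loss: list[float] = field(default_factory=list)
    d_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_val: float = np.inf
    best_epoch: int = -1
    epochs_since_best: int = 0


@dataclass
class RegionModel:
    """One trained region: its geometry plus the generator weights."""

    input_obs_rank: list[int]      # indices into the chromosome-wide observed list
    input_positions: list[int]
    target_sites: list[VariantSite]  # metadata incl. training-panel MAF
    generator: Generator


class Checkpoint:
    """Self-describing bundle: weights + configs + site metadata, so a
    pre-trained model can impute new samples without panel access."""

    def __init__(self, gen_config: GeneratorConfig, train_config: TrainConfig,
                 observed_keys: list, observed_freq: np.ndarray,
                 regions: list[RegionModel], seed: int):
        self.version = CHECKPOINT_VERSION
        self.gen_config = gen_config
        self.train_config = train_config
        self.observed_keys = observed_keys
        self.observed_freq = np.asarray(observed_freq, dtype=float)
        self.regions = regions
        self.seed = seed

    def save(self, path: str | Path) -> None:
        meta = {
            "version": self.version,
            "seed": self.seed,
            "gen_config": asdict(self.gen_config),
            "train_config": asdict(self.train_config),
            "observed_keys": [list(k) for k in self.observed_keys],
            "regions": [
                {
                    "input_obs_rank": rm.input_obs_rank,
                    "input_positions": rm.input_positions,
                    "target_sites": [[s.chrom, s.pos, s.ref_allele, s.alt_allele, s.maf]
                                     for s in rm.target_sites],
                }
                for rm in self.regions
            ],
        }
        arrays = {"observed_freq": self.observed_freq}
        for r, rm in enumerate(self.regions):
            for i, arr in enumerate(rm.generator.state_arrays()):
                arrays[f"r{r}_a{i}"] = arr
        buf = io.BytesIO()
        np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        Path(path).write_bytes(buf.getvalue())

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta["version"] != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta['version']}")
            gen_config = GeneratorConfig(**meta["gen_config"])
            train_config = TrainConfig(**meta["train_config"])
            dummy_rng = np.random.default_rng(0)
            regions = []
            for r, rmeta in enumerate(meta["regions"]):
                target_sites = [VariantSite(c, p, ref, alt, maf)
                                for c, p, ref, alt, maf in rmeta["target_sites"]]
                gen = Generator(rmeta["input_positions"],
                                [s.pos for s in target_sites], gen_config, dummy_rng)
                arrays = []
                i = 0
                while f"r{r}_a{i}" in data:
                    arrays.append(data[f"r{r}_a{i}"])
                    i += 1
                gen.load_state_arrays(arrays)
                gen.eval()
                regions.append(RegionModel(rmeta["input_obs_rank"],
                                           rmeta["input_positions"],
                                           target_sites, gen))
            observed_keys = [tuple(k) for k in meta["observed_keys"]]
            return cls(gen_config, train_config, observed_keys,
                       data["observed_freq"], regions, meta["seed"])


def _sample_split(n_samples: int, fraction: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Holdout split by sample so both haplotypes of a sample stay together."""
    n_val = int(round(fraction * n_samples))
    perm = rng.permutation(n_samples)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _hap_rows(sample_idx: np.ndarray) -> np.ndarray:
    return np.repeat(sample_idx * 2, 2) + np.tile([0, 1], len(sample_idx))


def _region_eval_loss(gen: Generator, x: np.ndarray, z: np.ndarray,
                      maf: np.ndarray, gamma: float) -> float:
    was_training = gen.training
    gen.eval()
    with nn.no_grad():
        probs = gen.forward(x)
        loss = generator_loss(z, probs.data[:, :, 1], maf, gamma)
    if was_training:
        gen.train()
    return float(loss)


def train(panel: HaplotypePanel, manifest: MarkerManifest,
          gen_config: GeneratorConfig | None = None,
          train_config: TrainConfig | None = None,
          log_path: str | Path | None = None) -> tuple[Checkpoint, TrainState]:
    """Train one generator/discriminator pair per region.

    Per batch: (1) one discriminator step on real panel slices (label 1)
    vs detached generated slices (label 0); (2) one generator step on the
    joint objective L = L_D + L_G with the discriminator's parameters held
    fixed. Learning rate is multiplied by `lr_decay` each epoch.
    """
    gen_config = gen_config or GeneratorConfig()
    train_config = train_config or TrainConfig()
    rng = np.random.default_rng(train_config.seed)
    init_rng = np.random.default_rng(rng.integers(2**63))
    split_rng = np.random.default_rng(rng.integers(2**63))
    shuffle_rng = np.random.default_rng(rng.integers(2**63))

    observed_idx, unobserved_idx = split_observed_unobserved(panel, manifest)
    regions = make_regions(observed_idx, unobserved_idx,
                           train_config.region_size, train_config.flank_size)
    regions = [r for r in regions if r.unobserved_idx]
    if not regions:
        raise ValueError("no region has unobserved targets")
    maf = compute_maf(panel)
    positions = panel.positions

    train_s, val_s = _sample_split(panel.n_samples,
                                   train_config.validation_fraction, split_rng)
    if len(val_s) == 0 and train_config.validation_fraction > 0:
        logger.warning("validation split empty; early stopping uses training loss")
    train_rows = _hap_rows(train_s)
    val_rows = _hap_rows(val_s)

    obs_rank = {idx: r for r, idx in enumerate(observed_idx)}
    gens: list[Generator] = []
    discs: list[Discriminator] = []
    g_opts: list[nn.Adam] = []
    d_opts: list[nn.Adam] = []
    region_data = []
    for region in regions:
        inp = region.input_idx
        gen = Generator(positions[inp], positions[region.unobserved_idx],
                        gen_config, init_rng)
        disc = Discriminator(len(region.unobserved_idx), init_rng,
                             train_config.disc_hidden, gen_config.leaky_slope)
        gens.append(gen)
        discs.append(disc)
        g_opts.append(nn.Adam(gen.parameters(), train_config.learning_rate))
        d_opts.append(nn.Adam(disc.parameters(), train_config.learning_rate))
        region_data.append({
            "x_train": panel.alleles[np.ix_(train_rows, inp)],
            "z_train": panel.alleles[np.ix_(train_rows, region.unobserved_idx)].astype(float),
            "x_val": panel.alleles[np.ix_(val_rows, inp)],
            "z_val": panel.alleles[np.ix_(val_rows, region.unobserved_idx)].astype(float),
            "maf": maf[region.unobserved_idx],
        })

    state = TrainState()
    best_arrays: list[list[np.ndarray]] | None = None
    log_rows = []
    n_train = len(train_rows)
    gamma = gen_config.gamma
    for epoch in range(train_config.max_epochs):
        lr = train_config.learning_rate * train_config.lr_decay ** epoch
        g_losses, d_losses = [], []
        order = shuffle_rng.permutation(n_train)
        for gen, disc, g_opt, d_opt, data in zip(gens, discs, g_opts, d_opts,
                                                 region_data):
            g_opt.lr = d_opt.lr = lr
            for start in range(0, n_train, train_config.batch_size):
                rows = order[start:start + train_config.batch_size]
                if len(rows) < 2:
                    continue  # batch norm needs >= 2 rows
                xb = data["x_train"][rows]
                zb = data["z_train"][rows]

                probs = gen.forward(xb)
                alt = probs[:, :, 1]

                # --- discriminator step (generated input detached) --------
                fake_scores = disc.forward(alt.detach())
                real_scores = disc.forward(zb)
                labels = np.concatenate([np.zeros(len(rows)), np.ones(len(rows))])
                scores = nn.concat([fake_scores, real_scores], axis=0)
                l_d = discriminator_loss(labels, scores)
                disc.zero_grad()
                l_d.backward()
                d_opt.step()

                # --- generator step ---------------------------------------
                l_g = generator_loss(zb, alt, data["maf"], gamma)
                if train_config.adversarial_g_term:
                    # non-saturating alternative: push D(fake) towards "real"
                    l_d_live = discriminator_loss(np.ones(len(rows)),
                                                  disc.forward(alt))
                else:
                    # literal joint objective: L_D recomputed through the
                    # live generator output with the updated discriminator
                    live_scores = nn.concat([disc.forward(alt),
                                             disc.forward(zb)], axis=0)
                    l_d_live = discriminator_loss(labels, live_scores)
                loss = total_loss(l_g, l_d_live)
                gen.zero_grad()
                disc.zero_grad()
                loss.backward()
                g_opt.step()
                disc.zero_grad()  # discard D grads from the joint backward

                g_losses.append(float(l_g.data))
                d_losses.append(float(l_d.data))

        state.g_loss.append(float(np.mean(g_losses)))
        state.d_loss.append(float(np.mean(d_losses)))
        if len(val_rows) >= 2:
            val = float(np.mean([
                _region_eval_loss(gen, data["x_val"], data["z_val"],
                                  data["maf"], gamma)
                for gen, data in zip(gens, region_data)]))
        else:
            val = state.g_loss[-1]
        state.val_loss.append(val)
        state.epoch = epoch + 1
        log_rows.append((epoch, lr, state.g_loss[-1], state.d_loss[-1], val))
        logger.info("epoch %d lr=%.2e L_G=%.4f L_D=%.4f val=%.4f",
                    epoch, lr, state.g_loss[-1], state.d_loss[-1], val)

        if val < state.best_val:
            state.best_val = val
            state.best_epoch = epoch
            state.epochs_since_best = 0
            best_arrays = [[a.copy() for a in g.state_arrays()] for g in gens]
        else:
            state.epochs_since_best += 1
            if state.epochs_since_best >= train_config.early_stop_patience:
                logger.info("early stop at epoch %d (best %d)", epoch, state.best_epoch)
                break

    if best_arrays is not None:
        for gen, arrays in zip(gens, best_arrays):
            gen.load_state_arrays(arrays)
    for gen in gens:
        gen.eval()

    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("epoch\tlr\tg_loss\td_loss\tval_loss\n")
            for row in log_rows:
                fh.write("{}\t{:.6e}\t{:.6f}\t{:.6f}\t{:.6f}\n".format(*row))

    region_models = [
        RegionModel([obs_rank[i] for i in region.input_idx],
                    [int(p) for p in positions[region.input_idx]],
                    [panel.sites[i] for i in region.unobserved_idx], gen)
        for region, gen in zip(regions, gens)
    ]
    observed_keys = [panel.sites[i].key for i in observed_idx]
    observed_freq = panel.alleles[:, observed_idx].mean(axis=0)
    ckpt = Checkpoint(gen_config, train_config, observed_keys, observed_freq,
                      region_models, train_config.seed)
    return ckpt, state


def validate(checkpoint: Checkpoint, panel: HaplotypePanel) -> dict:
    """Eval-mode generator loss and mean per-variant dosage R^2 of a
    checkpoint on held-out haplotypes carrying truth at the target sites."""
    from .evaluation import average_r2_per_variant
    from .imputation import impute

    key_to_col = {s.key: j for j, s in enumerate(panel.sites)}
    result = impute(checkpoint, panel)
    losses = []
    for rm in checkpoint.regions:
        cols = [key_to_col[s.key] for s in rm.target_sites]
        z = panel.alleles[:, cols].astype(float)
        x = panel.alleles[:, [key_to_col[checkpoint.observed_keys[r]]
                              for r in rm.input_obs_rank]]
        losses.append(_region_eval_loss(rm.generator, x, z,
                                        np.array([s.maf for s in rm.target_sites]),
                                        checkpoint.gen_config.gamma))
    truth_cols = [key_to_col[s.key] for s in result.sites]
    truth = (panel.alleles[0::2, truth_cols] + panel.alleles[1::2, truth_cols]).astype(float)
    r2, n_excluded = average_r2_per_variant(result.dosages.dosages, truth,
                                            return_excluded=True)
    return {"val_g_loss": float(np.mean(losses)),
            "average_r2_per_variant": r2,
            "n_excluded_sites": n_excluded}
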
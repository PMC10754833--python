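# grud

Reference-free genotype imputation for biallelic variants. A
bidirectional-GRU generator (one-hot encoding → sequential feature layer →
stacked bi-GRU with residual skip-connections → per-target softmax) is
trained against a small discriminator network in a GAN-style loop on a
phased haplotype reference panel. Once trained, the generator alone imputes
unobserved variants for new samples — no reference panel access at
inference time.

Everything runs on CPU with NumPy: the package ships its own minimal
reverse-mode autodiff engine (`grud.nn`) with fused GRU/batch-norm
backward passes, validated against finite differences in the test suite.

## Layout

| module | contents |
|---|---|
| `grud.haplotype_io` | phased VCF ↔ binary haplotype matrices, marker manifests, rare-variant (MAF) filtering, imputation-region windowing |
| `grud.model_core` | generator / discriminator networks, MAF-weighted generator BCE (`(2·MAF)^γ` weights), discriminator BCE, joint loss |
| `grud.training` | alternating D/G optimization, Adam + exponential LR decay, early stopping, self-describing checkpoints |
| `grud.imputation` | checkpoint → allele probabilities → dosages, region concatenation, imputed-VCF output (GT/DS/GP) |
| `grud.evaluation` | dosage R² (overall, average-per-variant, MAF-binned) |
| `grud.synthetic_data` | founder-mosaic panel simulator, chip-manifest sampling, perfect-LD test fixture |
| `grud.nn` | autograd tensors, GRU/linear/batch-norm layers, Adam |

## CLI

```sh
# simulate a phased panel with LD plus an array-style marker manifest
grud simulate --config sim.yaml --out panel.vcf --manifest chip.tsv

# train (YAML mirrors GeneratorConfig / TrainConfig field-for-field)
grud train --panel panel.vcf --manifest chip.tsv --config train.yaml \
    --out model.grud --log train_log.tsv

# impute new samples from their observed markers only
grud impute --model model.grud --in target.vcf --out imputed.vcf

# dosage R² report (overall / average-per-variant / MAF bins)
grud evaluate --imputed imputed.vcf --truth truth.vcf --panel panel.vcf \
    --out report.tsv
```

Training YAML example:

```yaml
generator:
  hidden_units: 40
  num_layers: 8
  feature_size: 50
  gamma: 0.0        # >0 favours high-MAF sites, <0 low-MAF, 0 unweighted
training:
  batch_size: 128
  max_epochs: 100
  learning_rate: 0.001
  lr_decay: 0.98
  early_stop_patience: 10
```

## Conventions

- VCF positions are 1-based; all internal indices are 0-based.
- Variant identity is the exact `(chrom, pos, ref, alt)` key; allele-swapped
  records are logged, never auto-flipped.
- MAF is always computed from the training panel (the loss weights need it
  at training time); sites with MAF < 0.005 are conventionally filtered
  before training (`filter_rare` / `--min-maf`).
- Dosage = sum of the two haplotypes' alternate-allele probabilities,
  in [0, 2]; `R²` is the squared Pearson correlation between dosage and
  true genotype count.
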
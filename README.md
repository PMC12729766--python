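# rnarepair

Degraded RNA-seq samples — FFPE archives, delayed processing, poor storage —
carry systematically distorted expression profiles: 3′ bias from fragmentation
(poly-A–primed library prep loses 5′ signal, hitting long transcripts
hardest), stochastic gene dropout, and technical noise. `rnarepair` provides
the three ingredients needed to study computational repair of such data at
desk scale:

1. **A pseudo-degradation simulator.** From a clean log-normalized profile
   `X_orig`, a degraded twin is drawn as

       X_deg = clamp₀( M ⊙ X_orig ⊙ d + ε )

   where `M_g = exp(−α·L_g/median(L))` attenuates genes by transcript length
   `L_g`, `d ~ Bernoulli(1−p_d)` is an entrywise dropout mask, and
   `ε ~ N(0, σ_n²)` is additive noise. Aligned (clean, degraded) pairs are the
   training data — real paired samples are essentially unobtainable.

2. **One-step repair networks.** The main model is a Transformer encoder over
   gene-chunk tokens trained to regress the clean profile directly from the
   degraded one, `L = E‖F_θ(X_deg) − X_orig‖²`, with a single deterministic
   forward pass at inference (no iterative sampling). MLP denoising and
   variational autoencoders are included as baselines. The networks run on the
   package's own NumPy reverse-mode autodiff engine — no deep-learning
   framework required.

3. **An evaluation scorecard.** Technical: MSE, Pearson, PR-AUC and F1 on the
   expressed-vs-unexpressed task. Biological (each 0–100): silhouette-based
   cell-type separation in PCA space, preservation of top rank-sum
   differential genes (Jaccard/F1), and Spearman recovery of curated marker
   genes — averaged into an overall biological score. Paired t-tests with
   Cohen's d, a CITE-seq-style RNA–protein orthogonal validation, and a
   cross-validated cell-type classifier round out the suite.

A synthetic-data module generates clustered negative-binomial counts with
planted marker genes, log-normal transcript lengths and a paired noisy
protein panel, so the whole pipeline is testable without downloads.

## Worked example

```python
from rnarepair import (
    SyntheticSpec, generate_truth, qc_filter, normalize_log, select_hvg,
    DegradationParams, degrade, split_dataset, RepairModelConfig,
    build_model, TrainConfig, train, technical_metrics,
)

truth, markers = generate_truth(SyntheticSpec(seed=42))   # 2000 x 500 counts
lognorm = select_hvg(normalize_log(qc_filter(truth)[0]))
pair = degrade(lognorm, DegradationParams(alpha=0.5, dropout_rate=0.3,
                                          noise_sd=0.2, seed=7))
split = split_dataset(lognorm.n_cells, labels=lognorm.cell_labels, seed=3)
model = build_model(RepairModelConfig(n_genes=lognorm.n_genes, embed_dim=64,
                                      num_layers=2, num_heads=4, ffn_dim=512,
                                      token_size=25, dropout=0.0, seed=5))
model, history = train(model, pair, split,
                       TrainConfig(max_epochs=30, learning_rate=3e-3, seed=11))

test = split.test_idx
repaired = model.repair(pair.x_deg.values[test])
print(technical_metrics(repaired, pair.x_orig.values[test]))
print(technical_metrics(pair.x_deg.values[test], pair.x_orig.values[test]))
```

prints (about a minute of single-core training):

```
TechnicalMetrics(mse=1.2479608717494373, pearson=0.6621889035712938, pr_auc=0.9571681643875022, f1=0.8450243942010175)
TechnicalMetrics(mse=3.1832169610795784, pearson=0.5744008880667241, pr_auc=0.9427749017145783, f1=0.8294996442968935)
```

The first line scores the repaired held-out cells, the second the degraded
input: repair removes about 60% of the degradation-induced squared error
(1.25 vs 3.18) and improves every agreement metric. For scale: an oracle that knows the realized dropout mask and
the per-type means reaches MSE ≈ 0.73 on the same task, so the trained
network closes about two thirds of the learnable gap.

## Command line

```bash
rnarepair synth --n-cells 2000 --n-genes 500 --n-types 4 --seed 1 --out data/
rnarepair preprocess --input data/counts --hvg 500 --out data/lognorm
rnarepair simulate --input data/lognorm --lengths data/lengths.tsv \
    --alpha 0.5 --dropout 0.3 --noise-sd 0.2 --seed 2 --out data/deg
rnarepair train --orig data/lognorm --degraded data/deg/degraded \
    --embed-dim 64 --num-layers 2 --num-heads 4 --token-size 25 \
    --max-epochs 30 --out model.ckpt
rnarepair repair --checkpoint model.ckpt --input data/deg/degraded \
    --output data/repaired
rnarepair evaluate --orig data/lognorm --degraded data/deg/degraded \
    --repaired data/repaired --labels data/labels.tsv \
    --markers data/markers.tsv --out metrics.json
rnarepair run --seed 1 --out run/        # the whole pipeline in one command
```

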
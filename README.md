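# kansformer-epi

Enhancer–promoter interaction (EPI) prediction from binned epigenomic
signal windows, using a Transformer encoder whose feed-forward sub-layers
are Kolmogorov–Arnold networks (KANs).

## The problem

Enhancers regulate target genes over distances of up to megabases, and
identifying which enhancer talks to which promoter underpins the study of
gene regulation and disease-associated noncoding variation. Assays that
measure contacts directly (Hi-C, ChIA-PET) are expensive, so a standard
computational formulation is: given a candidate enhancer–promoter pair
(promoter = TSS −1500 bp to +500 bp) and the surrounding epigenomic
landscape — CTCF, DNase-I accessibility, and the histone marks H3K4me1,
H3K4me3, H3K27me3, H3K36me3, H3K9me3, optionally DNA methylation — predict
whether the pair interacts. This package is aimed at computational
genomicists who want a tested, CPU-runnable implementation of the full
pipeline: feature extraction, model, training protocol, evaluation and
regulatory-network analysis.

## The model

A window of 2.5 Mbp centered on the pair is divided into 5000 bins of
500 bp; every signal track is averaged per bin, and an extra channel holds
the shortest distance from each bin to either anchor element (scaled by the
window size). The network maps the resulting `5000 × C` matrix to a
probability:

1. 1-D CNN (180 channels, kernel 11) + ReLU, then max-pooling (width 10);
2. BiLSTM producing a sequence `Z ∈ R^{l×h}`;
3. a stack of **Kansformer** encoder blocks — pre-norm multi-head
   self-attention (`Q = ZW_q`, `K = ZW_k`, `V = ZW_v`,
   `softmax(QKᵀ/√d_k)V`, projected with bias) alternating with a
   position-wise two-layer KAN (`h → 256 → h`), residual connections after
   each sub-layer — giving `H₀`;
4. a self-attention embedding `A_s = softmax(W_s² tanh(W_s¹ H₀ᵀ))`
   (rows sum to 1) pooling `H₁ = A_s H₀`;
5. the aggregate `H = AvgPool(H₁) ‖ MaxPool(H₁) ‖ h_e ‖ h_p ∈ R^{4h}`,
   where `h_e`, `h_p` are the encoder states at the enhancer and promoter
   positions;
6. two KAN heads: `p = σ(KAN₁(H))` and a distance regression
   `d_p = KAN₂(H)`.

Each KAN edge carries a learnable univariate activation
`φ(x) = w_b·silu(x) + w_s·Σ_j c_j B_j(x)` on a B-spline basis (cubic,
grid 5 on [−1, 1]); node values are sums of incoming edge activations.
Training minimises `L = L_class + L_dist` (binary cross-entropy plus MSE on
the window-scaled distance) with AdamW (lr 1e-4), early stopping on the
mean of validation AUROC and AUPR (patience 10), under five-fold
cross-validation partitioned **by chromosome**, so validation chromosomes
are never seen in training. Class imbalance (up to 20:1
negative:positive) can be addressed by seeded 1:1 undersampling of
training folds.

The whole network runs on a small reverse-mode autodiff engine over numpy
(`kansformer_epi.autodiff`), so no deep-learning framework is required.

## Worked example

Synthetic data with a *planted* interaction rule makes learning
verifiable: element activities are drawn, tracks receive activity-scaled
peaks, and labels follow a logistic rule on the observed anchor signal and
the pair distance — so the generating probabilities are a Bayes-optimal
ceiling for any model.

```python
import numpy as np
from kansformer_epi import (SimConfig, simulate_dataset, featurize_pairs,
                            chromosome_folds, train_fold, auroc,
                            ModelConfig, TrainConfig)
from kansformer_epi.training import zscore_split
from kansformer_epi.genome_features import CANONICAL_TRACKS

cfg = SimConfig.tiny(seed=7)                      # 3 x 400 kb chromosomes
tracks, catalog, pairs, truth = simulate_dataset(cfg)
y = np.array([p.label for p in pairs])
bayes = np.array([truth[p.pair_id] for p in pairs])
print(f"pairs: {len(pairs)}  positives: {int(y.sum())}")
print(f"Bayes ceiling AUROC: {auroc(y, bayes):.3f}")

ds = featurize_pairs(pairs, [tracks[n] for n in CANONICAL_TRACKS],
                     None, window_bp=100_000, bin_bp=500,
                     chrom_lengths=cfg.chrom_sizes)
folds = chromosome_folds(ds.chrom, k=3, seed=7)
tr_idx, va_idx = folds.train_val_indices(0)
train_ds, val_ds, _ = zscore_split(ds.subset(tr_idx), ds.subset(va_idx))
model_cfg = ModelConfig.small(in_channels=ds.X.shape[-1], bins=ds.X.shape[1])
result = train_fold(train_ds, val_ds, model_cfg,
                    TrainConfig(lr=1e-3, weight_decay=0.1, max_epochs=5,
                                patience=5, batch_size=32, seed=7))
p, _ = result.model.predict(val_ds.X, val_ds.e_bin, val_ds.p_bin)
print(f"held-out chromosome AUROC after 5 epochs: {auroc(val_ds.y, p):.3f}")
```

Output:

```
pairs: 240  positives: 120
Bayes ceiling AUROC: 0.973
held-out chromosome AUROC after 5 epochs: 0.926
```

240 balanced pairs are simulated on three small chromosomes; the
generating rule would score AUROC 0.973, and after five epochs the reduced
model already recovers 0.926 of it on a chromosome it never saw — the
planted signal is being read out of the tracks, not memorised.

## Command line

`kansformer-epi` exposes the pipeline as subcommands, each writing a
`run_manifest.json` (command, config hash, seed, inputs/outputs, version):

```bash
kansformer-epi simulate  --config sim.yaml --out fixtures/ --bigwig
kansformer-epi featurize --pairs pairs.tsv --tracks tracks.yaml \
                         --out cache/ --bin-bp 500 --window-bp 2500000
kansformer-epi train     --cache cache/ --config train.yaml --out runs/run1/
kansformer-epi predict   --checkpoint runs/run1/checkpoint_fold0.npz \
                         --cache cache/ --out predictions.tsv
kansformer-epi evaluate  --pred runs/run1/oof_predictions.tsv --out metrics.json
kansformer-epi patterns  --pairs pairs.tsv --pred predictions.tsv --out patterns.tsv
```

`patterns` classifies every positive pair by the shape of its connected
component in the bipartite enhancer–promoter graph: Single (1:1), MO (one
enhancer, many promoters), MI (many enhancers, one promoter), MIMO
(many-to-many).

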
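"""Self-contained study recipes used by the acceptance machinery.

Each function generates its own inputs from a seed, runs the package's
method, and reports the measured quantities.  The learnability study is the
package's core synthetic benchmark: a planted-rule dataset whose generating
probabilities provide a Bayes-optimal ceiling, against which a reduced model
(h=64, one encoder block) trained for a fixed budget is compared on a
chromosome-held-out fold.
"""

from __future__ import annotations

import numpy as np

from .evaluation import auroc, aupr
from .genome_features import CANONICAL_TRACKS
from .model import ModelConfig
from .simulate import SimConfig, simulate_dataset
from .training import (TrainConfig, chromosome_folds, featurize_pairs,
                       train_fold, undersample, zscore_split)

LEARNABILITY_WINDOW_BP = 250_000
LEARNABILITY_BIN_BP = 500


def run_learnability_study(seed: int = 1, epochs: int = 10,
                           folds: int = 5) -> dict:
    """Planted-rule benchmark: reduced model vs the Bayes ceiling.

    Simulates the default synthetic study (2000 pairs over six chromosomes),
    featurizes 250 kb windows at 500 bp bins, holds out one chromosome fold,
    z-scores with training-fold statistics, trains the reduced model for
    ``epochs`` epochs and reports held-out AUROC/AUPR next to the Bayes
    ceiling of the generating rule.
    """
    cfg = SimConfig(seed=seed)
    tracks, catalog, pairs, truth = simulate_dataset(cfg)
    labels = np.array([p.label for p in pairs])
    bayes_scores = np.array([truth[p.pair_id] for p in pairs])

    track_list = [tracks[name] for name in CANONICAL_TRACKS]
    ds = featurize_pairs(pairs, track_list, None,
                         window_bp=LEARNABILITY_WINDOW_BP,
                         bin_bp=LEARNABILITY_BIN_BP,
                         chrom_lengths=cfg.chrom_sizes)
    assignment = chromosome_folds(ds.chrom, folds, seed)
    tr_idx, va_idx = assignment.train_val_indices(0)
    train_ds, val_ds, _ = zscore_split(ds.subset(tr_idx), ds.subset(va_idx))

    model_cfg = ModelConfig.small(in_channels=ds.X.shape[-1],
                                  bins=ds.X.shape[1])
    train_cfg = TrainConfig(lr=1e-3, weight_decay=0.1, max_epochs=epochs,
                            patience=epochs, batch_size=32, seed=seed)
    result = train_fold(train_ds, val_ds, model_cfg, train_cfg)
    p_val, _ = result.model.predict(val_ds.X, val_ds.e_bin, val_ds.p_bin)

    t = {pid: truth[pid] for pid in val_ds.pair_ids}
    return {
        "n_pairs": len(pairs),
        "bayes_auroc": auroc(labels, bayes_scores),
        "bayes_auroc_heldout": auroc(val_ds.y, [t[pid] for pid in
                                                val_ds.pair_ids]),
        "heldout_auroc": auroc(val_ds.y, p_val),
        "heldout_aupr": aupr(val_ds.y, p_val),
        "best_epoch": result.best_epoch,
        "history": result.history,
        "assignment": assignment,
        "dataset": ds,
        "pairs": pairs,
        "config": cfg,
    }


def run_kan_sin_fit(seed: int = 0, steps: int = 2000,
                    n_samples: int = 200) -> dict:
    """Fit y = sin(3x) with a 1->5->1 KAN; report the final MSE."""
    from .autodiff import Tensor
    from .kan import KANNetwork
    from .optim import AdamW

    rng = np.random.default_rng(seed)
    x = rng.uniform(-1, 1, size=(n_samples, 1))
    y = np.sin(3 * x)
    net = KANNetwork([1, 5, 1], np.random.default_rng(seed + 1))
    opt = AdamW(net.parameters(), lr=0.02, weight_decay=0.0)
    mse = np.inf
    for step in range(steps):
        diff = net(Tensor(x)) - Tensor(y)
        loss = (diff * diff).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()
        mse = loss.item()
        if mse < 1e-4:
            break
    return {"mse": mse, "steps_run": step + 1, "n": n_samples}


def run_undersampling_check(pairs, seed: int = 0) -> dict:
    """Apply 1:1 undersampling and report the resulting class counts."""
    labels = np.array([p.label for p in pairs])
    idx = undersample(labels, seed)
    y = labels[idx]
    return {"n_positive": int((y == 1).sum()),
            "n_negative": int((y == 0).sum()),
            "ratio": float((y == 0).sum() / max(1, (y == 1).sum()))}
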
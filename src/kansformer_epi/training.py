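"""Chromosome-partitioned cross-validation training with dual objectives.

Pairs never straddle folds by chromosome: all pairs of one chromosome land in
one fold, so a validation fold shares no chromosome with its training folds.
Training minimises L = L_class + L_dist with AdamW; early stopping monitors
the mean of validation AUROC and AUPR.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .autodiff import Tensor
from .evaluation import aupr, auroc
from .genome_features import (ChannelNormalizer, EPPair, SignalTrack,
                              bin_signal, featurize, make_window)
from .model import KansformerEPI, ModelConfig, combined_loss
from .optim import AdamW


@dataclass
class TrainConfig:
    lr: float = 1e-4
    max_epochs: int = 300
    patience: int = 10
    folds: int = 5
    batch_size: int = 16
    seed: int = 0
    balance: str = "none"            # {"none", "undersample_1to1"}
    weight_decay: float = 1e-2

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.balance not in ("none", "undersample_1to1"):
            raise ValueError(f"unknown balance mode {self.balance!r}")


@dataclass
class PairDataset:
    """Featurized pairs ready for training: tensors plus bookkeeping arrays."""

    X: np.ndarray                    # (n, bins, channels)
    e_bin: np.ndarray
    p_bin: np.ndarray
    y: np.ndarray
    d_scaled: np.ndarray             # anchor distance / window size
    chrom: np.ndarray                # per-pair chromosome label
    pair_ids: list[str]

    def __post_init__(self):
        n = len(self.X)
        for name in ("e_bin", "p_bin", "y", "d_scaled", "chrom"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length differs from X")
        if len(self.pair_ids) != n:
            raise ValueError("pair_ids length differs from X")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx: np.ndarray) -> "PairDataset":
        idx = np.asarray(idx)
        return PairDataset(self.X[idx], self.e_bin[idx], self.p_bin[idx],
                           self.y[idx], self.d_scaled[idx], self.chrom[idx],
                           [self.pair_ids[i] for i in idx])


def featurize_pairs(pairs: Sequence[EPPair], tracks: Sequence[SignalTrack],
                    normalizer: ChannelNormalizer | None,
                    window_bp: int, bin_bp: int,
                    chrom_lengths: dict[str, int] | None = None,
                    log_transform: bool = False) -> PairDataset:
    """Featurize a pair list into a stacked dataset (see ``featurize``)."""
    mats, e_bins, p_bins = [], [], []
    for pair in pairs:
        clen = chrom_lengths.get(pair.chrom) if chrom_lengths else None
        fw = featurize(pair, tracks, normalizer, window_bp, bin_bp, clen,
                       log_transform=log_transform)
        mats.append(fw.matrix)
        e_bins.append(fw.e_bin)
        p_bins.append(fw.p_bin)
    return PairDataset(
        X=np.stack(mats),
        e_bin=np.asarray(e_bins), p_bin=np.asarray(p_bins),
        y=np.asarray([p.label for p in pairs], dtype=np.float64),
        d_scaled=np.asarray([p.distance_bp / window_bp for p in pairs]),
        chrom=np.asarray([p.chrom for p in pairs]),
        pair_ids=[p.pair_id for p in pairs])


def fit_normalizer(pairs: Sequence[EPPair], tracks: Sequence[SignalTrack],
                   window_bp: int, bin_bp: int,
                   chrom_lengths: dict[str, int] | None = None
                   ) -> ChannelNormalizer:
    """Per-channel statistics over the *training* pairs' binned signals."""
    mats = []
    for pair in pairs:
        clen = chrom_lengths.get(pair.chrom) if chrom_lengths else None
        window = make_window(pair, window_bp, clen)
        mats.append(np.stack([bin_signal(t, window, bin_bp) for t in tracks],
                             axis=1))
    return ChannelNormalizer().fit(mats)


# ---------------------------------------------------------------------------
# fold assignment and class balancing
# ---------------------------------------------------------------------------

@dataclass
class FoldAssignment:
    chrom_to_fold: dict[str, int]
    folds: list[np.ndarray] = field(default_factory=list)  # per-fold pair indices

    def train_val_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        val = self.folds[fold]
        train = np.concatenate([f for i, f in enumerate(self.folds) if i != fold])
        return train, val


def chromosome_folds(chroms: Sequence[str], k: int,
                     seed: int = 0) -> FoldAssignment:
    """Greedy largest-first packing of chromosomes into k balanced folds.

    ``chroms`` gives the chromosome of every pair; chromosomes are assigned
    whole, largest pair count first, each to the currently lightest fold
    (seeded shuffle breaks count ties).
    """
    chroms = np.asarray(chroms)
    uniq, counts = np.unique(chroms, return_counts=True)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} chromosomes for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    uniq, counts = uniq[order], counts[order]
    by_size = np.argsort(-counts, kind="stable")
    totals = np.zeros(k, dtype=int)
    chrom_to_fold: dict[str, int] = {}
    for i in by_size:
        fold = int(np.argmin(totals))
        chrom_to_fold[str(uniq[i])] = fold
        totals[fold] += counts[i]
    folds = [np.flatnonzero([chrom_to_fold[str(c)] == f for c in chroms])
             for f in range(k)]
    return FoldAssignment(chrom_to_fold=chrom_to_fold, folds=folds)


def undersample(labels: Sequence[int], seed: int = 0) -> np.ndarray:
    """Indices keeping every positive and a seeded 1:1 sample of negatives."""
    labels = np.asarray(labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("undersampling needs at least one of each class")
    if len(neg) < len(pos):
        warnings.warn("fewer negatives than positives; keeping all pairs")
        return np.sort(np.concatenate([pos, neg]))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(neg, size=len(pos), replace=False)
    return np.sort(np.concatenate([pos, chosen]))


def undersample_pairs(pairs: Sequence[EPPair], seed: int = 0) -> list[EPPair]:
    idx = undersample([p.label for p in pairs], seed)
    return [pairs[i] for i in idx]


# ---------------------------------------------------------------------------
# training loops
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    model: KansformerEPI
    history: pd.DataFrame
    best_epoch: int
    best_monitor: float


def _run_epoch(model: KansformerEPI, ds: PairDataset, opt: AdamW,
               batch_size: int, rng: np.random.Generator) -> dict[str, float]:
    order = rng.permutation(len(ds))
    tot_class = tot_dist = 0.0
    n_batches = 0
    for lo in range(0, len(order), batch_size):
        idx = order[lo:lo + batch_size]
        p, d_p = model.forward(Tensor(ds.X[idx]), ds.e_bin[idx], ds.p_bin[idx])
        l_class, l_dist, loss = combined_loss(p, ds.y[idx], d_p, ds.d_scaled[idx])
        if not np.isfinite(loss.item()):
            raise RuntimeError(
                f"non-finite loss at batch {n_batches}: "
                f"L_class={l_class.item():.4g}, L_dist={l_dist.item():.4g}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        tot_class += l_class.item()
        tot_dist += l_dist.item()
        n_batches += 1
    return {"train_l_class": tot_class / n_batches,
            "train_l_dist": tot_dist / n_batches}


def train_fold(train_ds: PairDataset, val_ds: PairDataset,
               model_cfg: ModelConfig, train_cfg: TrainConfig) -> TrainResult:
    """Train one fold with early stopping on mean(val AUROC, val AUPR).

    The best-monitor parameters are restored into the returned model; ties
    keep the earlier epoch.
    """
    if set(train_ds.chrom) & set(val_ds.chrom):
        raise ValueError("train and validation folds share chromosomes")
    if train_cfg.balance == "undersample_1to1":
        train_ds = train_ds.subset(undersample(train_ds.y, train_cfg.seed))
    model = KansformerEPI(model_cfg, seed=train_cfg.seed)
    opt = AdamW(model.parameters(), lr=train_cfg.lr,
                weight_decay=train_cfg.weight_decay)
    rng = np.random.default_rng(train_cfg.seed + 1)
    best_state: dict | None = None
    best_monitor = -np.inf
    best_epoch = -1
    rows = []
    for epoch in range(train_cfg.max_epochs):
        model.train()
        stats = _run_epoch(model, train_ds, opt, train_cfg.batch_size, rng)
        p_val, _ = model.predict(val_ds.X, val_ds.e_bin, val_ds.p_bin)
        val_auroc = auroc(val_ds.y, p_val)
        val_aupr = aupr(val_ds.y, p_val)
        monitor = 0.5 * (val_auroc + val_aupr)
        rows.append({"epoch": epoch, **stats, "val_auroc": val_auroc,
                     "val_aupr": val_aupr, "monitor": monitor})
        if monitor > best_monitor:
            best_monitor = monitor
            best_epoch = epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= train_cfg.patience:
            break
    model.load_state_dict(best_state)
    model.eval()
    return TrainResult(model=model, history=pd.DataFrame(rows),
                       best_epoch=best_epoch, best_monitor=best_monitor)


def zscore_split(train_ds: PairDataset, val_ds: PairDataset,
                 sd_floor: float = 1e-8
                 ) -> tuple[PairDataset, PairDataset, ChannelNormalizer]:
    """z-score the signal channels (all but the distance channel, which is
    already scaled) using statistics from the training split only."""
    norm = ChannelNormalizer(sd_floor=sd_floor)
    flat = train_ds.X[..., :-1].reshape(-1, train_ds.X.shape[-1] - 1)
    norm.fit([flat])

    def apply(ds: PairDataset) -> PairDataset:
        X = ds.X.copy()
        X[..., :-1] = (X[..., :-1] - norm.mean) / norm.std
        return PairDataset(X, ds.e_bin, ds.p_bin, ds.y, ds.d_scaled,
                           ds.chrom, list(ds.pair_ids))

    return apply(train_ds), apply(val_ds), norm


@dataclass
class CVResult:
    fold_metrics: pd.DataFrame
    oof_predictions: pd.DataFrame
    results: list[TrainResult]
    assignment: FoldAssignment


def cross_validate(ds: PairDataset, model_cfg: ModelConfig,
                   train_cfg: TrainConfig,
                   normalize: bool = False) -> CVResult:
    """k-fold chromosome-partitioned CV; every pair predicted out-of-fold once.

    ``normalize=True`` z-scores the signal channels per fold with statistics
    from that fold's training split (use when ``ds`` holds raw binned means).
    """
    assignment = chromosome_folds(ds.chrom, train_cfg.folds, train_cfg.seed)
    fold_rows, oof_rows, results = [], [], []
    for fold in range(train_cfg.folds):
        tr_idx, va_idx = assignment.train_val_indices(fold)
        tr_ds, va_ds = ds.subset(tr_idx), ds.subset(va_idx)
        if normalize:
            tr_ds, va_ds, _ = zscore_split(tr_ds, va_ds)
        cfg = copy.copy(train_cfg)
        cfg.seed = train_cfg.seed + fold
        res = train_fold(tr_ds, va_ds, model_cfg, cfg)
        val = va_ds
        p, d_p = res.model.predict(val.X, val.e_bin, val.p_bin)
        fold_rows.append({"fold": fold, "auroc": auroc(val.y, p),
                          "aupr": aupr(val.y, p),
                          "best_epoch": res.best_epoch})
        for i in range(len(val)):
            oof_rows.append({"pair_id": val.pair_ids[i], "fold": fold,
                             "y": int(val.y[i]), "p": float(p[i]),
                             "d_p": float(d_p[i])})
        results.append(res)
    return CVResult(fold_metrics=pd.DataFrame(fold_rows),
                    oof_predictions=pd.DataFrame(oof_rows),
                    results=results, assignment=assignment)
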
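"""Synthetic epigenomic fixtures with a planted, known interaction rule.

The generator emulates the inputs the predictor consumes in the wild --
per-base nonnegative signal tracks with peak-like enrichment at regulatory
elements, and E-P candidate pair tables -- but with a fully known generative
rule, so learnability can be checked against the Bayes-optimal ceiling:

* each element (enhancer or promoter) carries a latent activity a ~ N(0, 1);
* tracks are background noise plus Gaussian-shaped peaks at element loci,
  peak height scaling with exp(activity_scale * a) for the marks associated
  with that element class (DNase everywhere, H3K4me1 at enhancers, H3K4me3
  at promoters), plus unrelated decoy peaks;
* each element's *observed* activity is the standardized log mean signal of
  its class marks in a 500 bp window at the element center, read back from
  the synthesised tracks;
* a candidate pair interacts with probability
  sigmoid(intercept + beta (s_e + s_p) - gamma d/d_max + eps) with s the
  observed activities, so the label is a logistic function of signal the
  model can actually see, and the returned generating probabilities are an
  achievable Bayes ceiling;
* negatives are drawn from non-interacting pairs whose distances lie within
  the central 95% of the positive distance distribution, mirroring the
  distance-matched negative sampling of the benchmark pair tables.

Everything is reproducible from ``SimConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_features import (EPPair, GenomicInterval, SignalTrack,
                              promoter_from_tss, write_bed6, write_pairs)

#: peak-association weights per feature: (enhancer, promoter, decoy rate)
FEATURE_ASSOCIATION = {
    "CTCF": (0.3, 0.3, 1.0),
    "DNase": (1.0, 1.0, 0.2),
    "H3K4me1": (1.0, 0.2, 0.3),
    "H3K4me3": (0.2, 1.0, 0.3),
    "H3K27me3": (0.1, 0.1, 1.0),
    "H3K36me3": (0.1, 0.1, 1.0),
    "H3K9me3": (0.1, 0.1, 1.0),
    "Methyl": (0.1, 0.1, 1.0),
}


@dataclass
class SimConfig:
    """Generator settings; the defaults define the package's synthetic study.

    The default genome is six 1.2 Mb chromosomes with E-P separations up to
    220 kb, sized for 250 kb feature windows; ``tiny()`` shrinks everything
    further for fast unit tests.
    """

    seed: int = 0
    chrom_sizes: dict[str, int] = field(
        default_factory=lambda: {f"chr{i}": 1_200_000 for i in range(1, 7)})
    enhancers_per_chrom: int = 70
    promoters_per_chrom: int = 28
    enhancer_width: tuple[int, int] = (500, 2000)
    min_element_spacing: int = 4000  # between element centers: keeps each
                                     # anchor's signal attributable to it
    edge_margin: int = 5000
    min_distance: int = 5000
    max_distance: int = 220_000
    n_positive: int = 1000
    negatives_per_positive: int = 1
    # planted logistic rule
    beta_signal: float = 4.0
    gamma_distance: float = 2.0
    intercept: float = -1.0
    logit_noise_sd: float = 0.5
    # track synthesis
    features: tuple[str, ...] = ("CTCF", "DNase", "H3K4me1", "H3K4me3",
                                 "H3K27me3", "H3K36me3", "H3K9me3")
    noise_sd: float = 0.3
    peak_height: float = 3.0
    activity_scale: float = 0.6
    element_peak_sd: float = 150.0   # fixed element peak shape: the binned
                                     # peak height is then monotone in activity
    peak_width: tuple[int, int] = (200, 2000)
    decoy_peaks_per_chrom: int = 30

    def __post_init__(self):
        for name in ("noise_sd", "peak_height"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.min_distance >= self.max_distance:
            raise ValueError("min_distance must be < max_distance")
        for size in self.chrom_sizes.values():
            if size <= 2 * self.edge_margin:
                raise ValueError("chromosome too small for the edge margin")

    @classmethod
    def tiny(cls, seed: int = 0) -> "SimConfig":
        """Fast unit-test scale: three 400 kb chromosomes, 100 kb windows."""
        return cls(seed=seed,
                   chrom_sizes={f"chr{i}": 400_000 for i in range(1, 4)},
                   enhancers_per_chrom=25, promoters_per_chrom=10,
                   min_distance=2000, max_distance=80_000,
                   n_positive=120, decoy_peaks_per_chrom=10)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Element:
    kind: str                    # {"enhancer", "promoter"}
    interval: GenomicInterval
    activity: float
    tss: int = -1                # promoters only
    name: str = ""


def _spaced_centers(n: int, lo: int, hi: int, spacing: int,
                    rng: np.random.Generator, max_tries: int = 200) -> np.ndarray:
    """n positions in [lo, hi) with pairwise distance >= spacing (seeded)."""
    if (hi - lo) < n * spacing:
        raise ValueError(f"cannot place {n} elements {spacing} bp apart "
                         f"in {hi - lo} bp")
    for _ in range(max_tries):
        pos = np.sort(rng.integers(lo, hi, size=3 * n))
        keep = [int(pos[0])]
        for x in pos[1:]:
            if x - keep[-1] >= spacing:
                keep.append(int(x))
            if len(keep) == n:
                break
        if len(keep) == n:
            return rng.permutation(keep)
    raise ValueError("could not satisfy element spacing; enlarge chromosomes")


def simulate_elements(cfg: SimConfig,
                      rng: np.random.Generator) -> list[Element]:
    """Place enhancers and promoter TSSs with latent activities.

    Element centers keep ``min_element_spacing`` so every anchor's local
    signal is attributable to that element (overlapping elements would make
    the planted pair labels unidentifiable from the tracks).
    """
    catalog: list[Element] = []
    for chrom, size in cfg.chrom_sizes.items():
        n_enh, n_prom = cfg.enhancers_per_chrom, cfg.promoters_per_chrom
        centers = _spaced_centers(n_enh + n_prom, cfg.edge_margin,
                                  size - cfg.edge_margin,
                                  cfg.min_element_spacing, rng)
        for i in range(n_enh):
            width = int(rng.integers(*cfg.enhancer_width))
            center = int(centers[i])
            start = max(0, center - width // 2)
            catalog.append(Element(
                kind="enhancer",
                interval=GenomicInterval(chrom, start, start + width),
                activity=float(rng.normal()), name=f"{chrom}_E{i}"))
        for i in range(n_prom):
            tss = int(centers[n_enh + i])
            strand = "+" if rng.random() < 0.5 else "-"
            catalog.append(Element(
                kind="promoter",
                interval=promoter_from_tss(chrom, tss, strand),
                activity=float(rng.normal()), tss=tss, name=f"{chrom}_P{i}"))
    return catalog


def _add_peak(arr: np.ndarray, center: int, sd: float, height: float) -> None:
    lo = max(0, int(center - 4 * sd))
    hi = min(len(arr), int(center + 4 * sd) + 1)
    if lo >= hi:
        return
    x = np.arange(lo, hi, dtype=np.float64)
    arr[lo:hi] += height * np.exp(-0.5 * ((x - center) / sd) ** 2)


def simulate_tracks(cfg: SimConfig, catalog: Sequence[Element],
                    rng: np.random.Generator) -> dict[str, SignalTrack]:
    """Per-feature per-base tracks: background noise + element/decoy peaks."""
    tracks: dict[str, SignalTrack] = {}
    for feat in cfg.features:
        enh_w, prom_w, decoy_rate = FEATURE_ASSOCIATION[feat]
        arrays: dict[str, np.ndarray] = {}
        for chrom, size in cfg.chrom_sizes.items():
            arr = np.abs(rng.normal(0.0, cfg.noise_sd, size=size)) \
                if cfg.noise_sd > 0 else np.zeros(size)
            arrays[chrom] = arr
        for elem in catalog:
            weight = enh_w if elem.kind == "enhancer" else prom_w
            if weight == 0:
                continue
            height = cfg.peak_height * weight * np.exp(
                cfg.activity_scale * elem.activity)
            _add_peak(arrays[elem.interval.chrom], elem.interval.center,
                      cfg.element_peak_sd, height)
        for chrom, size in cfg.chrom_sizes.items():
            n_decoys = rng.poisson(decoy_rate * cfg.decoy_peaks_per_chrom)
            for _ in range(n_decoys):
                center = int(rng.integers(0, size))
                sd = rng.uniform(*cfg.peak_width) / 4.0
                height = cfg.peak_height * rng.lognormal(-0.5, 0.5)
                _add_peak(arrays[chrom], center, sd, height)
        tracks[feat] = SignalTrack.from_arrays(
            feat, {c: a.astype(np.float32) for c, a in arrays.items()})
    return tracks


#: marks whose peak height encodes an element's activity, per element class
ACTIVITY_MARKS = {"enhancer": ("DNase", "H3K4me1"),
                  "promoter": ("DNase", "H3K4me3")}


def observed_activities(catalog: Sequence[Element],
                        tracks: dict[str, SignalTrack],
                        half_window: int = 250) -> np.ndarray:
    """Standardized log mean signal at each element's center.

    For every element, average its class marks over
    [center - half_window, center + half_window), take log1p, and z-score
    within each element class.  This is the activity the label rule uses, so
    the planted signal is exactly what the tracks expose.
    """
    raw = np.empty(len(catalog))
    for i, elem in enumerate(catalog):
        marks = [m for m in ACTIVITY_MARKS[elem.kind] if m in tracks]
        if not marks:
            raise KeyError(f"no activity marks available for {elem.kind}")
        center = elem.interval.center
        lo = max(0, center - half_window)
        vals = [tracks[m].values(elem.interval.chrom, lo,
                                 center + half_window).mean() for m in marks]
        raw[i] = np.log1p(np.mean(vals))
    out = np.empty_like(raw)
    for kind in ("enhancer", "promoter"):
        mask = np.asarray([e.kind == kind for e in catalog])
        if mask.any():
            vals = raw[mask]
            out[mask] = (vals - vals.mean()) / max(vals.std(), 1e-8)
    return out


def planted_rule_labels(cfg: SimConfig, act_e: np.ndarray, act_p: np.ndarray,
                        distance_bp: np.ndarray,
                        rng: np.random.Generator
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Sample labels from the planted logistic rule; return (probs, labels).

    The returned probabilities are the generating (Bayes-optimal) scores:
    ranking by them upper-bounds any model's achievable AUROC on this data.
    """
    logit = (cfg.intercept
             + cfg.beta_signal * (np.asarray(act_e) + np.asarray(act_p))
             - cfg.gamma_distance * np.asarray(distance_bp) / cfg.max_distance)
    if cfg.logit_noise_sd > 0:
        logit = logit + rng.normal(0.0, cfg.logit_noise_sd, size=logit.shape)
    probs = 1.0 / (1.0 + np.exp(-logit))
    labels = (rng.random(probs.shape) < probs).astype(int)
    return probs, labels


def simulate_pairs(cfg: SimConfig, catalog: Sequence[Element],
                   rng: np.random.Generator,
                   tracks: dict[str, SignalTrack] | None = None
                   ) -> tuple[list[EPPair], dict[str, float]]:
    """Candidate pairs + planted labels + distance-matched negative sampling.

    When ``tracks`` is given the rule uses activities observed from the
    tracks (the generated probabilities are then an achievable ceiling);
    otherwise it falls back to the latent element activities.  Returns the
    pair list (positives first) and the truth map
    pair_id -> generating probability.
    """
    activities = (observed_activities(catalog, tracks) if tracks is not None
                  else np.array([e.activity for e in catalog]))
    index = {id(e): i for i, e in enumerate(catalog)}
    enhancers = [e for e in catalog if e.kind == "enhancer"]
    promoters = [e for e in catalog if e.kind == "promoter"]
    cand: list[tuple[Element, Element, int]] = []
    for enh in enhancers:
        for prom in promoters:
            if enh.interval.chrom != prom.interval.chrom:
                continue
            d = enh.interval.edge_gap(prom.interval)
            if cfg.min_distance <= d <= cfg.max_distance:
                cand.append((enh, prom, d))
    if not cand:
        raise ValueError("no candidate pairs satisfy the distance constraint")
    act_e = np.array([activities[index[id(c[0])]] for c in cand])
    act_p = np.array([activities[index[id(c[1])]] for c in cand])
    dist = np.array([c[2] for c in cand], dtype=np.float64)
    probs, labels = planted_rule_labels(cfg, act_e, act_p, dist, rng)

    pos_idx = np.flatnonzero(labels == 1)
    if len(pos_idx) < cfg.n_positive:
        raise ValueError(
            f"rule produced only {len(pos_idx)} positives; requested "
            f"{cfg.n_positive}. Add elements or relax the distance range.")
    pos_idx = rng.choice(pos_idx, size=cfg.n_positive, replace=False)

    q_lo, q_hi = np.quantile(dist[pos_idx], [0.025, 0.975])
    neg_pool = np.flatnonzero((labels == 0) & (dist >= q_lo) & (dist <= q_hi))
    n_neg = cfg.n_positive * cfg.negatives_per_positive
    if len(neg_pool) < n_neg:
        raise ValueError(
            f"only {len(neg_pool)} distance-matched negatives available for "
            f"{n_neg} requested (positive distance range "
            f"[{q_lo:.0f}, {q_hi:.0f}] bp)")
    neg_idx = rng.choice(neg_pool, size=n_neg, replace=False)

    pairs: list[EPPair] = []
    truth: dict[str, float] = {}
    for idx, label in [(i, 1) for i in pos_idx] + [(i, 0) for i in neg_idx]:
        enh, prom, _ = cand[idx]
        pair = EPPair(enhancer=enh.interval, promoter=prom.interval,
                      tss=prom.tss, label=label, cell_line="SIM",
                      source="planted-rule")
        pairs.append(pair)
        truth[pair.pair_id] = float(probs[idx])
    return pairs, truth


def simulate_dataset(cfg: SimConfig
                     ) -> tuple[dict[str, SignalTrack], list[Element],
                                list[EPPair], dict[str, float]]:
    """One-call generator: (tracks, element catalog, pairs, truth scores)."""
    rng = np.random.default_rng(cfg.seed)
    catalog = simulate_elements(cfg, rng)
    tracks = simulate_tracks(cfg, catalog, rng)
    pairs, truth = simulate_pairs(cfg, catalog, rng, tracks=tracks)
    return tracks, catalog, pairs, truth


def write_fixture(cfg: SimConfig, out_dir: str | Path,
                  write_bigwig: bool = False) -> dict[str, Path]:
    """Materialise a fixture directory: pairs.tsv, elements.bed, truth.json.

    ``write_bigwig=True`` additionally writes each track as a real bigWig
    (requires pyBigWig), exercising the bigWig reading path end to end.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tracks, catalog, pairs, truth = simulate_dataset(cfg)
    paths = {"pairs": out_dir / "pairs.tsv",
             "elements": out_dir / "elements.bed",
             "truth": out_dir / "truth.json"}
    write_pairs(pairs, paths["pairs"])
    write_bed6([e.interval for e in catalog], paths["elements"],
               names=[e.name for e in catalog])
    paths["truth"].write_text(json.dumps(
        {"config": cfg.to_dict(), "bayes_scores": truth}, indent=2))
    if write_bigwig:
        import pyBigWig
        bw_dir = out_dir / "tracks"
        bw_dir.mkdir(exist_ok=True)
        header = list(cfg.chrom_sizes.items())
        for name, track in tracks.items():
            bw_path = bw_dir / f"{name}.bw"
            bw = pyBigWig.open(str(bw_path), "w")
            bw.addHeader(header)
            for chrom, size in header:
                vals = track.values(chrom, 0, size)
                bw.addEntries(chrom, 0, values=vals.tolist(), span=1, step=1)
            bw.close()
            paths[f"track:{name}"] = bw_path
    return paths
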
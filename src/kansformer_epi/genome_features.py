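"""Genomic feature extraction for enhancer-promoter pair windows.

The prediction model consumes, per candidate enhancer-promoter (E-P) pair, a
fixed genomic window centered on the pair (2.5 Mbp by default, the maximum
E-P separation in the benchmark pair tables), divided into consecutive bins
(500 bp by default, 5000 bins per window).  Each bin carries the mean of
every epigenomic signal track (CTCF, DNase-I, five histone marks, optionally
DNA methylation) plus one extra channel holding the shortest distance from
the bin to either anchor element, scaled by the window size.

Coordinates are 0-based half-open throughout, matching BED/bigWig.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MAX_PAIR_DISTANCE_BP = 2_500_000
DEFAULT_WINDOW_BP = 2_500_000
DEFAULT_BIN_BP = 500
PROMOTER_UPSTREAM_BP = 1500
PROMOTER_DOWNSTREAM_BP = 500

#: canonical channel order for the signal tracks (methylation optional, last)
CANONICAL_TRACKS = ("CTCF", "DNase", "H3K4me1", "H3K4me3",
                    "H3K27me3", "H3K36me3", "H3K9me3")
OPTIONAL_TRACKS = ("Methyl",)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chromosome name must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)

    def edge_gap(self, other: "GenomicInterval") -> int:
        """bp gap between closest edges; 0 when overlapping or adjacent."""
        if self.chrom != other.chrom:
            raise ValueError("edge_gap requires intervals on one chromosome")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass(frozen=True)
class EPPair:
    """One enhancer/promoter candidate with label and provenance."""

    enhancer: GenomicInterval
    promoter: GenomicInterval
    tss: int
    label: int
    cell_line: str = ""
    source: str = ""
    pair_id: str = ""
    distance_bp: int = -1

    def __post_init__(self):
        if self.enhancer.chrom != self.promoter.chrom:
            raise ValueError(
                f"pair {self.pair_id or '?'}: enhancer on {self.enhancer.chrom} "
                f"but promoter on {self.promoter.chrom}")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0/1, got {self.label}")
        if self.distance_bp < 0:
            object.__setattr__(self, "distance_bp",
                               self.enhancer.edge_gap(self.promoter))
        if self.distance_bp > MAX_PAIR_DISTANCE_BP:
            raise ValueError(
                f"pair {self.pair_id or '?'}: distance {self.distance_bp} bp "
                f"exceeds {MAX_PAIR_DISTANCE_BP} bp")
        if not self.pair_id:
            object.__setattr__(
                self, "pair_id",
                f"{self.enhancer.chrom}:{self.enhancer.start}-{self.enhancer.end}"
                f"|{self.tss}|{self.cell_line or 'NA'}")

    @property
    def chrom(self) -> str:
        return self.enhancer.chrom


class SignalTrack:
    """Named per-base nonnegative signal, in-memory or bigWig-backed.

    Queries outside the covered region return 0.
    """

    def __init__(self, name: str, arrays: dict[str, np.ndarray] | None = None,
                 bigwig_path: str | Path | None = None):
        if (arrays is None) == (bigwig_path is None):
            raise ValueError("provide exactly one of arrays / bigwig_path")
        self.name = name
        self._arrays = ({c: np.asarray(a, dtype=np.float32)
                         for c, a in arrays.items()} if arrays else None)
        self._bigwig_path = str(bigwig_path) if bigwig_path else None
        self._bw = None

    @classmethod
    def from_arrays(cls, name: str, arrays: dict[str, np.ndarray]) -> "SignalTrack":
        return cls(name, arrays=arrays)

    @classmethod
    def from_bigwig(cls, name: str, path: str | Path) -> "SignalTrack":
        return cls(name, bigwig_path=path)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base values over [start, end); 0 outside coverage."""
        if start < 0 or end <= start:
            raise ValueError(f"bad query {chrom}:{start}-{end}")
        out = np.zeros(end - start, dtype=np.float64)
        if self._arrays is not None:
            arr = self._arrays.get(chrom)
            if arr is None:
                return out
            lo, hi = start, min(end, len(arr))
            if lo < hi:
                out[: hi - lo] = arr[lo:hi]
            return out
        if self._bw is None:
            import pyBigWig  # optional dependency, only on this path
            self._bw = pyBigWig.open(self._bigwig_path)
        chroms = self._bw.chroms()
        if chrom not in chroms:
            return out
        hi = min(end, chroms[chrom])
        if start < hi:
            vals = np.asarray(self._bw.values(chrom, start, hi), dtype=np.float64)
            out[: hi - start] = np.nan_to_num(vals, nan=0.0)
        return out


@dataclass
class FeatureWindow:
    """Binned bins x channels matrix for one pair, plus anchor bin indices."""

    window: GenomicInterval
    matrix: np.ndarray               # (bins, channels), distance channel last
    channels: tuple[str, ...]
    e_bin: int
    p_bin: int
    pair_id: str

    def __post_init__(self):
        bins = self.matrix.shape[0]
        if not (0 <= self.e_bin < bins and 0 <= self.p_bin < bins):
            raise ValueError("anchor bin index outside the window")
        if self.matrix.shape[1] != len(self.channels):
            raise ValueError("channel names do not match matrix width")


@dataclass(frozen=True)
class ManifestRow:
    cell_line: str
    source: str
    n_positive: int
    n_negative: int

    def __post_init__(self):
        if self.n_positive < 0 or self.n_negative < 0:
            raise ValueError("manifest counts must be nonnegative")


@dataclass
class DatasetManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def cell_lines(self) -> set[str]:
        return {r.cell_line for r in self.rows}


#: bundled accounting of the BENGI-derived benchmark pair tables used for
#: training (GM12878, HeLa-S3) and independent testing (HMEC, IMR90, K562,
#: NHEK), broken down by interaction evidence source.
BENCHMARK_MANIFEST = DatasetManifest(rows=[
    ManifestRow("GM12878", "Hi-C", 2695, 46_212),
    ManifestRow("GM12878", "CTCF ChIA-PET", 4817, 36_028),
    ManifestRow("GM12878", "RNAPII ChIA-PET", 24_985, 70_670),
    ManifestRow("HeLa-S3", "Hi-C", 2256, 21_086),
    ManifestRow("HeLa-S3", "CTCF ChIA-PET", 1346, 10_789),
    ManifestRow("HeLa-S3", "RNAPII ChIA-PET", 744, 2182),
    ManifestRow("HMEC", "Hi-C", 2286, 20_019),
    ManifestRow("IMR90", "Hi-C", 1468, 13_268),
    ManifestRow("K562", "Hi-C", 2765, 73_299),
    ManifestRow("NHEK", "Hi-C", 1820, 13_582),
])

TRAINING_CELL_LINES = ("GM12878", "HeLa-S3")
TEST_CELL_LINES = ("HMEC", "IMR90", "K562", "NHEK")


def manifest_stats(manifest: DatasetManifest,
                   cell_lines: Iterable[str] | None = None) -> tuple[int, int]:
    """Total (positive, negative) pair counts over the requested cell lines."""
    if cell_lines is None:
        selected = manifest.rows
    else:
        requested = list(cell_lines)
        known = manifest.cell_lines()
        unknown = [c for c in requested if c not in known]
        if unknown:
            raise KeyError(f"unknown cell line(s): {unknown}")
        wanted = set(requested)
        selected = [r for r in manifest.rows if r.cell_line in wanted]
    return (sum(r.n_positive for r in selected),
            sum(r.n_negative for r in selected))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def promoter_from_tss(chrom: str, tss: int, strand: str,
                      pair_id: str = "") -> GenomicInterval:
    """Promoter span around a TSS: 1500 bp upstream to 500 bp downstream.

    Upstream/downstream follow the gene's strand; the interval is clipped at
    the chromosome origin.
    """
    if tss < 0:
        raise ValueError(f"TSS must be nonnegative, got {tss}")
    if strand == "+":
        start, end = tss - PROMOTER_UPSTREAM_BP, tss + PROMOTER_DOWNSTREAM_BP
    elif strand == "-":
        start, end = tss - PROMOTER_DOWNSTREAM_BP, tss + PROMOTER_UPSTREAM_BP
    else:
        raise ValueError(
            f"unknown strand {strand!r} for pair {pair_id or '?'}")
    return GenomicInterval(chrom, max(0, start), end, strand)


def make_window(pair: EPPair, window_bp: int = DEFAULT_WINDOW_BP,
                chrom_length: int | None = None) -> GenomicInterval:
    """Fixed-size window centered on the midpoint between the two anchors.

    If the centered window would run past the chromosome start (or, when
    ``chrom_length`` is known, past its end) it is shifted to fit, preserving
    its size; both elements always remain inside.
    """
    lo = min(pair.enhancer.start, pair.promoter.start)
    hi = max(pair.enhancer.end, pair.promoter.end)
    if hi - lo > window_bp:
        raise ValueError(
            f"pair {pair.pair_id}: span {hi - lo} bp exceeds window {window_bp} bp")
    mid = (pair.enhancer.center + pair.promoter.center) // 2
    start = mid - window_bp // 2
    if start < 0:
        start = 0
    if chrom_length is not None and start + window_bp > chrom_length:
        start = max(0, chrom_length - window_bp)
    return GenomicInterval(pair.chrom, start, start + window_bp)


def bin_signal(track: SignalTrack, window: GenomicInterval,
               bin_bp: int = DEFAULT_BIN_BP) -> np.ndarray:
    """Arithmetic mean of the per-base signal within each consecutive bin."""
    if window.length % bin_bp:
        raise ValueError(
            f"window length {window.length} not divisible by bin size {bin_bp}")
    vals = track.values(window.chrom, window.start, window.end)
    return vals.reshape(window.length // bin_bp, bin_bp).mean(axis=1)


def distance_channel(window: GenomicInterval, enhancer: GenomicInterval,
                     promoter: GenomicInterval,
                     bin_bp: int = DEFAULT_BIN_BP) -> np.ndarray:
    """Per-bin shortest base-level distance to the enhancer or promoter.

    Bins overlapping either element get 0; otherwise the minimum |x - y| over
    bases x in the bin and y in the nearer element.
    """
    for elem in (enhancer, promoter):
        if not (window.start <= elem.start and elem.end <= window.end):
            raise ValueError(
                f"element {elem.chrom}:{elem.start}-{elem.end} outside window")
    n_bins = window.length // bin_bp
    starts = window.start + bin_bp * np.arange(n_bins)
    ends = starts + bin_bp

    def dist_to(elem: GenomicInterval) -> np.ndarray:
        before = np.maximum(0, elem.start - (ends - 1))   # bin left of element
        after = np.maximum(0, starts - (elem.end - 1))    # bin right of element
        return np.maximum(before, after)                  # one side is 0

    return np.minimum(dist_to(enhancer), dist_to(promoter)).astype(np.float64)


def rasterize_narrowpeak(source: str | Path | Iterable[str],
                         chrom_lengths: dict[str, int],
                         name: str = "CTCF",
                         binary: bool = False) -> SignalTrack:
    """Per-base track from UCSC 10-column narrowPeak records.

    Each covered base takes the peak's signalValue (column 7); overlapping
    peaks take the maximum.  ``binary=True`` records occupancy (0/1) instead.
    """
    if isinstance(source, (str, Path)):
        lines = Path(source).read_text().splitlines()
    else:
        lines = list(source)
    arrays = {c: np.zeros(n, dtype=np.float32) for c, n in chrom_lengths.items()}
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 10:
            raise ValueError(f"narrowPeak line {i}: expected 10 columns, "
                             f"got {len(fields)}")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
            signal = 1.0 if binary else float(fields[6])
        except ValueError as exc:
            raise ValueError(f"narrowPeak line {i}: {exc}") from exc
        if end <= start:
            raise ValueError(f"narrowPeak line {i}: end <= start")
        if chrom not in arrays:
            continue
        arr = arrays[chrom]
        lo, hi = max(0, start), min(len(arr), end)
        if lo < hi:
            np.maximum(arr[lo:hi], signal, out=arr[lo:hi])
    return SignalTrack.from_arrays(name, arrays)


class ChannelNormalizer:
    """Per-channel z-scoring with statistics fitted on training bins only."""

    def __init__(self, mean: np.ndarray | None = None,
                 std: np.ndarray | None = None, sd_floor: float = 1e-8):
        self.mean = None if mean is None else np.asarray(mean, dtype=np.float64)
        self.std = None if std is None else np.asarray(std, dtype=np.float64)
        self.sd_floor = sd_floor

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, binned: Sequence[np.ndarray]) -> "ChannelNormalizer":
        """Fit on stacked (bins, channels) matrices of *training* windows."""
        stacked = np.concatenate([np.asarray(m, dtype=np.float64) for m in binned])
        self.mean = stacked.mean(axis=0)
        self.std = np.maximum(stacked.std(axis=0), self.sd_floor)
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("normalizer used before fitting")
        return (np.asarray(matrix, dtype=np.float64) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist(),
                "sd_floor": self.sd_floor}

    @staticmethod
    def from_dict(d: dict) -> "ChannelNormalizer":
        return ChannelNormalizer(np.asarray(d["mean"]), np.asarray(d["std"]),
                                 d.get("sd_floor", 1e-8))


def featurize(pair: EPPair, tracks: Sequence[SignalTrack],
              normalizer: ChannelNormalizer | None = None,
              window_bp: int = DEFAULT_WINDOW_BP,
              bin_bp: int = DEFAULT_BIN_BP,
              chrom_length: int | None = None,
              log_transform: bool = False) -> FeatureWindow:
    """Build the (bins, channels+1) feature matrix for one pair.

    Signal channels are binned means, optionally log(1+x)-compressed (the
    usual variance-stabilising transform for coverage-like tracks) and
    z-scored when a fitted ``normalizer`` is given; the final channel is the
    per-bin anchor distance divided by the window size so every channel is
    O(1).
    """
    if not tracks:
        raise ValueError(f"pair {pair.pair_id}: no signal tracks supplied")
    window = make_window(pair, window_bp, chrom_length)
    signal = np.stack([bin_signal(t, window, bin_bp) for t in tracks], axis=1)
    if log_transform:
        signal = np.log1p(np.maximum(signal, 0.0))
    if normalizer is not None:
        signal = normalizer.transform(signal)
    dist = distance_channel(window, pair.enhancer, pair.promoter, bin_bp)
    matrix = np.concatenate([signal, (dist / window_bp)[:, None]], axis=1)
    e_bin = (pair.enhancer.center - window.start) // bin_bp
    p_bin = (pair.promoter.center - window.start) // bin_bp
    names = tuple(t.name for t in tracks) + ("distance",)
    return FeatureWindow(window=window, matrix=matrix, channels=names,
                         e_bin=int(e_bin), p_bin=int(p_bin), pair_id=pair.pair_id)


# ---------------------------------------------------------------------------
# pair-table IO (TSV with header; BED6 export; window cache)
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["chrom", "enh_start", "enh_end", "tss", "strand",
                "label", "cell_line", "source"]


def read_pairs(path: str | Path) -> list[EPPair]:
    """Read a pair table (TSV, 0-based coordinates) into EPPair records."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"pair table {path} missing column(s): {missing}")
    pairs = []
    for row in df.itertuples(index=False):
        enh = GenomicInterval(row.chrom, int(row.enh_start), int(row.enh_end))
        prom = promoter_from_tss(row.chrom, int(row.tss), row.strand)
        pairs.append(EPPair(enhancer=enh, promoter=prom, tss=int(row.tss),
                            label=int(row.label), cell_line=str(row.cell_line),
                            source=str(row.source)))
    return pairs


def pairs_to_frame(pairs: Sequence[EPPair]) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [p.chrom for p in pairs],
        "enh_start": [p.enhancer.start for p in pairs],
        "enh_end": [p.enhancer.end for p in pairs],
        "tss": [p.tss for p in pairs],
        "strand": [p.promoter.strand for p in pairs],
        "label": [p.label for p in pairs],
        "cell_line": [p.cell_line for p in pairs],
        "source": [p.source for p in pairs],
    })


def write_pairs(pairs: Sequence[EPPair], path: str | Path) -> None:
    pairs_to_frame(pairs).to_csv(path, sep="\t", index=False)


def write_bed6(intervals: Sequence[GenomicInterval], path: str | Path,
               names: Sequence[str] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            label = names[i] if names else f"elem{i}"
            strand = iv.strand if iv.strand in "+-" else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\t0\t{strand}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Read a UCSC chrom.sizes file (two tab-separated columns)."""
    sizes: dict[str, int] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"chrom.sizes line {i}: expected 2 columns")
        sizes[fields[0]] = int(fields[1])
    return sizes


def save_window(fw: FeatureWindow, directory: str | Path) -> Path:
    """Cache one feature window: binary tensor + JSON sidecar metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = fw.pair_id.replace("/", "_").replace(":", "_").replace("|", "_")
    np.save(directory / f"{stem}.npy", fw.matrix.astype(np.float32))
    meta = {"pair_id": fw.pair_id, "channels": list(fw.channels),
            "chrom": fw.window.chrom, "start": fw.window.start,
            "end": fw.window.end, "e_bin": fw.e_bin, "p_bin": fw.p_bin}
    (directory / f"{stem}.json").write_text(json.dumps(meta))
    return directory / f"{stem}.npy"


def load_window(npy_path: str | Path) -> FeatureWindow:
    npy_path = Path(npy_path)
    meta = json.loads(npy_path.with_suffix(".json").read_text())
    matrix = np.load(npy_path).astype(np.float64)
    window = GenomicInterval(meta["chrom"], meta["start"], meta["end"])
    return FeatureWindow(window=window, matrix=matrix,
                         channels=tuple(meta["channels"]),
                         e_bin=meta["e_bin"], p_bin=meta["p_bin"],
                         pair_id=meta["pair_id"])
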
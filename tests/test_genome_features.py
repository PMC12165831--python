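"""Feature-extraction geometry: promoters, windows, binning, distances."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kansformer_epi.genome_features import (
    BENCHMARK_MANIFEST, ChannelNormalizer, EPPair, GenomicInterval,
    SignalTrack, bin_signal, distance_channel, featurize, make_window,
    manifest_stats, promoter_from_tss, rasterize_narrowpeak, read_pairs,
    write_pairs)


def make_pair(chrom="chr1", enh=(1_000_000, 1_001_000), tss=1_500_000,
              strand="+", label=1):
    enhancer = GenomicInterval(chrom, *enh)
    promoter = promoter_from_tss(chrom, tss, strand)
    return EPPair(enhancer=enhancer, promoter=promoter, tss=tss, label=label)


class TestPromoterFromTss:
    @pytest.mark.parametrize("tss,strand,expected", [
        (10_000, "+", (8_500, 10_500)),     # 1500 bp upstream, 500 down
        (10_000, "-", (9_500, 11_500)),     # mirrored on the minus strand
        (1_000, "+", (0, 1_500)),           # clipped at the chromosome origin
    ])
    def test_offsets(self, tss, strand, expected):
        iv = promoter_from_tss("chr1", tss, strand)
        assert (iv.start, iv.end) == expected

    def test_unknown_strand_names_pair(self):
        with pytest.raises(ValueError, match="pairX"):
            promoter_from_tss("chr1", 1000, ".", pair_id="pairX")


class TestMakeWindow:
    def test_centered(self):
        pair = make_pair(enh=(999_500, 1_000_500), tss=1_500_500, strand="+")
        # enhancer center 1,000,000; promoter [1,499,000, 1,501,000) center 1.5e6
        win = make_window(pair, 2_500_000)
        assert (win.start, win.end) == (0, 2_500_000)

    def test_degenerate_midpoint(self):
        enh = GenomicInterval("chr1", 4_999_500, 5_000_500)
        prom = GenomicInterval("chr1", 4_999_500, 5_000_500)
        pair = EPPair(enhancer=enh, promoter=prom, tss=5_000_000, label=0)
        win = make_window(pair, 2_500_000)
        assert (win.start, win.end) == (3_750_000, 6_250_000)

    def test_left_shift_keeps_elements_inside(self):
        pair = make_pair(enh=(99_500, 100_500), tss=300_500)
        win = make_window(pair, 2_500_000)
        assert (win.start, win.end) == (0, 2_500_000)
        for elem in (pair.enhancer, pair.promoter):
            assert win.start <= elem.start and elem.end <= win.end

    def test_right_shift_with_chrom_length(self):
        pair = make_pair(enh=(2_000_000, 2_001_000), tss=2_200_000)
        win = make_window(pair, 2_500_000, chrom_length=2_400_000)
        assert (win.start, win.end) == (0, 2_500_000)

    def test_span_exceeding_window_errors(self):
        pair = make_pair(enh=(0, 1_000), tss=400_000)
        with pytest.raises(ValueError, match="span"):
            make_window(pair, 100_000)


class TestBinSignal:
    def test_full_scale_window_gives_5000_bins(self):
        track = SignalTrack.from_arrays("DNase", {"chr1": np.zeros(10)})
        win = GenomicInterval("chr1", 0, 2_500_000)
        assert len(bin_signal(track, win, 500)) == 5000

    def test_constant_track(self):
        track = SignalTrack.from_arrays("DNase", {"chr1": np.full(5000, 3.5)})
        win = GenomicInterval("chr1", 0, 5000)
        assert np.allclose(bin_signal(track, win, 500), 3.5)

    def test_single_base_spike(self):
        arr = np.zeros(5000)
        arr[1234] = 10.0
        track = SignalTrack.from_arrays("DNase", {"chr1": arr})
        vals = bin_signal(track, GenomicInterval("chr1", 0, 5000), 500)
        assert vals[2] == pytest.approx(10.0 / 500)
        assert vals[[0, 1, 3, 4]].sum() == 0

    def test_indivisible_window_errors(self):
        track = SignalTrack.from_arrays("x", {"chr1": np.zeros(100)})
        with pytest.raises(ValueError, match="divisible"):
            bin_signal(track, GenomicInterval("chr1", 0, 999), 500)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(1, 40), st.integers(0, 10**9))
    def test_mass_conservation_and_per_base_oracle(self, n_bins, seed):
        """sum(bin means) * bin_bp equals the per-base mass; bins match a loop."""
        bin_bp = 50
        length = n_bins * bin_bp
        r = np.random.default_rng(seed)
        arr = r.gamma(1.0, 1.0, size=length)
        track = SignalTrack.from_arrays("t", {"chr1": arr})
        win = GenomicInterval("chr1", 0, length)
        vals = bin_signal(track, win, bin_bp)
        oracle = np.array([arr[i * bin_bp:(i + 1) * bin_bp].mean()
                           for i in range(n_bins)])
        assert np.allclose(vals, oracle)
        assert np.isclose(vals.sum() * bin_bp, arr.sum(), rtol=1e-6)

    def test_uncovered_bases_count_as_zero(self):
        track = SignalTrack.from_arrays("t", {"chr1": np.full(250, 2.0)})
        win = GenomicInterval("chr1", 0, 500)
        vals = bin_signal(track, win, 500)
        assert vals[0] == pytest.approx(2.0 * 250 / 500)


class TestDistanceChannel:
    def _oracle(self, win, enh, prom, bin_bp):
        n = win.length // bin_bp
        out = np.empty(n)
        for i in range(n):
            bases = np.arange(win.start + i * bin_bp, win.start + (i + 1) * bin_bp)
            best = np.inf
            for elem in (enh, prom):
                epos = np.arange(elem.start, elem.end)
                best = min(best, np.abs(bases[:, None] - epos[None, :]).min())
            out[i] = best
        return out

    def test_overlapping_bins_zero_and_oracle_match(self, rng):
        win = GenomicInterval("chr1", 1000, 1000 + 60 * 50)
        enh = GenomicInterval("chr1", 1500, 1600)
        prom = GenomicInterval("chr1", 3200, 3300)
        got = distance_channel(win, enh, prom, 50)
        oracle = self._oracle(win, enh, prom, 50)
        assert np.array_equal(got, oracle)
        # bins overlapping either element read zero
        assert got[(1500 - 1000) // 50] == 0
        assert got[(3200 - 1000) // 50] == 0

    def test_unimodal_between_elements(self):
        win = GenomicInterval("chr1", 0, 100 * 50)
        enh = GenomicInterval("chr1", 500, 600)
        prom = GenomicInterval("chr1", 4000, 4100)
        got = distance_channel(win, enh, prom, 50)
        inner = got[12:80]
        peak = int(np.argmax(inner))
        assert np.all(np.diff(inner[:peak + 1]) >= 0)
        assert np.all(np.diff(inner[peak:]) <= 0)

    def test_element_outside_window_errors(self):
        win = GenomicInterval("chr1", 0, 1000)
        enh = GenomicInterval("chr1", 1500, 1600)
        prom = GenomicInterval("chr1", 100, 200)
        with pytest.raises(ValueError, match="outside"):
            distance_channel(win, enh, prom, 50)


class TestRasterizeNarrowPeak:
    def _line(self, chrom, start, end, signal):
        return f"{chrom}\t{start}\t{end}\tp\t0\t.\t{signal}\t-1\t-1\t-1"

    def test_single_peak(self):
        track = rasterize_narrowpeak([self._line("chr1", 100, 200, 5.0)],
                                     {"chr1": 300})
        vals = track.values("chr1", 0, 300)
        assert np.all(vals[100:200] == 5.0)
        assert vals[:100].sum() == 0 and vals[200:].sum() == 0

    def test_overlap_takes_max(self):
        lines = [self._line("chr1", 100, 200, 3.0),
                 self._line("chr1", 150, 250, 7.0)]
        track = rasterize_narrowpeak(lines, {"chr1": 300})
        vals = track.values("chr1", 0, 300)
        assert np.all(vals[150:200] == 7.0)
        assert np.all(vals[100:150] == 3.0)

    def test_empty_input_all_zero(self):
        track = rasterize_narrowpeak([], {"chr1": 100})
        assert track.values("chr1", 0, 100).sum() == 0

    def test_malformed_line_reports_number(self):
        with pytest.raises(ValueError, match="line 2"):
            rasterize_narrowpeak([self._line("chr1", 0, 10, 1.0),
                                  "chr1\t5\t6"], {"chr1": 100})

    def test_binary_mode(self):
        track = rasterize_narrowpeak([self._line("chr1", 10, 20, 9.0)],
                                     {"chr1": 50}, binary=True)
        assert np.all(track.values("chr1", 10, 20) == 1.0)


class TestFeaturize:
    def _tracks(self, n, length=20_000):
        r = np.random.default_rng(0)
        return [SignalTrack.from_arrays(f"t{i}",
                                        {"chr1": r.gamma(1, 1, size=length)})
                for i in range(n)]

    def test_channel_counts(self):
        pair = make_pair(enh=(2_000, 3_000), tss=8_000)
        for n_tracks, expect in [(7, 8), (8, 9)]:
            fw = featurize(pair, self._tracks(n_tracks), None,
                           window_bp=10_000, bin_bp=500, chrom_length=20_000)
            assert fw.matrix.shape == (20, expect)

    def test_distance_channel_zero_at_anchors_and_scaled(self):
        pair = make_pair(enh=(2_000, 3_000), tss=8_000)
        fw = featurize(pair, self._tracks(3), None, window_bp=10_000,
                       bin_bp=500, chrom_length=20_000)
        assert fw.matrix[fw.e_bin, -1] == 0
        assert fw.matrix[fw.p_bin, -1] == 0
        assert fw.matrix[:, -1].max() <= 1.0

    def test_deterministic(self):
        pair = make_pair(enh=(2_000, 3_000), tss=8_000)
        tracks = self._tracks(4)
        a = featurize(pair, tracks, None, 10_000, 500, 20_000).matrix
        b = featurize(pair, tracks, None, 10_000, 500, 20_000).matrix
        assert np.array_equal(a, b)

    def test_zero_tracks_map_to_normalizer_zero_image(self):
        pair = make_pair(enh=(2_000, 3_000), tss=8_000)
        zero = [SignalTrack.from_arrays("z", {"chr1": np.zeros(20_000)})]
        norm = ChannelNormalizer(mean=np.array([2.0]), std=np.array([4.0]))
        fw = featurize(pair, zero, norm, 10_000, 500, 20_000)
        assert np.allclose(fw.matrix[:, 0], -0.5)

    def test_no_tracks_errors(self):
        with pytest.raises(ValueError, match="tracks"):
            featurize(make_pair(), [], None)


class TestManifest:
    def test_all_cell_lines_totals(self):
        assert manifest_stats(BENCHMARK_MANIFEST) == (45_182, 307_135)

    def test_training_subset_totals(self):
        assert manifest_stats(BENCHMARK_MANIFEST, ["GM12878", "HeLa-S3"]) == \
            (36_843, 186_967)

    def test_test_subset_totals(self):
        assert manifest_stats(
            BENCHMARK_MANIFEST, ["HMEC", "IMR90", "K562", "NHEK"]) == \
            (8_339, 120_168)

    def test_empty_subset(self):
        assert manifest_stats(BENCHMARK_MANIFEST, []) == (0, 0)

    def test_unknown_cell_line_errors(self):
        with pytest.raises(KeyError, match="HEK293"):
            manifest_stats(BENCHMARK_MANIFEST, ["HEK293"])

    def test_partition_additivity(self):
        lines = sorted(BENCHMARK_MANIFEST.cell_lines())
        whole = manifest_stats(BENCHMARK_MANIFEST, lines)
        parts = [manifest_stats(BENCHMARK_MANIFEST, [c]) for c in lines]
        assert whole == tuple(np.sum(parts, axis=0))


class TestPairTableIO:
    def test_roundtrip(self, tmp_path, tiny_sim):
        pairs = tiny_sim["pairs"][:50]
        path = tmp_path / "pairs.tsv"
        write_pairs(pairs, path)
        back = read_pairs(path)
        assert len(back) == len(pairs)
        for a, b in zip(pairs, back):
            assert a.enhancer == b.enhancer
            assert a.tss == b.tss and a.label == b.label
            assert a.distance_bp == b.distance_bp

    def test_missing_column_errors(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tenh_start\nchr1\t0\n")
        with pytest.raises(ValueError, match="missing column"):
            read_pairs(path)


class TestWindowCacheAndChromSizes:
    def test_window_cache_roundtrip(self, tmp_path):
        from kansformer_epi.genome_features import load_window, save_window
        pair = make_pair(enh=(2_000, 3_000), tss=8_000)
        r = np.random.default_rng(1)
        tracks = [SignalTrack.from_arrays(
            "DNase", {"chr1": r.gamma(1, 1, size=20_000)})]
        fw = featurize(pair, tracks, None, 10_000, 500, 20_000)
        path = save_window(fw, tmp_path)
        back = load_window(path)
        assert back.pair_id == fw.pair_id
        assert back.channels == fw.channels
        assert (back.e_bin, back.p_bin) == (fw.e_bin, fw.p_bin)
        assert np.allclose(back.matrix, fw.matrix, atol=1e-6)  # float32 cache

    def test_read_chrom_sizes(self, tmp_path):
        from kansformer_epi.genome_features import read_chrom_sizes
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1\t248956422\nchr2\t242193529\n")
        assert read_chrom_sizes(p) == {"chr1": 248956422, "chr2": 242193529}
        bad = tmp_path / "bad.sizes"
        bad.write_text("chr1 100\n")
        with pytest.raises(ValueError, match="line 1"):
            read_chrom_sizes(bad)


class TestEPPairInvariants:
    def test_cross_chromosome_rejected(self):
        enh = GenomicInterval("chr1", 0, 100)
        prom = GenomicInterval("chr2", 0, 100)
        with pytest.raises(ValueError, match="chr2"):
            EPPair(enhancer=enh, promoter=prom, tss=50, label=0)

    def test_distance_cap(self):
        enh = GenomicInterval("chr1", 0, 100)
        prom = GenomicInterval("chr1", 3_000_000, 3_000_100)
        with pytest.raises(ValueError, match="exceeds"):
            EPPair(enhancer=enh, promoter=prom, tss=3_000_050, label=0)

    def test_overlap_distance_zero(self):
        enh = GenomicInterval("chr1", 0, 100)
        prom = GenomicInterval("chr1", 50, 150)
        assert EPPair(enhancer=enh, promoter=prom, tss=60,
                      label=1).distance_bp == 0
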
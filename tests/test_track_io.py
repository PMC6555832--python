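import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oncochrom.errors import (
    DimensionError,
    NormalizationError,
    ParseError,
    ValidationError,
)
from oncochrom.genome import AUTOSOME, X, Chromosome, GenomeAssembly
from oncochrom.track_io import (
    STATE_LOGRATIO,
    STATE_SCALED,
    BinnedTrack,
    ReadPlacements,
    bin_coverage,
    coverage_uniformity,
    merge_replicates,
    normalize_input,
    read_bedgraph,
    rebin,
    scale_to_total,
    smooth,
    write_bedgraph,
)

from _oracles import per_base_bin_max, rebin_loop, smooth_loop


def tiny_assembly(length=100):
    return GenomeAssembly(
        (Chromosome("chrI", length, AUTOSOME), Chromosome("chrX", length, X))
    )


def random_track(assembly, bin_size, rng, state=STATE_LOGRATIO, positive=False):
    values = {}
    for c in assembly:
        v = rng.normal(0, 1, assembly.n_bins(c.name, bin_size))
        values[c.name] = np.abs(v) + 0.1 if positive else v
    return BinnedTrack(assembly, bin_size, values, state=state)


# ---------------------------------------------------------------------------
# bin_coverage


class TestBinCoverage:
    def test_single_fragment_single_bin(self):
        asm = tiny_assembly(100)
        track = bin_coverage(
            ReadPlacements({"chrI": [(0, 10)]}), asm, bin_size=100
        )
        assert track.values["chrI"].tolist() == [1.0]
        assert track.values["chrX"].tolist() == [0.0]
        assert track.state == "raw"
        assert track.read_total == 1

    def test_overlapping_fragments_stack(self):
        asm = tiny_assembly(100)
        track = bin_coverage(
            ReadPlacements({"chrI": [(0, 10), (5, 15)]}), asm, bin_size=100
        )
        assert track.values["chrI"].tolist() == [2.0]

    def test_random_fragments_match_per_base_oracle(self):
        rng = np.random.default_rng(0)
        asm = tiny_assembly(10_000)
        for _ in range(25):
            starts = rng.integers(0, 9_800, size=200)
            frags = [(int(s), int(s + rng.integers(1, 200))) for s in starts]
            frags = [(s, min(e, 10_000)) for s, e in frags]
            track = bin_coverage(ReadPlacements({"chrI": frags}), asm, 1000)
            expected = per_base_bin_max(frags, 10_000, 1000)
            np.testing.assert_array_equal(track.values["chrI"], expected)

    def test_out_of_bounds_rejected(self):
        asm = tiny_assembly(100)
        with pytest.raises(ValidationError):
            bin_coverage(ReadPlacements({"chrI": [(90, 110)]}), asm, 100)
        with pytest.raises(ValidationError):
            bin_coverage(ReadPlacements({"chrZ": [(0, 10)]}), asm, 100)

    def test_count_statistic(self):
        asm = tiny_assembly(200)
        # one fragment spanning the bin boundary counts in both bins
        track = bin_coverage(
            ReadPlacements({"chrI": [(90, 110)]}), asm, 100, statistic="count"
        )
        assert track.values["chrI"].tolist() == [1.0, 1.0]

    def test_trailing_partial_bin(self):
        asm = GenomeAssembly(
            (Chromosome("chrI", 250, AUTOSOME), Chromosome("chrX", 250, X))
        )
        track = bin_coverage(ReadPlacements({"chrI": [(200, 250)]}), asm, 100)
        assert track.values["chrI"].size == 3
        assert track.values["chrI"].tolist() == [0.0, 0.0, 1.0]


# ---------------------------------------------------------------------------
# scale_to_total / merge_replicates


class TestScaling:
    def test_identity(self):
        asm = tiny_assembly()
        t = bin_coverage(ReadPlacements({"chrI": [(0, 50)]}), asm, 100)
        scaled = scale_to_total(t, 1)
        np.testing.assert_array_equal(scaled.values["chrI"], t.values["chrI"])
        assert scaled.state == STATE_SCALED

    def test_doubling(self):
        asm = tiny_assembly()
        t = bin_coverage(ReadPlacements({"chrI": [(0, 50)]}), asm, 100)
        scaled = scale_to_total(t, 2)
        np.testing.assert_array_equal(scaled.values["chrI"], 2 * t.values["chrI"])

    def test_elementwise_oracle(self):
        rng = np.random.default_rng(1)
        asm = tiny_assembly(1000)
        for _ in range(20):
            v = {c: rng.integers(0, 50, 10).astype(float) for c in ("chrI", "chrX")}
            t = BinnedTrack(asm, 100, v, state="raw", read_total=500.0)
            target = float(rng.integers(1, 2000))
            scaled = scale_to_total(t, target)
            for c in v:
                expected = np.array([x * target / 500.0 for x in v[c]])
                np.testing.assert_allclose(scaled.values[c], expected, rtol=1e-12)

    def test_zero_total_rejected(self):
        asm = tiny_assembly()
        t = BinnedTrack(asm, 100, {"chrI": np.zeros(1), "chrX": np.zeros(1)},
                        state="raw", read_total=0.0)
        with pytest.raises(NormalizationError):
            scale_to_total(t, 1000)

    def test_merge_single_identity(self):
        asm = tiny_assembly()
        t = bin_coverage(ReadPlacements({"chrI": [(0, 50)]}), asm, 100)
        merged = merge_replicates([t])
        np.testing.assert_array_equal(merged.values["chrI"], t.values["chrI"])

    def test_merge_two_identical_doubles(self):
        asm = tiny_assembly()
        t = bin_coverage(ReadPlacements({"chrI": [(0, 50)]}), asm, 100)
        merged = merge_replicates([t, t])
        np.testing.assert_array_equal(merged.values["chrI"], 2 * t.values["chrI"])
        assert merged.read_total == 2 * t.read_total

    def test_merge_three_random_sum_oracle(self):
        rng = np.random.default_rng(2)
        asm = tiny_assembly(1000)
        tracks = [
            BinnedTrack(asm, 100,
                        {c: rng.integers(0, 9, 10).astype(float) for c in ("chrI", "chrX")},
                        state="raw", read_total=10.0)
            for _ in range(3)
        ]
        merged = merge_replicates(tracks)
        for c in ("chrI", "chrX"):
            expected = sum(t.values[c] for t in tracks)
            np.testing.assert_array_equal(merged.values[c], expected)

    def test_merge_empty_rejected(self):
        with pytest.raises(ValidationError):
            merge_replicates([])


# ---------------------------------------------------------------------------
# normalize_input


class TestNormalizeInput:
    def _pair(self, rng, positive=True):
        asm = tiny_assembly(1000)
        ip = random_track(asm, 100, rng, state=STATE_SCALED, positive=True)
        inp = random_track(asm, 100, rng, state=STATE_SCALED, positive=True)
        return ip, inp

    def test_delta_of_self_is_zero(self):
        ip, _ = self._pair(np.random.default_rng(3))
        out = normalize_input(ip, ip, method="delta")
        for c in out.values:
            np.testing.assert_array_equal(out.values[c], 0.0)
        assert out.state == "delta"

    def test_logratio_of_double_is_one(self):
        ip, _ = self._pair(np.random.default_rng(4))
        doubled = ip.like({c: 2 * v for c, v in ip.values.items()})
        out = normalize_input(doubled, ip, method="logratio", pseudocount=0.0)
        for c in out.values:
            np.testing.assert_allclose(out.values[c], 1.0, rtol=1e-12)

    def test_elementwise_formula_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ip, inp = self._pair(rng)
            delta = normalize_input(ip, inp, method="delta")
            logr = normalize_input(ip, inp, method="logratio", pseudocount=1.0)
            for c in ip.values:
                np.testing.assert_allclose(
                    delta.values[c],
                    [a - b for a, b in zip(ip.values[c], inp.values[c])],
                )
                np.testing.assert_allclose(
                    logr.values[c],
                    [np.log2((a + 1) / (b + 1))
                     for a, b in zip(ip.values[c], inp.values[c])],
                )

    def test_logratio_antisymmetry(self):
        rng = np.random.default_rng(6)
        ip, inp = self._pair(rng)
        ab = normalize_input(ip, inp, method="logratio", pseudocount=0.0)
        ba = normalize_input(inp, ip, method="logratio", pseudocount=0.0)
        for c in ab.values:
            np.testing.assert_allclose(ab.values[c], -ba.values[c], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(7)
        asm = tiny_assembly(1000)
        ip = random_track(asm, 100, rng, state=STATE_SCALED, positive=True)
        inp = random_track(asm, 200, rng, state=STATE_SCALED, positive=True)
        with pytest.raises(DimensionError):
            normalize_input(ip, inp, method="delta")

    def test_unknown_method_rejected(self):
        ip, inp = self._pair(np.random.default_rng(8))
        with pytest.raises(ValidationError):
            normalize_input(ip, inp, method="ratio")


# ---------------------------------------------------------------------------
# smooth / rebin


class TestSmooth:
    def test_window_one_is_identity(self):
        rng = np.random.default_rng(9)
        t = random_track(tiny_assembly(1000), 100, rng)
        out = smooth(t, 1)
        for c in t.values:
            np.testing.assert_array_equal(out.values[c], t.values[c])

    def test_constant_track_unchanged(self, track_factory):
        t = track_factory(fill=3.25)
        out = smooth(t, 5)
        for c in out.values:
            np.testing.assert_allclose(out.values[c], 3.25, rtol=1e-14)

    def test_window5_matches_loop_oracle(self):
        rng = np.random.default_rng(10)
        asm = tiny_assembly(10_000)
        for _ in range(20):
            t = random_track(asm, 100, rng)
            out = smooth(t, 5)
            for c in t.values:
                np.testing.assert_allclose(
                    out.values[c], smooth_loop(list(t.values[c]), 5), rtol=1e-12
                )

    def test_even_window_rejected(self, track_factory):
        with pytest.raises(ValidationError):
            smooth(track_factory(), 4)

    def test_raw_track_rejected(self):
        asm = tiny_assembly()
        t = BinnedTrack(asm, 100, {"chrI": np.ones(1), "chrX": np.ones(1)}, state="raw")
        with pytest.raises(ValidationError):
            smooth(t, 3)

    @given(window=st.sampled_from([3, 5, 7, 9]), seed=st.integers(0, 1000))
    @settings(max_examples=30, deadline=None)
    def test_range_preserved(self, window, seed):
        rng = np.random.default_rng(seed)
        t = random_track(tiny_assembly(2000), 100, rng)
        out = smooth(t, window)
        for c in t.values:
            assert out.values[c].min() >= t.values[c].min() - 1e-12
            assert out.values[c].max() <= t.values[c].max() + 1e-12


class TestRebin:
    def test_same_size_identity(self):
        rng = np.random.default_rng(11)
        t = random_track(tiny_assembly(1000), 100, rng)
        out = rebin(t, 100)
        for c in t.values:
            np.testing.assert_array_equal(out.values[c], t.values[c])

    def test_constant_groups(self):
        asm = tiny_assembly(1000)
        t = BinnedTrack(asm, 100, {c: np.full(10, 2.0) for c in ("chrI", "chrX")},
                        state=STATE_LOGRATIO)
        out = rebin(t, 1000)
        for c in out.values:
            assert out.values[c].tolist() == [2.0]

    def test_partial_group_mean_oracle(self):
        # 42500 bp at 1 kb -> 43 fine bins; at 10 kb -> 5 coarse, last has 3 members
        asm = GenomeAssembly(
            (Chromosome("chrI", 42_500, AUTOSOME), Chromosome("chrX", 42_500, X))
        )
        rng = np.random.default_rng(12)
        for _ in range(20):
            t = random_track(asm, 1000, rng)
            out = rebin(t, 10_000)
            for c in t.values:
                np.testing.assert_allclose(
                    out.values[c], rebin_loop(list(t.values[c]), 10), rtol=1e-12
                )

    def test_non_multiple_rejected(self):
        rng = np.random.default_rng(13)
        t = random_track(tiny_assembly(1000), 100, rng)
        with pytest.raises(ValidationError):
            rebin(t, 250)

    def test_bin_counts_follow_ceil_rule(self):
        asm = GenomeAssembly(
            (Chromosome("chrI", 42_500, AUTOSOME), Chromosome("chrX", 9_999, X))
        )
        rng = np.random.default_rng(14)
        t = random_track(asm, 1000, rng)
        out = rebin(t, 10_000)
        assert out.values["chrI"].size == 5
        assert out.values["chrX"].size == 1


# ---------------------------------------------------------------------------
# bedGraph I/O


class TestBedgraphIO:
    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(15)
        asm = tiny_assembly(1050)  # partial trailing bin
        t = random_track(asm, 100, rng)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(t, path)
        back = read_bedgraph(path, asm, 100)
        assert back.state == t.state
        for c in t.values:
            np.testing.assert_array_equal(back.values[c], t.values[c])

    def test_empty_file_reads_as_zero(self, tmp_path):
        asm = tiny_assembly()
        path = tmp_path / "empty.bedgraph"
        path.write_text("")
        t = read_bedgraph(path, asm, 100)
        for c in t.values:
            np.testing.assert_array_equal(t.values[c], 0.0)

    def test_hand_written_file(self, tmp_path):
        asm = tiny_assembly(500)
        path = tmp_path / "hand.bedgraph"
        path.write_text(
            "chrI\t0\t100\t1.5\n"
            "chrI\t100\t300\t-2.0\n"
            "chrI\t400\t500\t0.25\n"
            "chrX\t0\t100\t3.0\n"
            "chrX\t200\t300\t-1.0\n"
        )
        t = read_bedgraph(path, asm, 100, state=STATE_LOGRATIO)
        assert t.values["chrI"].tolist() == [1.5, -2.0, -2.0, 0.0, 0.25]
        assert t.values["chrX"].tolist() == [3.0, 0.0, -1.0, 0.0, 0.0]

    @pytest.mark.parametrize(
        "line",
        [
            "chrI\t0\t100",  # 3 columns
            "chrZ\t0\t100\t1.0",  # unknown chromosome
            "chrI\t0\tx\t1.0",  # bad int
            "chrI\t50\t100\t1.0",  # not grid-aligned
            "chrI\t0\t600\t1.0",  # out of bounds
        ],
    )
    def test_malformed_lines_raise_with_line_number(self, tmp_path, line):
        asm = tiny_assembly(500)
        path = tmp_path / "bad.bedgraph"
        path.write_text("chrI\t0\t100\t1.0\n" + line + "\n")
        with pytest.raises(ParseError) as err:
            read_bedgraph(path, asm, 100)
        assert err.value.line == 2

    def test_overlapping_records_rejected(self, tmp_path):
        asm = tiny_assembly(500)
        path = tmp_path / "ovl.bedgraph"
        path.write_text("chrI\t0\t200\t1.0\nchrI\t100\t300\t2.0\n")
        with pytest.raises(ParseError):
            read_bedgraph(path, asm, 100)


# ---------------------------------------------------------------------------
# coverage uniformity


class TestUniformity:
    def test_identical_tracks(self):
        rng = np.random.default_rng(16)
        t = random_track(tiny_assembly(1000), 100, rng, state=STATE_SCALED, positive=True)
        rep = coverage_uniformity(t, t)
        assert rep.sd == 0.0
        assert rep.mad == 0.0
        assert rep.outlier_fraction == 0.0

    def test_one_bin_doubled(self):
        asm = tiny_assembly(1000)
        base = {c: np.full(10, 4.0) for c in ("chrI", "chrX")}
        ref = BinnedTrack(asm, 100, base, state=STATE_SCALED)
        samp_vals = {c: v.copy() for c, v in base.items()}
        samp_vals["chrI"][3] = 8.0
        samp = BinnedTrack(asm, 100, samp_vals, state=STATE_SCALED)
        rep = coverage_uniformity(samp, ref, pseudocount=0.0, threshold=0.5)
        flat = rep.log2_ratio.flatten()
        assert np.sum(flat == 1.0) == 1
        assert np.sum(flat == 0.0) == flat.size - 1
        assert rep.outlier_fraction == pytest.approx(1 / flat.size)

    def test_sd_matches_oracle(self):
        rng = np.random.default_rng(17)
        asm = tiny_assembly(1000)
        a = random_track(asm, 100, rng, state=STATE_SCALED, positive=True)
        b = random_track(asm, 100, rng, state=STATE_SCALED, positive=True)
        rep = coverage_uniformity(a, b, pseudocount=1.0)
        manual = np.concatenate(
            [np.log2((a.values[c] + 1) / (b.values[c] + 1)) for c in ("chrI", "chrX")]
        )
        assert rep.sd == pytest.approx(float(np.std(manual)), rel=1e-12)
        assert rep.mad == pytest.approx(
            float(np.median(np.abs(manual - np.median(manual)))), rel=1e-12
        )


def test_grid_conservation_across_ops():
    rng = np.random.default_rng(18)
    asm = tiny_assembly(1050)
    t = random_track(asm, 100, rng)
    for out in (smooth(t, 5), rebin(t, 100)):
        for c in t.values:
            assert out.values[c].size == t.values[c].size
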
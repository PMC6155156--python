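import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spermhist.intervals_io import (
    BedParseError,
    CoverageTrack,
    EmptyQueryError,
    GeneModel,
    GenomicInterval,
    StructuralError,
    benjamini_hochberg,
    enrichment_screen,
    merge_intervals,
    overlap_count,
    read_bed,
    read_bedgraph,
    read_genes,
    write_bed,
    write_bedgraph,
    write_genes,
)


# ---------------------------------------------------------------------------
# GenomicInterval / GeneModel invariants
# ---------------------------------------------------------------------------

class TestGenomicInterval:
    def test_valid(self):
        iv = GenomicInterval("chr1", 100, 200, "+", "p1", 8.2)
        assert len(iv) == 100 and iv.midpoint == 150

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="chr1", start=200, end=100),
            dict(chrom="chr1", start=100, end=100),
            dict(chrom="chr1", start=-1, end=100),
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_overlap_is_strand_blind(self):
        a = GenomicInterval("chr1", 0, 100, "+")
        b = GenomicInterval("chr1", 99, 150, "-")
        c = GenomicInterval("chr1", 100, 150)
        assert a.overlaps(b) and not a.overlaps(c)


class TestGeneModel:
    def test_minus_strand_tss_is_five_prime(self):
        g = GeneModel.from_tx("g", "chr1", "-", 1000, 5000)
        assert g.tss == 5000 and g.tes == 1000
        assert g.promoter_window(1000) == (4000, 6000)

    def test_exons_must_fit_body(self):
        with pytest.raises(ValueError):
            GeneModel.from_tx("g", "chr1", "+", 1000, 2000, [(900, 1500)])

    def test_round_trip(self, tmp_path):
        genes = [
            GeneModel.from_tx("a", "chr1", "+", 100, 900, [(100, 300), (500, 900)]),
            GeneModel.from_tx("b", "chr2", "-", 50, 600, [(50, 600)]),
        ]
        path = tmp_path / "genes.tsv"
        write_genes(genes, path)
        assert read_genes(path) == genes


# ---------------------------------------------------------------------------
# BED I/O
# ---------------------------------------------------------------------------

class TestBedIO:
    def test_bed6_line(self, tmp_path):
        path = tmp_path / "a.bed"
        path.write_text("chr1\t100\t200\tp1\t8.2\t+\n")
        (iv,) = read_bed(path)
        assert iv == GenomicInterval("chr1", 100, 200, "+", "p1", 8.2)

    def test_reversed_coordinates_fail_with_line_number(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t200\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(path)

    @pytest.mark.parametrize("line", ["chr1\t100", "chr1\tx\t200", "chr1\t-5\t10"])
    def test_malformed(self, tmp_path, line):
        path = tmp_path / "bad.bed"
        path.write_text(line + "\n")
        with pytest.raises(BedParseError):
            read_bed(path)

    @settings(max_examples=25, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2", "chrX"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
                st.sampled_from(["+", "-", "."]),
                st.floats(-100, 100, allow_nan=False),
            ),
            max_size=50,
        )
    )
    def test_round_trip_property(self, tmp_path_factory, raw):
        intervals = [
            GenomicInterval(c, s, s + w, strand, f"iv{i}", round(score, 3))
            for i, (c, s, w, strand, score) in enumerate(raw)
        ]
        path = tmp_path_factory.mktemp("bed") / "rt.bed"
        write_bed(intervals, path)
        assert read_bed(path) == intervals


class TestBedgraph:
    def test_round_trip(self, tmp_path, rng):
        track = CoverageTrack(
            50, {"chr1": rng.integers(0, 20, 40), "chr2": rng.integers(0, 20, 30)}, 5000
        )
        path = tmp_path / "cov.bedGraph"
        write_bedgraph(track, path)
        back = read_bedgraph(path, 5000)
        assert back.bin_width == 50
        for chrom in track.counts:
            np.testing.assert_array_equal(back.counts[chrom], track.counts[chrom])

    def test_off_grid_rejected(self, tmp_path):
        path = tmp_path / "cov.bedGraph"
        path.write_text("chr1\t0\t50\t1\nchr1\t60\t110\t2\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bedgraph(path, 100)


# ---------------------------------------------------------------------------
# overlap_count
# ---------------------------------------------------------------------------

def brute_force_overlap(a, b):
    """O(|a|*|b|) oracle."""
    return sum(1 for x in a if any(x.overlaps(y) for y in b))


class TestOverlapCount:
    def test_self_overlap(self):
        a = [GenomicInterval("chr1", 100, 200)]
        assert overlap_count(a, a) == (1, 1.0)

    def test_enumerated_example(self):
        a = [GenomicInterval("c", 0, 100), GenomicInterval("c", 200, 300),
             GenomicInterval("c", 400, 500)]
        b = [GenomicInterval("c", 250, 260), GenomicInterval("c", 450, 455),
             GenomicInterval("c", 600, 700)]
        n, frac = overlap_count(a, b)
        assert n == brute_force_overlap(a, b) == 2
        assert frac == pytest.approx(2 / 3, abs=1e-12)

    def test_empty_query_is_an_error(self):
        with pytest.raises(EmptyQueryError):
            overlap_count([], [GenomicInterval("c", 0, 10)])

    def test_empty_subject(self):
        assert overlap_count([GenomicInterval("c", 0, 10)], []) == (0, 0.0)

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_matches_brute_force(self, data):
        def mk(n):
            return [
                GenomicInterval(
                    data.draw(st.sampled_from(["chr1", "chr2"])),
                    (s := data.draw(st.integers(0, 2000))),
                    s + data.draw(st.integers(1, 300)),
                )
                for _ in range(n)
            ]

        a = mk(data.draw(st.integers(1, 30)))
        b = mk(data.draw(st.integers(0, 30)))
        n, frac = overlap_count(a, b)
        assert n == brute_force_overlap(a, b)
        assert n <= len(a) and frac == n / len(a)

    def test_monotone_in_b(self, rng):
        a = [GenomicInterval("c", int(s), int(s) + 10) for s in rng.integers(0, 5000, 50)]
        b = [GenomicInterval("c", int(s), int(s) + 10) for s in rng.integers(0, 5000, 50)]
        prev = 0
        for k in range(0, 51, 10):
            n, _ = overlap_count(a, b[:k]) if k else (0, 0.0)
            assert n >= prev
            prev = n

    def test_merge_intervals(self):
        merged = merge_intervals(
            [GenomicInterval("c", 0, 10), GenomicInterval("c", 5, 20),
             GenomicInterval("c", 30, 40)]
        )
        assert [(m.start, m.end) for m in merged] == [(0, 20), (30, 40)]


# ---------------------------------------------------------------------------
# enrichment screen
# ---------------------------------------------------------------------------

def exact_poisson_upper_tail(k, lam, terms=500):
    """P(X >= k) by direct summation of upper-tail pmf terms in log space."""
    return sum(
        math.exp(-lam + i * math.log(lam) - math.lgamma(i + 1))
        for i in range(k, k + terms)
    )


class TestEnrichmentScreen:
    def _flat_tracks(self, chip_bins, input_bins, total=1e6):
        chip = CoverageTrack(50, {"chr1": np.asarray(chip_bins, float)}, total)
        inp = CoverageTrack(50, {"chr1": np.asarray(input_bins, float)}, total)
        return chip, inp

    def test_strong_bin_retained(self):
        chip_bins = np.ones(200)
        chip_bins[100] = 50.0
        inp_bins = np.full(200, 5.0)
        chip, inp = self._flat_tracks(chip_bins, inp_bins)
        peaks = enrichment_screen(chip, inp, fdr_max=0.01, fc_min=5.0)
        assert len(peaks) == 1
        (p,) = peaks
        assert (p.start, p.end) == (100 * 50, 101 * 50)
        assert p.fold_change == pytest.approx(10.0)
        # oracle: exact Poisson tail is astronomically small and matches the
        # library tail used by the implementation
        from scipy.stats import poisson

        oracle = exact_poisson_upper_tail(50, 5.0)
        assert oracle < 1e-20
        assert poisson.sf(49, 5.0) == pytest.approx(oracle, rel=1e-9)

    def test_chip_equals_input_yields_no_peaks(self):
        bins = np.full(100, 7.0)
        chip, inp = self._flat_tracks(bins, bins)
        assert len(enrichment_screen(chip, inp)) == 0

    def test_adjacent_bins_merge(self):
        chip_bins = np.ones(100)
        chip_bins[20] = chip_bins[21] = 60.0
        inp_bins = np.ones(100)
        chip, inp = self._flat_tracks(chip_bins, inp_bins)
        peaks = enrichment_screen(chip, inp)
        assert len(peaks) == 1
        (p,) = peaks
        assert (p.start, p.end) == (1000, 1100)

    def test_depth_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        chip_bins = rng.poisson(3, 300).astype(float)
        chip_bins[50:55] = 80
        inp_bins = rng.poisson(3, 300).astype(float)
        chip, inp = self._flat_tracks(chip_bins, inp_bins, total=1e6)
        chip2 = CoverageTrack(50, {"chr1": chip_bins}, 7e6)
        inp2 = CoverageTrack(50, {"chr1": inp_bins}, 7e6)
        p1 = enrichment_screen(chip, inp)
        p2 = enrichment_screen(chip2, inp2)
        assert [(p.start, p.end) for p in p1] == [(p.start, p.end) for p in p2]

    def test_retained_peaks_satisfy_thresholds_independently(self):
        rng = np.random.default_rng(1)
        chip_bins = rng.poisson(2, 500).astype(float)
        chip_bins[rng.integers(0, 500, 10)] += 40
        inp_bins = rng.poisson(2, 500).astype(float)
        chip, inp = self._flat_tracks(chip_bins, inp_bins)
        for p in enrichment_screen(chip, inp, fdr_max=0.01, fc_min=5.0):
            assert p.fold_change > 5.0 and p.fdr < 0.01

    def test_grid_mismatch(self):
        chip = CoverageTrack(50, {"chr1": np.ones(10)}, 100)
        inp = CoverageTrack(100, {"chr1": np.ones(10)}, 100)
        with pytest.raises(StructuralError):
            enrichment_screen(chip, inp)

    def test_bad_fdr(self):
        chip = CoverageTrack(50, {"chr1": np.ones(10)}, 100)
        with pytest.raises(ValueError):
            enrichment_screen(chip, chip, fdr_max=0.0)


def test_benjamini_hochberg_against_reference():
    p = np.array([0.01, 0.04, 0.03, 0.005])
    from scipy.stats import false_discovery_control

    np.testing.assert_allclose(benjamini_hochberg(p), false_discovery_control(p))
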
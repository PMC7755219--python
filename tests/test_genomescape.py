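"""Genomescape tracks, SOS window scores and predicted-peak ranking."""
import numpy as np
import pytest

from oracles import revcomp, sos_brute
from polyscape import presets, sequences as sq
from polyscape.cosmic import interval_overlap_fraction
from polyscape.enrichment import EnrichmentTable
from polyscape.genomescape import (GenomeTrack, genomescape, profile_matrix,
                                   region_profile, sos, top_peaks)


def toy_table(k, z_by_kmer=None, default=0.0):
    size = 4**k
    z = np.full(size, default)
    for kmer, val in (z_by_kmer or {}).items():
        z[sq.kmer_to_code(kmer)] = val
    return EnrichmentTable(k=k, observed=np.zeros(size), expected=np.zeros(size),
                           ratio=np.zeros(size), z=z, n_windows=0)


class TestGenomescape:
    def test_sequence_shorter_than_k_gives_empty_track(self):
        track = genomescape("ACGTACG", toy_table(8))
        assert track.n_values == 0

    def test_values_are_strand_max_lookups(self):
        seq = "ACGTACGTACGT"
        table = toy_table(8)
        rng = np.random.default_rng(3)
        table.z[:] = rng.normal(size=4**8)
        track = genomescape(seq, table)
        for i in range(len(seq) - 7):
            word = seq[i : i + 8]
            want = max(table.z_of(word), table.z_of(revcomp(word)))
            assert track.values[i] == pytest.approx(want)

    def test_revcomp_sequence_gives_mirrored_track(self):
        seq = "ACGTTGCAACGGATTACGGATCAA"
        table = toy_table(8)
        table.z[:] = np.random.default_rng(5).normal(size=4**8)
        fwd = genomescape(seq, table)
        rev = genomescape(revcomp(seq), table)
        assert np.allclose(fwd.values, rev.values[::-1], equal_nan=True)

    def test_non_acgt_windows_are_skipped(self):
        seq = "ACGTNACGTACGTACG"  # N at index 4 spoils window starts 0..4
        track = genomescape(seq, toy_table(8, default=1.0))
        assert np.isnan(track.values[:5]).all()
        assert track.n_values == len(seq) - 8 + 1 - 5


class TestSos:
    def test_constant_track_arithmetic(self):
        # 630-bp contig: windows at 0 and 210 only, each containing 413
        # fully-enclosed 8-mers of value c
        c = 2.5
        seq = "A" * 630
        windows = sos(genomescape(seq, toy_table(8, default=c)))
        frame = windows.frame
        assert list(frame["start"]) == [0, 210]
        assert np.allclose(frame["score"], 413 * c)
        assert list(frame["n_kmers"]) == [413, 413]

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(8)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 2000))
        table = toy_table(8)
        table.z[:] = rng.normal(size=4**8)
        track = genomescape(seq, table)
        windows = sos(track, window=420, step=210)
        values = {i: track.values[i] for i in track.starts}
        brute = sos_brute(values, len(seq), 8, 420, 210)
        assert len(brute) == len(windows.frame)
        for (start, score, n), row in zip(brute, windows.frame.itertuples()):
            assert row.start == start
            assert row.score == pytest.approx(score)
            assert row.n_kmers == n

    def test_mean_mode_is_sum_over_count(self):
        rng = np.random.default_rng(9)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 1500))
        table = toy_table(8)
        table.z[:] = rng.normal(size=4**8)
        track = genomescape(seq, table)
        s = sos(track, mode="sum").frame
        m = sos(track, mode="mean").frame
        assert np.allclose(m["score"], s["score"] / s["n_kmers"])

    def test_parameter_validation(self):
        track = genomescape("A" * 500, toy_table(8))
        with pytest.raises(ValueError):
            sos(track, window=4)
        with pytest.raises(ValueError):
            sos(track, window=420, step=211)


class TestTopPeaks:
    def test_requesting_more_than_available_returns_all(self):
        track = genomescape("A" * 1000, toy_table(8, default=1.0))
        peaks = top_peaks(sos(track), n=100)
        assert len(peaks) == len(sos(track).frame)

    def test_constant_scores_rank_by_coordinate(self):
        track = genomescape("A" * 2000, toy_table(8, default=1.0))
        peaks = top_peaks(sos(track), n=4)
        assert list(peaks["start"]) == [0, 210, 420, 630]

    def test_planted_clusters_dominate_top_windows(self, genome_truth, table_m2):
        genome, truth = genome_truth
        track = genomescape(genome, table_m2, contig=truth.contig)
        peaks = top_peaks(sos(track), n=30)
        frac = interval_overlap_fraction(peaks, truth.intervals_for("WGGWCW"))
        assert frac >= 0.9

    def test_cross_model_top_windows_are_disjoint(self, genome_truth,
                                                  table_m1, table_m2):
        genome, truth = genome_truth
        p1 = top_peaks(sos(genomescape(genome, table_m1, contig=truth.contig)), 30)
        p2 = top_peaks(sos(genomescape(genome, table_m2, contig=truth.contig)), 30)
        assert interval_overlap_fraction(p1, p2) <= 0.1


class TestRegionProfile:
    def test_left_edge_is_padded(self):
        track = genomescape("A" * 1000, toy_table(8, default=1.0))
        prof = region_profile(track, center=100, span=400)
        assert np.isnan(prof[:100]).all()
        assert np.allclose(prof[100:300], 1.0)

    def test_zero_span_is_empty(self):
        track = genomescape("A" * 100, toy_table(8))
        assert len(region_profile(track, 50, span=0)) == 0

    def test_extraction_equals_direct_slice(self):
        rng = np.random.default_rng(13)
        seq = "".join("ACGT"[c] for c in rng.integers(0, 4, 3000))
        table = toy_table(8)
        table.z[:] = rng.normal(size=4**8)
        track = genomescape(seq, table)
        prof = region_profile(track, center=1500, span=1000)
        assert np.allclose(prof, track.values[1000:2000], equal_nan=True)

    def test_matrix_rows_stack(self):
        track = genomescape("A" * 5000, toy_table(8, default=1.0))
        mat = profile_matrix(track, [1000, 2000, 3000], span=400)
        assert mat.shape == (3, 400)
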
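"""k-mer counting, Markov background and standardized enrichment."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import (all_kmers, contains_motif_brute, count_kmers_brute,
                     markov_word_prob_brute, revcomp)
from polyscape import sequences as sq
from polyscape.enrichment import (EnrichmentTable, classify_by_motif,
                                  count_kmers, enrich, expected_counts,
                                  fit_markov)


class TestCountKmers:
    def test_homopolymer_read(self):
        table = count_kmers(["A" * 20], k=8)
        assert table.count_of("A" * 8) == 13
        assert table.count_of("T" * 8) == 13
        assert table.n_windows == 26
        assert table.counts.sum() == 26

    def test_matches_brute_force_on_fixed_reads(self):
        reads = ["ACGTACGTACGTACGTACGT", "TTGACCAGTAGGCATNACGT"]
        table = count_kmers(reads, k=5)
        brute = count_kmers_brute(reads, 5)
        for kmer, n in brute.items():
            assert table.count_of(kmer) == n
        assert table.n_windows == sum(brute.values())

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.text(alphabet="ACGT", min_size=4, max_size=12),
                    min_size=1, max_size=5))
    def test_strand_symmetry(self, reads):
        table = count_kmers(reads, k=4)
        rc = sq.revcomp_table(4)
        assert np.array_equal(table.counts, table.counts[rc])

    def test_array_and_string_paths_agree(self):
        reads = ["ACGTACGTACGTACGTACGT", "GGGTTTAAACCCGGGTTTAA"]
        a = count_kmers(reads, k=8)
        b = count_kmers(sq.encode_reads(reads), k=8)
        assert np.array_equal(a.counts, b.counts)


class TestMarkovBackground:
    def test_uniform_background_gives_flat_word_probs(self):
        rng = np.random.default_rng(0)
        reads = rng.integers(0, 4, size=(50_000, 20)).astype(np.uint8)
        model = fit_markov(reads, order=5, alpha=1.0)
        probs = model.word_probs(8)
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        rel_err = np.abs(probs - 4.0**-8) * 4.0**8
        assert rel_err.mean() < 0.1  # flat up to sampling noise
        assert rel_err.max() < 0.6

    def test_order1_chain_matches_hand_computed_product(self):
        reads = ["ACGTACGATT", "GGCATTACCA"]
        model = fit_markov(reads, order=1, alpha=0.5)
        probs = model.word_probs(4)
        for word in ("ACGT", "TTTT", "GCAT"):
            expected = markov_word_prob_brute(reads, 1, 0.5, word)
            assert probs[sq.kmer_to_code(word)] == pytest.approx(
                expected, rel=1e-12
            )

    def test_unseen_context_falls_back_to_uniform(self):
        model = fit_markov(["AAAAAAAA"], order=2, alpha=1.0)
        cond = model.conditional
        ctx = sq.kmer_to_code("CG")  # never observed
        assert np.allclose(cond[ctx], 0.25)

    def test_conditionals_normalize(self):
        model = fit_markov(["ACGTTGCAGT", "TTATGCGCAT"], order=3, alpha=1.0)
        assert np.allclose(model.conditional.sum(axis=1), 1.0)
        assert model.initial_dist.sum() == pytest.approx(1.0)

    def test_scoring_requires_word_longer_than_order(self):
        model = fit_markov(["ACGTACGTAC"], order=5)
        with pytest.raises(ValueError):
            model.word_probs(5)


class TestExpectedCounts:
    def test_sums_to_n_windows(self):
        model = fit_markov(["ACGGTTACCAGTTACGGATC"], order=2, alpha=1.0)
        exp = expected_counts(model, n_windows=123_456, k=6)
        assert exp.sum() == pytest.approx(123_456, rel=1e-9)

    def test_oracle_equivalence_small_alphabet_problem(self):
        # k=4, order=1 toy: every expected count matches enumeration
        reads = ["ACGTACGATTGCAGGATACA", "TTGCACGGATTTACGGTACA"]
        model = fit_markov(reads, order=1, alpha=1.0)
        exp = expected_counts(model, n_windows=10_000, k=4)
        for word in all_kmers(4):
            brute = 10_000 * markov_word_prob_brute(reads, 1, 1.0, word)
            assert exp[sq.kmer_to_code(word)] == pytest.approx(brute, rel=1e-9)


class TestEnrich:
    def _null_table(self):
        obs = count_kmers(["ACGTACGTAC" * 2] * 50, k=4)
        return obs

    def test_null_enrichment_gives_zero_z(self):
        from polyscape.enrichment import KmerTable

        obs = KmerTable(4, np.full(256, 10, dtype=np.int64), 2560)
        table = enrich(obs, np.full(256, 10.0))
        assert np.allclose(table.ratio, 1.0)
        assert np.all(table.z == 0.0)  # sd of a constant ratio is zero

    def test_global_scaling_preserves_ranking(self):
        obs = self._null_table()
        expected = np.full(256, obs.n_windows / 256)
        t1 = enrich(obs, expected)
        from polyscape.enrichment import KmerTable

        doubled = KmerTable(4, obs.counts * 2, obs.n_windows * 2)
        t2 = enrich(doubled, expected)
        assert np.allclose(t2.ratio, 2 * t1.ratio)
        assert np.array_equal(np.argsort(-t1.z, kind="stable"),
                              np.argsort(-t2.z, kind="stable"))

    def test_standardization(self, table_m1):
        assert table_m1.z.mean() == pytest.approx(0.0, abs=1e-9)
        assert table_m1.z.std() == pytest.approx(1.0, abs=1e-9)

    def test_exact_seed_words_occupy_top_ranks(self, table_m1):
        frame = table_m1.to_frame()
        top = frame.head(50)["kmer"]
        assert all(contains_motif_brute(k, "WGWWCW") for k in top)

    def test_conservation(self, table_m1):
        assert table_m1.observed.sum() == table_m1.n_windows
        assert table_m1.expected.sum() == pytest.approx(
            table_m1.n_windows, rel=1e-6
        )

    def test_mismatched_k_rejected(self):
        obs = count_kmers(["ACGTACGT"], k=4)
        with pytest.raises(ValueError):
            enrich(obs, np.ones(4**5))

    def test_tsv_roundtrip(self, tmp_path):
        obs = count_kmers(["ACGTAACCGGTTACGTACGT"] * 3, k=4)
        table = enrich(obs, np.full(256, obs.n_windows / 256),
                       meta={"condition": "toy"})
        path = tmp_path / "enrichment.tsv"
        table.write_tsv(path)
        back = EnrichmentTable.read_tsv(path)
        assert back.k == 4 and back.n_windows == table.n_windows
        assert np.allclose(back.z, table.z, atol=1e-5)


class TestClassifyByMotif:
    def test_containment_examples(self):
        table = enrich(count_kmers(["ACGTACGTACGTACGTACGT"], 8),
                       np.full(4**8, 1.0))
        df = classify_by_motif(table, ["WGWWCW", "WGGWCW"])
        assert bool(df.loc["AAGATCAT", "WGWWCW"])
        assert df.loc["GGGGGGGG", "category"] == "neither"

    def test_category_counts_match_exhaustive_oracle(self, table_m1):
        df = classify_by_motif(table_m1, ["WGWWCW", "WGGWCW"])
        # exhaustive check on a deterministic subsample of all 65,536 words
        kmers = df.index[::97]
        for kmer in kmers:
            a = contains_motif_brute(kmer, "WGWWCW")
            b = contains_motif_brute(kmer, "WGGWCW")
            want = ("both" if a and b else "A-only" if a
                    else "B-only" if b else "neither")
            assert df.loc[kmer, "category"] == want
        # full-table totals are consistent with the boolean columns
        assert (df["category"] == "both").sum() == (
            df["WGWWCW"] & df["WGGWCW"]
        ).sum()

    def test_motif_longer_than_k_rejected(self):
        table = enrich(count_kmers(["ACGTAC"], 4), np.full(256, 1.0))
        with pytest.raises(ValueError):
            classify_by_motif(table, ["WGWWCWW"])
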
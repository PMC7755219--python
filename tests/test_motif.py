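"""Top-k-mer ranking, anchored alignment, PWM and site-width calls."""
import numpy as np
import pytest

from oracles import contains_motif_brute, revcomp
from polyscape import sequences as sq
from polyscape.enrichment import EnrichmentTable
from polyscape.motif import (AlignedKmerSet, align_kmers, build_pwm,
                             consensus, informative_run, recovered_motif,
                             site_width, top_kmers)
from polyscape.workflow import motif_pipeline


def toy_table(z_by_kmer, k=8):
    size = 4**k
    z = np.zeros(size)
    for kmer, val in z_by_kmer.items():
        z[sq.kmer_to_code(kmer)] = val
    return EnrichmentTable(k=k, observed=np.zeros(size), expected=np.zeros(size),
                           ratio=np.zeros(size), z=z, n_windows=0)


class TestTopKmers:
    def test_single_argmax(self):
        table = toy_table({"ACGTACGT": 5.0, "TTTTAAAA": 3.0})
        assert top_kmers(table, 1) == ["ACGTACGT"]

    def test_full_list_is_permutation(self):
        table = toy_table({"ACGTACGT": 5.0})
        ranked = top_kmers(table, 4**8)
        assert len(ranked) == 4**8
        assert len(set(ranked)) == 4**8

    def test_ties_break_alphabetically(self):
        table = toy_table({"TTTTTTTT": 2.0, "AAAACCCC": 2.0, "GGGGCCCC": 2.0})
        assert top_kmers(table, 3) == ["AAAACCCC", "GGGGCCCC", "TTTTTTTT"]

    def test_synthetic_top10_contain_planted_seed(self, table_m1):
        for kmer in top_kmers(table_m1, 10):
            assert contains_motif_brute(kmer, "WGWWCW")


class TestAlignKmers:
    def test_identical_words_stack_at_zero_forward(self):
        aligned = align_kmers(["ACGGTCAT"] * 10)
        assert all(off == 0 and strand == "+" for _, off, strand in
                   aligned.members)

    def test_revcomp_of_anchor_aligns_onto_the_core(self):
        # anchor with a non-palindromic base-class core: orientation is
        # pinned by the S-column pattern and the rc word flips
        anchor = "AGGTCTGA"
        aligned = align_kmers([anchor, revcomp(anchor)])
        (_, off, strand) = aligned.members[1]
        assert (off, strand) == (0, "-")

    def test_matches_exhaustive_two_pass_search(self):
        kmers = ["TAGGTCAT", "AAGGTCAT", "GGTCATTA", "CTAGGTCA", "ATGACCTA"]
        aligned = align_kmers(kmers)
        brute = _align_brute(kmers)
        assert aligned.members == brute

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            align_kmers([])


def _align_brute(kmers, max_offset=2):
    """Independent reimplementation of the two-pass placement rules."""
    k = len(kmers[0])
    width = k + 2 * max_offset

    def placements():
        out = [(o, s) for o in range(-max_offset, max_offset + 1) for s in "+-"]
        return sorted(out, key=lambda p: (abs(p[0]), p[1] == "-", p[0]))

    def place_all(score):
        profile = np.zeros((width, 4))
        members = []
        for rank, kmer in enumerate(kmers):
            if rank == 0:
                best = (0, "+")
            else:
                best, best_s = None, -1.0
                for off, strand in placements():
                    word = kmer if strand == "+" else revcomp(kmer)
                    s = sum(
                        score(profile, off + max_offset + j, b)
                        for j, b in enumerate(sq.encode(word))
                    )
                    if s > best_s:
                        best, best_s = (off, strand), s
            word = kmer if best[1] == "+" else revcomp(kmer)
            for j, b in enumerate(sq.encode(word)):
                profile[best[0] + max_offset + j, b] += 1
            members.append((kmer, best[0], best[1]))
        return members, profile

    _, profile = place_all(lambda prof, c, b: prof[c, b])
    classes = np.zeros((width, 4))
    s_profile = np.zeros((width, 4))
    n = len(kmers)
    for c in range(width):
        cov = profile[c].sum()
        if cov < 0.5 * n:
            continue
        if profile[c, 0] + profile[c, 3] >= 0.75 * cov:
            classes[c, [0, 3]] = 1
        elif profile[c, 1] + profile[c, 2] >= 0.75 * cov:
            classes[c, [1, 2]] = 1
            s_profile[c, 1] = profile[c, 1]
            s_profile[c, 2] = profile[c, 2]
    # evidence gate: need a contiguous classified core of >= 4 columns
    classified = classes.sum(axis=1) > 0
    run = best = 0
    for c in classified:
        run = run + 1 if c else 0
        best = max(best, run)
    if best < 4:
        return [(kmer, 0, "+") for kmer in kmers]
    big = 4.0 * (n + 1) * len(kmers[0])
    final = classes * big + s_profile
    members, _ = place_all(lambda prof, c, b: final[c, b])
    return members


class TestBuildPwm:
    def test_identical_words_give_near_two_bits(self):
        aligned = align_kmers(["ACGGTCAT"] * 50)
        pwm = build_pwm(aligned, pseudocount=0.25)
        assert pwm.width == 8
        assert (pwm.ic >= 1.9).all()

    def test_random_words_carry_no_information(self):
        rng = np.random.default_rng(11)
        words = ["".join("ACGT"[c] for c in rng.integers(0, 4, 8))
                 for _ in range(200)]
        pwm = build_pwm(align_kmers(words))
        assert (pwm.ic < 0.3).all()

    def test_columns_are_probability_distributions(self, table_m1):
        _, _, pwm = motif_pipeline(table_m1)
        assert np.allclose(pwm.probs.sum(axis=1), 1.0)
        assert ((pwm.ic >= 0) & (pwm.ic <= 2)).all()

    def test_meme_block_shape(self):
        pwm = build_pwm(align_kmers(["ACGGTCAT"] * 5))
        text = pwm.to_meme("toy")
        assert "MOTIF toy" in text
        assert f"w= {pwm.width}" in text


class TestSiteWidth:
    def test_all_columns_informative(self):
        pwm = build_pwm(align_kmers(["ACGGTCAT"] * 50))
        assert site_width(pwm, tau=0.3) == pwm.width

    def test_longest_run_on_alternating_fixture(self):
        from polyscape.motif import PWM

        ic = np.array([0.0, 0.5, 0.5, 0.1, 0.5, 0.5, 0.5, 0.0])
        pwm = PWM(probs=np.full((8, 4), 0.25), ic=ic, pseudocount=0.25,
                  n_members=1, start=0)
        assert site_width(pwm, tau=0.3) == 3
        assert informative_run(pwm, tau=0.3) == (4, 7)

    def test_no_column_reaches_threshold(self):
        from polyscape.motif import PWM

        pwm = PWM(probs=np.full((4, 4), 0.25), ic=np.zeros(4),
                  pseudocount=0.25, n_members=1, start=0)
        assert site_width(pwm) == 0


class TestConsensus:
    def test_uniform_column_is_n(self):
        from polyscape.motif import PWM

        pwm = PWM(probs=np.array([[0.25] * 4]), ic=np.zeros(1),
                  pseudocount=0.25, n_members=1, start=0)
        assert consensus(pwm) == "N"

    def test_strong_single_base_and_two_base_pools(self):
        from polyscape.motif import PWM

        probs = np.array([
            [0.9, 0.03, 0.03, 0.04],   # A
            [0.45, 0.05, 0.05, 0.45],  # W
            [0.05, 0.45, 0.45, 0.05],  # S
        ])
        pwm = PWM(probs=probs, ic=np.ones(3), pseudocount=0.25,
                  n_members=1, start=0)
        assert consensus(pwm) == "AWS"


class TestPlantedMotifRecovery:
    def test_wgwwcw_model(self, table_m1):
        _, _, pwm = motif_pipeline(table_m1)
        assert site_width(pwm) == 6
        assert recovered_motif(pwm) == "WGWWCW"

    def test_wggwcw_model(self, table_m2):
        # a flank column can graze the information threshold, widening
        # the raw run by one; the recovered motif is the 6-bp core
        _, _, pwm = motif_pipeline(table_m2)
        assert site_width(pwm) in (6, 7)
        assert recovered_motif(pwm) == "WGGWCW"

    def test_ic_invariant_under_global_strand_flip(self, table_m1):
        ranked = top_kmers(table_m1, 50)
        pwm_f = build_pwm(align_kmers(ranked))
        pwm_r = build_pwm(align_kmers([revcomp(k) for k in ranked]))
        assert np.allclose(np.sort(pwm_f.ic), np.sort(pwm_r.ic), atol=1e-9)
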
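"""Brute-force reference implementations used as independent oracles.

Every function here recomputes a quantity by direct enumeration with no
shared code path with the package internals (plain Python strings and
dictionaries), so agreement is a meaningful check.
"""
import itertools
from collections import Counter

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "N": "ACGT",
}


def revcomp(s):
    return "".join(COMP[c] for c in reversed(s))


def all_kmers(k):
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def count_kmers_brute(reads, k):
    """Sliding-window counts over each read and its reverse complement."""
    counts = Counter()
    for read in reads:
        for seq in (read, revcomp(read)):
            for i in range(len(seq) - k + 1):
                w = seq[i : i + k]
                if set(w) <= set("ACGT"):
                    counts[w] += 1
    return counts


def markov_word_prob_brute(background_reads, order, alpha, word):
    """Chain probability of a word under the order-m background model.

    Context counts are the marginal of the (m+1)-mer counts, matching
    the package's normalization convention.
    """
    m = order
    cm1 = count_kmers_brute(background_reads, m + 1)
    cm = count_kmers_brute(background_reads, m)
    total_m = sum(cm.values())
    p = (cm[word[:m]] + alpha) / (total_m + (4**m) * alpha)
    for j in range(m, len(word)):
        ctx = word[j - m : j]
        num = cm1[ctx + word[j]] + alpha
        den = sum(cm1[ctx + b] for b in "ACGT") + 4 * alpha
        p *= num / den
    return p


def pattern_mismatches(site, pattern):
    return sum(
        1 for a, p in zip(site, pattern) if a not in IUPAC[p]
    )


def site_distance_brute(site, pattern):
    """Strand-minimal mismatch count of a concrete site vs an IUPAC pattern."""
    return min(
        pattern_mismatches(site, pattern),
        pattern_mismatches(revcomp(site), pattern),
    )


def motif_distance_brute(kmer, seed):
    """(d, offset, strand, mism_pos) with forward-strand-then-smallest-offset
    tie breaking, by full enumeration."""
    best = None
    for strand in "+-":
        word = kmer if strand == "+" else revcomp(kmer)
        for off in range(len(kmer) - len(seed) + 1):
            mism = tuple(
                j + 1
                for j in range(len(seed))
                if word[off + j] not in IUPAC[seed[j]]
            )
            cand = (len(mism), off, strand, mism)
            if best is None or cand[0] < best[0]:
                best = cand
    return best


def contains_motif_brute(kmer, motif):
    return motif_distance_brute(kmer, motif)[0] == 0


def occupancy_brute(read, seed, theta, a0):
    total = 0.0
    for i in range(len(read) - 6 + 1):
        w = read[i : i + 6]
        if set(w) <= set("ACGT"):
            total += a0 * theta ** site_distance_brute(w, seed)
    return total


def sos_brute(values, length, k, window, step, mode="sum"):
    """Window scores by direct summation of fully contained k-mer values.

    ``values`` maps k-mer start -> value (missing starts skipped).
    """
    out = []
    start = 0
    while start + window <= length:
        contained = [
            values[i]
            for i in range(start, start + window - k + 1)
            if i in values
        ]
        score = sum(contained)
        if mode == "mean":
            score = score / len(contained) if contained else float("nan")
        out.append((start, score, len(contained)))
        start += step
    return out


def density_incidence_brute(tag_midpoints, peak_centres, span):
    """Number of (midpoint, peak-window) incidences by double loop."""
    n = 0
    for mid in tag_midpoints:
        for c in peak_centres:
            if c - span // 2 <= mid < c + span // 2:
                n += 1
    return n
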
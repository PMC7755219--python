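"""PWMs and apparent binding-site width from top-enriched k-mers.

The most-enriched 8-mers are multiply aligned by a greedy anchored
procedure (a deliberately simple, fully deterministic stand-in for an
EM-style motif finder): the rank-1 word anchors the profile, and every
subsequent word is placed at the offset (within +/-2) and strand that
maximize positional agreement with the running profile.  Column
probabilities with a pseudocount give the PWM; per-column information
content in bits,

    ic(col) = 2 + sum_b p_b log2 p_b,

defines the informative core, and the apparent binding-site width is the
longest run of columns at or above an information threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import sequences as sq
from .enrichment import EnrichmentTable

DEFAULT_TOP = 50
DEFAULT_MAX_OFFSET = 2
DEFAULT_PSEUDOCOUNT = 0.25
DEFAULT_TAU = 0.3


def top_kmers(table: EnrichmentTable, n: int = DEFAULT_TOP) -> list:
    """Top-n k-mers by z, ties broken alphabetically; deterministic."""
    kmers = np.array(sq.all_kmers(table.k))
    order = np.lexsort((kmers, -table.z))
    return list(kmers[order[:n]])


@dataclass
class AlignedKmerSet:
    """Greedy multiple ungapped alignment of ranked k-mers.

    ``members`` is a list of ``(kmer, offset, strand)`` in rank order;
    the anchor (rank 1) sits at offset 0 on the forward strand.  For a
    reverse-strand member the reverse complement of the word occupies
    columns ``offset .. offset+k-1``.
    """

    members: list
    k: int
    max_offset: int = DEFAULT_MAX_OFFSET

    @property
    def anchor(self) -> str:
        return self.members[0][0]


#: minimum fraction of members covering a column for it to be classified
CLASS_COVERAGE = 0.5
#: minimum within-class base fraction for a column to be classified
CLASS_PURITY = 0.75
#: minimum contiguous classified columns for class-guided realignment
MIN_CORE_COLS = 4


def _placements(max_offset: int):
    """Candidate (offset, strand) pairs in tie-preference order."""
    return sorted(
        ((o, s) for o in range(-max_offset, max_offset + 1) for s in "+-"),
        key=lambda p: (abs(p[0]), 0 if p[1] == "+" else 1, p[0]),
    )


def _greedy_pass(kmers, k, max_offset, score_matrix, pin_anchor=True,
                 accumulate=True):
    """One placement pass; scores each word against ``score_matrix``
    (width x 4), optionally accumulating placed words into it."""
    width = k + 2 * max_offset
    cols0 = np.arange(k)
    members = []
    for rank, kmer in enumerate(kmers):
        if len(kmer) != k:
            raise ValueError("k-mers must have equal length")
        if rank == 0 and pin_anchor:
            best = (0, "+")
        else:
            best_score = -1.0
            best = (0, "+")
            for off, strand in _placements(max_offset):
                word = kmer if strand == "+" else sq.revcomp(kmer)
                c = sq.encode(word)
                score = float(score_matrix[cols0 + off + max_offset, c].sum())
                if score > best_score:
                    best_score = score
                    best = (off, strand)
        if accumulate:
            codes = sq.encode(kmer if best[1] == "+" else sq.revcomp(kmer))
            score_matrix[cols0 + best[0] + max_offset, codes] += 1
        members.append((kmer, best[0], best[1]))
    return members


def _class_matrix(profile: np.ndarray, n_members: int) -> np.ndarray:
    """Strand-invariant column classes of a provisional profile.

    A column covered by >= 50 % of members whose base mass is >= 75 %
    within one complementary pair -- W (A/T) or S (C/G) -- scores 1 for
    either base of that pair and 0 otherwise; unclassified columns score
    0 for everything, so flank noise cannot steer placement.
    """
    width = profile.shape[0]
    out = np.zeros((width, 4))
    coverage = profile.sum(axis=1)
    for c in range(width):
        if coverage[c] < CLASS_COVERAGE * n_members:
            continue
        w_mass = profile[c, 0] + profile[c, 3]
        s_mass = profile[c, 1] + profile[c, 2]
        if w_mass >= CLASS_PURITY * coverage[c]:
            out[c, [0, 3]] = 1.0
        elif s_mass >= CLASS_PURITY * coverage[c]:
            out[c, [1, 2]] = 1.0
    return out


def align_kmers(kmers, max_offset: int = DEFAULT_MAX_OFFSET) -> AlignedKmerSet:
    """Greedy anchored multiple ungapped alignment, class-refined.

    Pass 1 places each ranked word at the (offset, strand) maximizing
    positional agreement with the running profile of already-placed
    words (anchor pinned at offset 0, forward).  Pass 2 re-places every
    word against the strand-invariant base-class pattern (W = A/T,
    S = C/G) of the provisional profile: this keeps orientation choices
    from being decided by flank noise or by the A-vs-T identity of
    degenerate positions -- for a reverse-complement-palindromic core
    the two orientations of a word tie exactly and the tie rules decide.

    Ties are broken by smaller |offset|, then forward strand, then
    smaller offset; the whole procedure is deterministic.
    """
    kmers = list(kmers)
    if not kmers:
        raise ValueError("empty k-mer list")
    k = len(kmers[0])
    width = k + 2 * max_offset
    profile = np.zeros((width, 4))
    _greedy_pass(kmers, k, max_offset, profile, pin_anchor=True, accumulate=True)
    classes = _class_matrix(profile, len(kmers))

    # evidence gate: greedy agreement-seeking invents coherence even in
    # pure-noise input, so class refinement only applies when the
    # classified columns contain a contiguous core of >= MIN_CORE_COLS;
    # otherwise the words are left unaligned (stacked at offset 0,
    # forward), which is the correct null alignment.
    classified = classes.sum(axis=1) > 0
    run = best = 0
    for c in classified:
        run = run + 1 if c else 0
        best = max(best, run)
    if best < MIN_CORE_COLS:
        members = [(kmer, 0, "+") for kmer in kmers]
        return AlignedKmerSet(members=members, k=k, max_offset=max_offset)

    # secondary score: profile agreement on S-classified columns only.
    # G-vs-C identity there pins down offset (and, for non-palindromic
    # cores, strand) without touching the A-vs-T balance of W columns.
    s_mask = np.zeros_like(profile)
    s_cols = classes[:, 1] > 0  # columns classified S
    s_mask[s_cols, 1] = profile[s_cols, 1]
    s_mask[s_cols, 2] = profile[s_cols, 2]
    big = 4.0 * (len(kmers) + 1) * k
    members = _greedy_pass(
        kmers, k, max_offset, classes * big + s_mask,
        pin_anchor=True, accumulate=False,
    )
    return AlignedKmerSet(members=members, k=k, max_offset=max_offset)


@dataclass
class PWM:
    """Position weight matrix with per-column information content.

    ``probs`` has one row per kept column (each summing to 1); ``ic`` is
    in bits, in [0, 2].  ``start`` records the first kept column's offset
    relative to the alignment anchor.
    """

    probs: np.ndarray
    ic: np.ndarray
    pseudocount: float
    n_members: int
    start: int

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    def to_meme(self, name: str = "motif_1") -> str:
        lines = [
            "MEME version 4", "", "ALPHABET= ACGT", "",
            "strands: + -", "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {name}",
            f"letter-probability matrix: alength= 4 w= {self.width} "
            f"nsites= {self.n_members} E= 0",
        ]
        for row in self.probs:
            lines.append(" ".join(f"{p:.6f}" for p in row))
        return "\n".join(lines) + "\n"


def build_pwm(
    aligned: AlignedKmerSet, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> PWM:
    """Column probabilities from an aligned set; sparsely covered end
    columns (< 25 % of members) are trimmed."""
    if not aligned.members:
        raise ValueError("empty aligned set")
    k, mo = aligned.k, aligned.max_offset
    width = k + 2 * mo
    counts = np.zeros((width, 4))
    for kmer, off, strand in aligned.members:
        word = kmer if strand == "+" else sq.revcomp(kmer)
        cols = np.arange(k) + off + mo
        counts[cols, sq.encode(word)] += 1
    coverage = counts.sum(axis=1)
    n = len(aligned.members)
    keep = coverage >= 0.25 * n
    first = int(np.argmax(keep))
    last = width - int(np.argmax(keep[::-1]))
    counts = counts[first:last]
    coverage = coverage[first:last]
    probs = (counts + pseudocount) / (coverage[:, None] + 4 * pseudocount)
    # information content from the raw column frequencies (the
    # pseudocount only regularizes the emitted probability matrix), with
    # the Schneider-Stephens small-sample bias correction: a column
    # covered by n random sequences carries ~3/(2 ln2 n) spurious bits
    raw = counts / np.maximum(coverage[:, None], 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(raw > 0, raw * np.log2(raw), 0.0)
    ic = 2.0 + plogp.sum(axis=1)
    ic = ic - 3.0 / (2.0 * np.log(2) * np.maximum(coverage, 1.0))
    return PWM(
        probs=probs,
        ic=np.clip(ic, 0.0, 2.0),
        pseudocount=pseudocount,
        n_members=n,
        start=first - mo,
    )


def _runs_at_or_above(ic: np.ndarray, tau: float):
    """(start, length) of every maximal run with ic >= tau."""
    runs = []
    start = None
    for i, v in enumerate(ic):
        if v >= tau and start is None:
            start = i
        elif v < tau and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(ic) - start))
    return runs


def site_width(pwm: PWM, tau: float = DEFAULT_TAU) -> int:
    """Apparent binding-site width: length of the longest run of
    consecutive columns with information content >= tau bits (0 if none)."""
    runs = _runs_at_or_above(pwm.ic, tau)
    return max((length for _, length in runs), default=0)


def informative_run(pwm: PWM, tau: float = DEFAULT_TAU):
    """(start, end) column range of the longest informative run
    (leftmost on ties); (0, 0) if no column reaches tau."""
    runs = _runs_at_or_above(pwm.ic, tau)
    if not runs:
        return (0, 0)
    start, length = max(runs, key=lambda r: (r[1], -r[0]))
    return (start, start + length)


_TWO_BASE_POOLS = [
    ("W", (0, 3)), ("S", (1, 2)), ("R", (0, 2)),
    ("Y", (1, 3)), ("K", (2, 3)), ("M", (0, 1)),
]


def consensus(pwm: PWM, strong: float = 0.65, w_pool: float = 0.8) -> str:
    """IUPAC consensus: a single base if its probability >= ``strong``,
    else a two-base degenerate code whose pooled probability >= ``w_pool``,
    else N."""
    out = []
    for row in pwm.probs:
        best = int(np.argmax(row))
        if row[best] >= strong:
            out.append(sq.BASES[best])
            continue
        for code, (i, j) in _TWO_BASE_POOLS:
            if row[i] + row[j] >= w_pool:
                out.append(code)
                break
        else:
            out.append("N")
    return "".join(out)


def recovered_motif(
    pwm: PWM,
    tau: float = DEFAULT_TAU,
    strong: float = 0.65,
    w_pool: float = 0.8,
) -> str:
    """Consensus of the informative run, canonicalized in orientation.

    Columns whose consensus is N carry no motif content, so N edges of
    the run (flanks that barely graze the information threshold) are
    trimmed.  Enrichment tables are strand-symmetric, so a recovered
    PWM's orientation is arbitrary; the lexicographically smaller of the
    consensus and its IUPAC reverse complement is returned.
    """
    lo, hi = informative_run(pwm, tau)
    sub = PWM(
        probs=pwm.probs[lo:hi], ic=pwm.ic[lo:hi],
        pseudocount=pwm.pseudocount, n_members=pwm.n_members,
        start=pwm.start + lo,
    )
    s = consensus(sub, strong=strong, w_pool=w_pool).strip("N")
    return min(s, sq.revcomp(s))
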
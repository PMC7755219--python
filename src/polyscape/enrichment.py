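"""Per-k-mer enrichment scores from SELEX read pools.

The analysis counts every k-mer (k = 8 by default) in the enriched pool
with a sliding window over both strands, predicts the expected count of
each word under a fifth-order Markov background fitted on the mock
("processed library") pool, and standardizes the observed/expected ratio
across all 4**k words:

    r(x) = observed(x) / max(expected(x), epsilon)
    z(x) = (r(x) - mean(r)) / sd(r)          (population sd)

z is the "binding intensity" consumed by the landscape and genome-scoring
stages.  Scanning both strands makes the table exactly
strand-symmetric: counts(x) == counts(revcomp(x)) by construction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sequences as sq

DEFAULT_K = 8
DEFAULT_ORDER = 5
DEFAULT_ALPHA = 1.0
DEFAULT_EPSILON = 0.5


# ---------------------------------------------------------------------------
# k-mer counting


@dataclass
class KmerTable:
    """Strand-aggregated k-mer counts.

    ``counts[x]`` includes windows of each read and of its reverse
    complement, so ``counts[x] == counts[revcomp(x)]`` always and
    ``counts.sum() == n_windows``.
    """

    k: int
    counts: np.ndarray
    n_windows: int

    def count_of(self, kmer: str) -> int:
        return int(self.counts[sq.kmer_to_code(kmer)])


def count_kmers(reads, k: int = DEFAULT_K) -> KmerTable:
    """Count every length-k window of every read and its reverse complement.

    ``reads`` may be a list of strings (possibly ragged, possibly with
    non-ACGT characters -- those windows are skipped) or a 2-D uint8 code
    array of clean equal-length reads.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    size = 4**k
    rc = sq.revcomp_table(k)
    fwd = np.zeros(size, dtype=np.int64)
    if isinstance(reads, np.ndarray) and reads.ndim == 2:
        if reads.shape[1] >= k:
            w = sq.window_codes_2d(reads, k)
            fwd = np.bincount(w.ravel(), minlength=size)
    else:
        for read in reads:
            codes = sq.encode(read) if isinstance(read, str) else np.asarray(read)
            w, valid = sq.window_codes(codes, k)
            if len(w):
                fwd += np.bincount(w[valid], minlength=size)
    counts = fwd + fwd[rc]
    return KmerTable(k=k, counts=counts, n_windows=int(counts.sum()))


# ---------------------------------------------------------------------------
# Markov background


@dataclass
class MarkovBackground:
    """Order-m Markov model of the background (mock) library.

    Fitted on both strands with the same sliding-window convention as
    :func:`count_kmers`.  Conditional probabilities use context counts
    obtained by marginalizing the (m+1)-mer counts so that
    ``sum_b P(b | c) == 1`` holds exactly for every context::

        P(b | c) = (N_{m+1}(c.b) + alpha) / (sum_b' N_{m+1}(c.b') + 4 alpha)

    The initial m-mer distribution is the smoothed m-mer window frequency.
    """

    order: int
    alpha: float
    extension_counts: np.ndarray  # length 4**(m+1)
    initial_counts: np.ndarray  # length 4**m, raw m-mer window counts
    context_counts: np.ndarray = field(init=False)  # marginal of extensions

    def __post_init__(self):
        m = self.order
        self.context_counts = self.extension_counts.reshape(4**m, 4).sum(axis=1)

    @property
    def conditional(self) -> np.ndarray:
        """(4**m, 4) array of P(next base | context)."""
        ext = self.extension_counts.reshape(4**self.order, 4).astype(float)
        return (ext + self.alpha) / (
            self.context_counts[:, None] + 4 * self.alpha
        )

    @property
    def initial_dist(self) -> np.ndarray:
        m = self.order
        tot = self.initial_counts.sum()
        return (self.initial_counts + self.alpha) / (tot + 4**m * self.alpha)

    def word_probs(self, k: int) -> np.ndarray:
        """P(word) for every k-mer, k > order, as a chain product."""
        m = self.order
        if k <= m:
            raise ValueError("word length must exceed the model order")
        codes = np.arange(4**k, dtype=np.int64)
        cond = self.conditional
        p = self.initial_dist[codes >> (2 * (k - m))].astype(float)
        mask = 4**m - 1
        for j in range(m, k):
            ctx = (codes >> (2 * (k - j))) & mask
            nxt = (codes >> (2 * (k - 1 - j))) & 3
            p *= cond[ctx, nxt]
        return p


def fit_markov(
    background_reads,
    order: int = DEFAULT_ORDER,
    alpha: float = DEFAULT_ALPHA,
) -> MarkovBackground:
    """Fit an order-m background model on the mock library (both strands)."""
    if order < 0:
        raise ValueError("order must be >= 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    ext = count_kmers(background_reads, order + 1).counts
    init = count_kmers(background_reads, order).counts if order > 0 else np.array(
        [1.0]
    )
    return MarkovBackground(
        order=order, alpha=alpha, extension_counts=ext, initial_counts=init
    )


def expected_counts(
    model: MarkovBackground, n_windows: int, k: int = DEFAULT_K
) -> np.ndarray:
    """Model-predicted count of every k-mer at the enriched sample's depth.

    Sums to ``n_windows`` to machine precision because the chain
    probabilities sum to one over all words.
    """
    return n_windows * model.word_probs(k)


# ---------------------------------------------------------------------------
# enrichment table


@dataclass
class EnrichmentTable:
    """Observed vs expected counts, ratio and standardized intensity per k-mer."""

    k: int
    observed: np.ndarray
    expected: np.ndarray
    ratio: np.ndarray
    z: np.ndarray
    n_windows: int
    meta: dict = field(default_factory=dict)

    def z_of(self, kmer: str) -> float:
        return float(self.z[sq.kmer_to_code(kmer)])

    def to_frame(self) -> pd.DataFrame:
        """Full table sorted by z descending, ties alphabetical."""
        kmers = np.array(sq.all_kmers(self.k))
        order = np.lexsort((kmers, -self.z))
        return pd.DataFrame(
            dict(
                kmer=kmers[order],
                observed=self.observed[order],
                expected=self.expected[order],
                ratio=self.ratio[order],
                z=self.z[order],
            )
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.meta.items()):
                fh.write(f"# {key}: {val}\n")
            fh.write(f"# k: {self.k}\n# n_windows: {self.n_windows}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def read_tsv(cls, path) -> "EnrichmentTable":
        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition(": ")
                meta[key] = val
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t")
        k = int(meta.pop("k"))
        n_windows = int(meta.pop("n_windows"))
        size = 4**k
        obs = np.zeros(size)
        exp = np.zeros(size)
        ratio = np.zeros(size)
        z = np.zeros(size)
        codes = np.array([sq.kmer_to_code(s) for s in df["kmer"]])
        obs[codes] = df["observed"]
        exp[codes] = df["expected"]
        ratio[codes] = df["ratio"]
        z[codes] = df["z"]
        return cls(k=k, observed=obs, expected=exp, ratio=ratio, z=z,
                   n_windows=n_windows, meta=meta)


def enrich(
    observed: KmerTable,
    expected: np.ndarray,
    epsilon: float = DEFAULT_EPSILON,
    log2: bool = False,
    meta: dict | None = None,
) -> EnrichmentTable:
    """Standardize observed/expected ratios into per-word intensities.

    With ``log2=True`` the standardized quantity is
    ``log2((observed + epsilon) / max(expected, epsilon))`` instead of the
    raw ratio (off by default).
    """
    expected = np.asarray(expected, dtype=float)
    if len(expected) != len(observed.counts):
        raise ValueError("observed and expected tables have different k")
    floor = np.maximum(expected, epsilon)
    ratio = observed.counts / floor
    scores = np.log2((observed.counts + epsilon) / floor) if log2 else ratio
    sd = scores.std()  # population sd
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    return EnrichmentTable(
        k=observed.k,
        observed=observed.counts.astype(float),
        expected=expected,
        ratio=ratio,
        z=z,
        n_windows=observed.n_windows,
        meta=dict(meta or {}, standardization="per-round", log2=log2),
    )


def classify_by_motif(table: EnrichmentTable, motifs) -> pd.DataFrame:
    """Label every k-mer by which IUPAC 6-mer motifs it contains.

    Containment means an exact IUPAC match at any offset on either
    strand.  With exactly two motifs a ``category`` column is added with
    levels A-only / B-only / both / neither, suitable for coloring a
    z_A vs z_B scatter.
    """
    k = table.k
    contains = {}
    for motif in motifs:
        L = len(motif)
        if L > k:
            raise ValueError(f"motif {motif!r} longer than k={k}")
        hexmatch = sq.min_mismatch_table(motif) == 0
        codes = np.arange(4**k, dtype=np.int64)
        hit = np.zeros(4**k, dtype=bool)
        for off in range(k - L + 1):
            sub = (codes >> (2 * (k - L - off))) & (4**L - 1)
            hit |= hexmatch[sub]
        contains[motif] = hit
    df = pd.DataFrame(contains, index=pd.Index(sq.all_kmers(k), name="kmer"))
    if len(motifs) == 2:
        a, b = list(motifs)
        cat = np.where(
            df[a] & df[b], "both",
            np.where(df[a], "A-only", np.where(df[b], "B-only", "neither")),
        )
        df["category"] = cat
    return df
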
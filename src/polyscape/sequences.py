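"""Low-level DNA encoding and degenerate-motif utilities.

DNA is handled internally as ``uint8`` code arrays (A=0, C=1, G=2, T=3;
the sentinel 4 marks any non-ACGT character).  k-mers are packed into
integers base 4, most-significant digit first, so the lexicographic order
of k-mer strings equals the numeric order of their codes -- a property
the ranking tie-breaks elsewhere in the package rely on.
"""
from __future__ import annotations

import functools
import itertools

import numpy as np

BASES = "ACGT"
INVALID = 4

_ENC = np.full(256, INVALID, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

#: IUPAC degenerate base -> concrete bases
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "W": "AT", "S": "CG", "R": "AG", "Y": "CT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPL = str.maketrans("ACGTWSRYKMBDHVNacgtwsrykmbdhvn",
                       "TGCAWSYRMKVHDBNtgcawsyrmkvhdbn")


def revcomp(seq: str) -> str:
    """Reverse complement; understands IUPAC degenerate codes."""
    return seq.translate(_COMPL)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a string to uint8 codes (non-ACGT -> 4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _DECODE[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def encode_reads(reads) -> np.ndarray:
    """Encode an iterable of equal-length reads into a 2-D code array."""
    if isinstance(reads, np.ndarray):
        return reads
    reads = list(reads)
    if not reads:
        return np.zeros((0, 0), dtype=np.uint8)
    lens = {len(r) for r in reads}
    if len(lens) != 1:
        raise ValueError("reads must be of equal length for array encoding")
    joined = "".join(reads)
    return _ENC[np.frombuffer(joined.encode("ascii"), dtype=np.uint8)].reshape(
        len(reads), lens.pop()
    )


def kmer_to_code(kmer: str) -> int:
    codes = encode(kmer)
    if (codes >= 4).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    code = 0
    for c in codes:
        code = (code << 2) | int(c)
    return code


def code_to_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


@functools.lru_cache(maxsize=None)
def all_kmers(k: int) -> tuple:
    """All 4**k k-mer strings in lexicographic (= code) order."""
    return tuple("".join(p) for p in itertools.product(BASES, repeat=k))


def window_codes(codes: np.ndarray, k: int):
    """Packed codes of every length-k window of a 1-D code array.

    Returns ``(wcodes, valid)`` where invalid windows (containing a
    non-ACGT sentinel) carry arbitrary packed values and ``valid`` is
    False for them.
    """
    codes = np.asarray(codes)
    n = len(codes)
    if n < k:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    c = codes.astype(np.int64)
    bad = codes >= 4
    m = n - k + 1
    w = np.zeros(m, dtype=np.int64)
    nbad = np.zeros(m, dtype=np.int64)
    for j in range(k):
        w = (w << 2) | (c[j : m + j] & 3)
        nbad += bad[j : m + j]
    return w, nbad == 0


def window_codes_2d(reads: np.ndarray, k: int) -> np.ndarray:
    """Packed window codes along axis 1 of a 2-D code array (no sentinels)."""
    n, L = reads.shape
    if L < k:
        return np.zeros((n, 0), dtype=np.int64)
    m = L - k + 1
    w = np.zeros((n, m), dtype=np.int64)
    c = reads.astype(np.int64)
    for j in range(k):
        w = (w << 2) | c[:, j : m + j]
    return w


@functools.lru_cache(maxsize=None)
def revcomp_table(k: int) -> np.ndarray:
    """Map packed k-mer code -> code of its reverse complement."""
    codes = np.arange(4**k, dtype=np.int64)
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = (rc << 2) | (3 - (tmp & 3))
        tmp >>= 2
    return rc


def pattern_sets(pattern: str):
    """Per-position allowed code sets of an IUPAC pattern."""
    try:
        return [frozenset(kmer_to_code(b) for b in IUPAC[p.upper()])
                for p in pattern]
    except KeyError as exc:  # pragma: no cover - defensive
        raise ValueError(f"unknown IUPAC code in pattern {pattern!r}") from exc


@functools.lru_cache(maxsize=None)
def mismatch_table(pattern: str) -> np.ndarray:
    """Forward-strand mismatch counts of every |pattern|-mer vs an IUPAC pattern.

    Entry x = number of positions of word x whose base falls outside the
    pattern's allowed set at that position.
    """
    L = len(pattern)
    codes = np.arange(4**L, dtype=np.int64)
    mm = np.zeros(4**L, dtype=np.uint8)
    for j, allowed in enumerate(pattern_sets(pattern)):
        digit = (codes >> (2 * (L - 1 - j))) & 3
        ok = np.zeros(4, dtype=bool)
        for a in allowed:
            ok[a] = True
        mm += ~ok[digit]
    return mm


@functools.lru_cache(maxsize=None)
def min_mismatch_table(pattern: str) -> np.ndarray:
    """Strand-minimal mismatch counts: min over a word and its reverse complement."""
    mm = mismatch_table(pattern)
    rc = revcomp_table(len(pattern))
    return np.minimum(mm, mm[rc])


@functools.lru_cache(maxsize=None)
def match_table(pattern: str) -> np.ndarray:
    """Forward-strand exact IUPAC match indicator over all |pattern|-mers."""
    return mismatch_table(pattern) == 0


def contains_motif(kmer: str, motif: str) -> bool:
    """True if the IUPAC motif occurs in the k-mer at any offset on either strand."""
    k, L = len(kmer), len(motif)
    if L > k:
        raise ValueError("motif longer than k-mer")
    mm = min_mismatch_table(motif)
    codes, valid = window_codes(encode(kmer), L)
    if not valid.all():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    return bool((mm[codes] == 0).any())
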
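"""Specificity-and-Energy Landscapes (SELs).

A SEL organizes all 4**8 8-mers into concentric rings around a
degenerate 6-bp seed motif: ring d holds every word whose minimal
mismatch distance to the seed -- over the three possible 6-bp alignments
within the 8-mer and both strands -- is d.  Within a ring, words are
arranged clockwise by the positions of their mismatches (lexicographic
on the sorted 1-based position tuple, so the ring begins with mismatches
at the first seed position) and then alphabetically.  Each entry carries
the word's standardized enrichment z as its height, giving the polar
"landscape" display.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import sequences as sq
from .affinity import SEED_LENGTH
from .enrichment import EnrichmentTable

_SEED_ALPHABET = set("ACGTW")


def validate_seed(seed: str) -> str:
    seed = seed.upper()
    if len(seed) != SEED_LENGTH:
        raise ValueError("seed motif must have length 6")
    if not set(seed) <= _SEED_ALPHABET:
        raise ValueError("seed alphabet is restricted to {A,C,G,T,W}")
    return seed


class MotifDistance(NamedTuple):
    d: int
    offset: int
    strand: str
    mism_pos: tuple  # sorted 1-based seed positions


def motif_distance(kmer: str, seed: str) -> MotifDistance:
    """Minimal mismatch distance of a k-mer to a 6-bp IUPAC seed.

    The minimum runs over all alignments of the seed within the k-mer
    (offsets 0..k-6) and both strands; among equal-distance alignments
    the forward strand wins, then the smallest offset.  ``mism_pos``
    reports the mismatching seed positions of the chosen alignment.
    """
    seed = validate_seed(seed)
    codes = sq.encode(kmer)
    if (codes >= 4).any():
        raise ValueError(f"non-ACGT base in k-mer {kmer!r}")
    if len(kmer) < SEED_LENGTH:
        raise ValueError("k-mer shorter than the seed")
    sets = sq.pattern_sets(seed)
    best = None
    for strand in "+-":
        word = codes if strand == "+" else sq.encode(sq.revcomp(kmer))
        for off in range(len(kmer) - SEED_LENGTH + 1):
            mism = tuple(
                j + 1
                for j in range(SEED_LENGTH)
                if int(word[off + j]) not in sets[j]
            )
            cand = MotifDistance(len(mism), off, strand, mism)
            if best is None or cand.d < best.d:
                best = cand
    return best


@dataclass
class SEL:
    """Concentric-ring organization of all 8-mers around a seed motif.

    ``entries`` holds one row per 8-mer with columns kmer, d, offset,
    strand, mism_pos (comma-joined 1-based positions), ring_index, angle
    (radians, 2*pi*i/ring_size) and z; rows are ordered by (d,
    ring_index), i.e. by ring then clockwise position.
    """

    seed: str
    entries: pd.DataFrame

    def ring(self, d: int) -> pd.DataFrame:
        return self.entries[self.entries["d"] == d].reset_index(drop=True)

    @property
    def ring_sizes(self) -> pd.Series:
        return self.entries["d"].value_counts().sort_index()

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed: {self.seed}\n")
            self.entries.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def _alignment_masks(k: int, seed: str):
    """Mismatch bitmasks of every k-mer for each (strand, offset) alignment,
    in tie-preference order: forward offsets ascending, then reverse."""
    sets = sq.pattern_sets(seed)
    codes = np.arange(4**k, dtype=np.int64)
    rc = sq.revcomp_table(k)
    out = []
    for strand in "+-":
        base_codes = codes if strand == "+" else rc[codes]
        for off in range(k - SEED_LENGTH + 1):
            mask = np.zeros(4**k, dtype=np.int64)
            for j, allowed in enumerate(sets):
                digit = (base_codes >> (2 * (k - 1 - off - j))) & 3
                ok = np.zeros(4, dtype=bool)
                for a in allowed:
                    ok[a] = True
                mask |= (~ok[digit]).astype(np.int64) << j
            out.append((strand, off, mask))
    return out


def build_sel(table: EnrichmentTable, seed: str) -> SEL:
    """Assign every 8-mer of an enrichment table to its mismatch ring."""
    seed = validate_seed(seed)
    k = table.k
    aligns = _alignment_masks(k, seed)
    popcount = np.array([bin(m).count("1") for m in range(2**SEED_LENGTH)])
    dmat = np.stack([popcount[mask] for _, _, mask in aligns])
    choice = np.argmin(dmat, axis=0)  # first minimum = tie-preference order
    n = 4**k
    rowsel = np.arange(n)
    d = dmat[choice, rowsel]
    masks = np.stack([mask for _, _, mask in aligns])[choice, rowsel]
    strands = np.array([s for s, _, _ in aligns])[choice]
    offsets = np.array([o for _, o, _ in aligns])[choice]

    kmers = np.array(sq.all_kmers(k))
    mism_tuples = [
        tuple(j + 1 for j in range(SEED_LENGTH) if (m >> j) & 1) for m in masks
    ]
    # within-ring clockwise order: mismatch-position tuple, then word
    order = sorted(range(n), key=lambda i: (d[i], mism_tuples[i], kmers[i]))
    order = np.array(order)

    ring_index = np.empty(n, dtype=np.int64)
    angle = np.empty(n, dtype=float)
    pos = 0
    for ring_d, size in zip(*np.unique(d, return_counts=True)):
        idx = order[pos : pos + size]
        ring_index[idx] = np.arange(size)
        angle[idx] = 2 * np.pi * np.arange(size) / size
        pos += size

    entries = pd.DataFrame(
        dict(
            kmer=kmers[order],
            d=d[order],
            offset=offsets[order],
            strand=strands[order],
            mism_pos=[",".join(map(str, mism_tuples[i])) for i in order],
            ring_index=ring_index[order],
            angle=angle[order],
            z=table.z[order],
        )
    ).reset_index(drop=True)
    return SEL(seed=seed, entries=entries)


def sel_to_polar(sel: SEL) -> pd.DataFrame:
    """Lossless polar export: one (radius=d, angle, height=z) record per
    8-mer, in SEL order.  Sorting by (radius, angle) reconstructs the SEL
    ordering exactly."""
    return pd.DataFrame(
        dict(
            kmer=sel.entries["kmer"],
            radius=sel.entries["d"],
            angle=sel.entries["angle"],
            height=sel.entries["z"],
        )
    )
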
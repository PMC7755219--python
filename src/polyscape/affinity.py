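"""Pairing-rule affinity model for hairpin minor-groove binders.

An eight-ring hairpin polyamide reads six base pairs; ring-pair chemistry
(Im/Py -> G*C, Py/Im -> C*G, Py/Py -> A*T or T*A, written W) defines a
degenerate 6-bp target such as 5'-WGWWCW-3'.  Relative affinity of any
duplex hexamer is modelled as a geometric penalty per mismatched position:

    affinity(site) = a0 * theta**d,

where d is the number of positions at which the site (read on whichever
strand matches better) falls outside the target's IUPAC set.  The single
parameter theta in [0, 1) captures the steep drop-off in binding for
near-cognate sites; a0 sets the overall scale.
"""
from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np

from . import sequences as sq

SEED_LENGTH = 6
_SEED_ALPHABET = set("ACGTW")


@dataclass(frozen=True)
class AffinityModel:
    """Degenerate seed motif plus mismatch penalty.

    Parameters
    ----------
    seed:
        IUPAC string of length 6 over {A, C, G, T, W}.
    theta:
        Multiplicative affinity penalty per mismatched position, in [0, 1).
        theta=0 is the degenerate exact-match-only model.
    a0:
        Maximal relative affinity (dimensionless, > 0).
    """

    seed: str = "WGWWCW"
    theta: float = 0.1
    a0: float = 1.0

    def __post_init__(self):
        if len(self.seed) != SEED_LENGTH:
            raise ValueError("seed motif must have length 6")
        if not set(self.seed.upper()) <= _SEED_ALPHABET:
            raise ValueError("seed alphabet is restricted to {A,C,G,T,W}")
        object.__setattr__(self, "seed", self.seed.upper())
        if not (0.0 <= self.theta < 1.0):
            raise ValueError("theta must lie in [0, 1)")
        if self.a0 <= 0:
            raise ValueError("a0 must be positive")

    # -- vectorized lookup tables ------------------------------------

    @property
    def distance_table(self) -> np.ndarray:
        """Strand-minimal mismatch count for every packed hexamer code."""
        return sq.min_mismatch_table(self.seed)

    @property
    def affinity_table(self) -> np.ndarray:
        """a0 * theta**d for every packed hexamer code (theta=0 handled exactly)."""
        return _affinity_table(self.seed, self.theta, self.a0)


@functools.lru_cache(maxsize=None)
def _affinity_table(seed: str, theta: float, a0: float) -> np.ndarray:
    d = sq.min_mismatch_table(seed).astype(np.float64)
    if theta == 0.0:
        return np.where(d == 0, a0, 0.0)
    return a0 * theta**d


def site_affinity(site: str, model: AffinityModel) -> float:
    """Relative affinity of a concrete 6-bp duplex site.

    The site is scored on both strands and the better-matching orientation
    is used, so ``site_affinity(s) == site_affinity(revcomp(s))``.
    """
    if len(site) != SEED_LENGTH:
        raise ValueError("site must have length 6")
    code = sq.kmer_to_code(site)  # raises on non-ACGT
    return float(model.affinity_table[code])


def read_occupancy(read, model: AffinityModel) -> float:
    """Total bound fraction proxy for a read: sum of site affinities
    over every 6-bp window (each window counted once; strand handled
    inside the per-site affinity).  Windows containing non-ACGT
    characters contribute nothing.
    """
    codes = sq.encode(read) if isinstance(read, str) else np.asarray(read)
    if len(codes) < SEED_LENGTH:
        raise ValueError("read shorter than the 6-bp site width")
    wcodes, valid = sq.window_codes(codes, SEED_LENGTH)
    return float(model.affinity_table[wcodes[valid]].sum())


def occupancy_2d(reads: np.ndarray, model: AffinityModel) -> np.ndarray:
    """Vectorized :func:`read_occupancy` for a 2-D code array of clean reads."""
    wcodes = sq.window_codes_2d(reads, SEED_LENGTH)
    return model.affinity_table[wcodes].sum(axis=1)
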
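"""Genomescapes and Summation-of-Sites (SOS) window scores.

A genomescape assigns the in vitro k-mer intensity (standardized
enrichment z) to every genomic position: the value at start i is
``max(z(word), z(revcomp(word)))`` for the word at [i, i+k), so a site
scores identically regardless of the reference strand.  The SOS score of
a 420-bp window (stepped by half a window) aggregates -- sum by default,
mean behind a flag -- the intensities of all k-mers fully contained in
the window; the top-ranked windows are the predicted binding loci.
Coordinates are 0-based half-open throughout.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import sequences as sq
from .enrichment import EnrichmentTable

DEFAULT_WINDOW = 420
DEFAULT_STEP = 210
DEFAULT_TOP = 1000
MAX_N_FRAC = 0.5


@dataclass
class GenomeTrack:
    """Per-start k-mer intensities over one contig.

    ``values`` has ``length - k + 1`` slots; slots whose k-mer window
    contains a non-ACGT base are NaN and carry no value.  ``valid_bases``
    marks ACGT positions of the underlying sequence.
    """

    contig: str
    values: np.ndarray
    k: int
    length: int
    valid_bases: np.ndarray

    @property
    def starts(self) -> np.ndarray:
        return np.flatnonzero(~np.isnan(self.values))

    @property
    def n_values(self) -> int:
        return int((~np.isnan(self.values)).sum())


def genomescape(
    sequence, table: EnrichmentTable, k: int | None = None,
    contig: str = "chr",
) -> GenomeTrack:
    """Score a contig position-by-position with in vitro intensities."""
    k = table.k if k is None else k
    if k != table.k:
        raise ValueError("k must match the enrichment table")
    codes = sq.encode(sequence) if isinstance(sequence, str) else np.asarray(sequence)
    valid_bases = codes < 4
    L = len(codes)
    if L < k:
        return GenomeTrack(contig, np.zeros(0), k, L, valid_bases)
    rc = sq.revcomp_table(k)
    zmax = np.maximum(table.z, table.z[rc])
    wcodes, valid = sq.window_codes(codes, k)
    values = np.where(valid, zmax[wcodes], np.nan)
    return GenomeTrack(contig, values, k, L, valid_bases)


@dataclass
class SOSWindows:
    """Tiled fixed-width window scores for one contig.

    ``frame`` columns: chrom, start, end, score, n_kmers (contained
    valid k-mers), n_frac (non-ACGT base fraction), flagged (n_frac >
    0.5; excluded from ranking), in coordinate order.
    """

    frame: pd.DataFrame
    window: int
    step: int
    mode: str


def sos(
    track: GenomeTrack,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
    mode: str = "sum",
) -> SOSWindows:
    """Aggregate k-mer intensities over tiled windows.

    Windows start at multiples of ``step``; only full windows are kept.
    A k-mer contributes to a window iff its [i, i+k) interval is fully
    contained in it.
    """
    if window < track.k:
        raise ValueError("window must be at least k")
    if window % step != 0:
        raise ValueError("window must be a multiple of step")
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    L = track.length
    if L < window:
        starts = np.zeros(0, dtype=np.int64)
    else:
        starts = np.arange(0, L - window + 1, step, dtype=np.int64)

    vals = np.nan_to_num(track.values, nan=0.0)
    valid = ~np.isnan(track.values)
    cv = np.concatenate([[0.0], np.cumsum(vals)])
    cn = np.concatenate([[0], np.cumsum(valid.astype(np.int64))])
    cb = np.concatenate([[0], np.cumsum((~track.valid_bases).astype(np.int64))])

    hi = starts + window - track.k + 1  # one past the last contained k-mer start
    scores = cv[hi] - cv[starts]
    n_kmers = cn[hi] - cn[starts]
    n_frac = (cb[starts + window] - cb[starts]) / window
    if mode == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(n_kmers > 0, scores / n_kmers, np.nan)
    frame = pd.DataFrame(
        dict(
            chrom=track.contig,
            start=starts,
            end=starts + window,
            score=scores,
            n_kmers=n_kmers,
            n_frac=n_frac,
            flagged=n_frac > MAX_N_FRAC,
        )
    )
    return SOSWindows(frame=frame, window=window, step=step, mode=mode)


def top_peaks(windows, n: int = DEFAULT_TOP) -> pd.DataFrame:
    """Rank predicted peaks: top n windows by score, ties by (contig,
    start); flagged (N-rich) windows are excluded.  Returns a BED6-style
    frame with a ``rank`` column (1-based)."""
    if isinstance(windows, SOSWindows):
        frames = [windows.frame]
    else:
        frames = [w.frame for w in windows]
    df = pd.concat(frames, ignore_index=True)
    df = df[~df["flagged"]]
    df = df.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True],
        kind="mergesort",
    ).head(n)
    df = df.reset_index(drop=True)
    out = pd.DataFrame(
        dict(
            chrom=df["chrom"],
            start=df["start"],
            end=df["end"],
            name=[f"sos_peak_{i + 1}" for i in range(len(df))],
            score=df["score"],
            strand=".",
        )
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def region_profile(obj, center: int, span: int = 10_000):
    """Values over a span centred on a locus, NaN-padded out of range.

    For a :class:`GenomeTrack`, returns one value per position (length
    ``span``).  For :class:`SOSWindows`, returns one value per step
    offset (length ``span // step``): the score of the window starting at
    each grid position, NaN where no full window exists.
    """
    if span % 2 != 0:
        raise ValueError("span must be even")
    if span == 0:
        return np.zeros(0)
    lo = center - span // 2
    if isinstance(obj, GenomeTrack):
        out = np.full(span, np.nan)
        src_lo = max(lo, 0)
        src_hi = min(lo + span, len(obj.values))
        if src_hi > src_lo:
            out[src_lo - lo : src_hi - lo] = obj.values[src_lo:src_hi]
        return out
    if isinstance(obj, SOSWindows):
        step = obj.step
        ncol = span // step
        out = np.full(ncol, np.nan)
        by_start = dict(zip(obj.frame["start"].to_numpy(),
                            obj.frame["score"].to_numpy()))
        for j in range(ncol):
            pos = lo + j * step
            # windows only exist on the step grid
            if pos % step == 0 and pos in by_start:
                out[j] = by_start[pos]
        return out
    raise TypeError("expected a GenomeTrack or SOSWindows")


def profile_matrix(obj, centers, span: int = 10_000) -> np.ndarray:
    """Stack :func:`region_profile` rows for a list of loci (heatmap input)."""
    rows = [region_profile(obj, int(c), span) for c in centers]
    if not rows:
        width = span if isinstance(obj, GenomeTrack) else span // obj.step
        return np.zeros((0, width))
    return np.vstack(rows)
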
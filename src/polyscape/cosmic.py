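"""Crosslink-capture tag densities, a stand-in peak caller and peak-set
comparison.

Tag sets are BED6-style DataFrames of mapped sonicated fragments; every
fragment is represented by its midpoint.  Densities around peaks use
25-bp bins over a 10-kbp window and are normalized to a fixed library
size so replicate depths are comparable.  The bundled peak caller is a
deliberately simple Poisson-rate scan intended only for synthetic
end-to-end tests -- real peak sets from an external caller can be read
in as BED and used directly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SPAN = 10_000
DEFAULT_BIN = 25
DEFAULT_NORM = 1e7


def tag_midpoints(tags: pd.DataFrame) -> dict:
    """Sorted fragment midpoints per contig."""
    mids = (tags["start"].to_numpy() + tags["end"].to_numpy()) // 2
    out = {}
    for contig, idx in tags.groupby("chrom").groups.items():
        out[contig] = np.sort(mids[np.asarray(idx)])
    return out


@dataclass
class DensityMatrix:
    """Binned, library-size-normalized tag densities around peaks.

    Rows follow the peak frame's order; columns are ``span // bin_size``
    bins of width ``bin_size`` spanning ``span`` bp centred on each peak.
    ``norm`` is the applied scale factor (``norm_to / total_tags``).
    """

    matrix: np.ndarray
    bin_size: int
    span: int
    norm: float
    peaks: pd.DataFrame

    @property
    def profile(self) -> np.ndarray:
        """Averaged (column-mean) profile across peaks."""
        return self.matrix.mean(axis=0) if len(self.matrix) else np.zeros(
            self.matrix.shape[1]
        )


def tag_density(
    tags: pd.DataFrame,
    peaks: pd.DataFrame,
    span: int = DEFAULT_SPAN,
    bin_size: int = DEFAULT_BIN,
    norm_to: float = DEFAULT_NORM,
) -> DensityMatrix:
    """Count fragment midpoints in bins around every peak centre.

    A tag contributes to every peak window containing its midpoint, so
    overlapping peaks each see it.  Values are scaled by
    ``norm_to / total_tags``.
    """
    if span % bin_size != 0:
        raise ValueError("span must be divisible by bin size")
    ncol = span // bin_size
    total = len(tags)
    norm = norm_to / total if total else 0.0
    mids = tag_midpoints(tags) if total else {}
    rows = np.zeros((len(peaks), ncol))
    for i, row in enumerate(peaks.itertuples(index=False)):
        centre = (row.start + row.end) // 2
        lo = centre - span // 2
        m = mids.get(row.chrom)
        if m is None:
            continue
        sel = m[np.searchsorted(m, lo) : np.searchsorted(m, lo + span)]
        if len(sel):
            rows[i] = np.bincount((sel - lo) // bin_size, minlength=ncol)[:ncol]
    return DensityMatrix(
        matrix=rows * norm, bin_size=bin_size, span=span, norm=norm,
        peaks=peaks.reset_index(drop=True),
    )


def call_peaks_simple(
    tags: pd.DataFrame,
    contig_lengths: dict,
    window: int = 420,
    step: int = 210,
    p_max: float = 1e-5,
) -> pd.DataFrame:
    """Poisson-rate window scan: a synthetic-data stand-in peak caller.

    Window midpoint counts are tested against a memoryless-arrival null
    with global rate ``total_midpoints * window / genome_length``;
    windows with tail probability < ``p_max`` are kept and overlapping
    keepers merged.  Each merged peak is scored by its best window's fold
    enrichment.  Returns a BED6-style frame sorted by score (rank 1 =
    strongest).
    """
    if len(tags) == 0:
        raise ValueError("empty tag set")
    genome_len = sum(int(v) for v in contig_lengths.values())
    if genome_len <= 0:
        raise ValueError("zero-length genome")
    mids = tag_midpoints(tags)
    total_mid = sum(len(v) for v in mids.values())
    lam = total_mid * window / genome_len

    merged_rows = []
    for contig, L in sorted(contig_lengths.items()):
        m = mids.get(contig)
        if m is None or L < window:
            continue
        starts = np.arange(0, L - window + 1, step, dtype=np.int64)
        counts = np.searchsorted(m, starts + window) - np.searchsorted(m, starts)
        pvals = stats.poisson.sf(counts - 1, lam)
        keep = np.flatnonzero(pvals < p_max)
        if keep.size == 0:
            continue
        fold = counts / lam
        cur_lo = cur_hi = None
        cur_fold = 0.0
        for i in keep:
            s, e = int(starts[i]), int(starts[i] + window)
            if cur_lo is None:
                cur_lo, cur_hi, cur_fold = s, e, fold[i]
            elif s <= cur_hi:  # overlapping keeper windows merge
                cur_hi = e
                cur_fold = max(cur_fold, fold[i])
            else:
                merged_rows.append((contig, cur_lo, cur_hi, cur_fold))
                cur_lo, cur_hi, cur_fold = s, e, fold[i]
        merged_rows.append((contig, cur_lo, cur_hi, cur_fold))

    df = pd.DataFrame(merged_rows, columns=["chrom", "start", "end", "score"])
    df = df.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df.insert(3, "name", [f"peak_{i + 1}" for i in range(len(df))])
    df["strand"] = "."
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# peak-set comparison


def _merge_intervals(df: pd.DataFrame) -> dict:
    """Per-contig merged (start, end) arrays, sorted."""
    out = {}
    for contig, sub in df.groupby("chrom"):
        ivs = sub[["start", "end"]].to_numpy()
        ivs = ivs[np.argsort(ivs[:, 0], kind="stable")]
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[contig] = np.array(merged, dtype=np.int64)
    return out


def _overlap_bp(a_ivs: np.ndarray, b_ivs: np.ndarray) -> int:
    i = j = 0
    total = 0
    while i < len(a_ivs) and j < len(b_ivs):
        lo = max(a_ivs[i, 0], b_ivs[j, 0])
        hi = min(a_ivs[i, 1], b_ivs[j, 1])
        if hi > lo:
            total += hi - lo
        if a_ivs[i, 1] <= b_ivs[j, 1]:
            i += 1
        else:
            j += 1
    return int(total)


def interval_overlap_fraction(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> float:
    """Fraction of a's intervals overlapping some b interval by
    >= min_overlap bp."""
    if len(a) == 0:
        return 0.0
    bm = _merge_intervals(b)
    hits = 0
    for row in a.itertuples(index=False):
        ivs = bm.get(row.chrom)
        if ivs is None:
            continue
        lo = np.searchsorted(ivs[:, 1], row.start, side="right")
        ov = 0
        for s, e in ivs[lo:]:
            if s >= row.end:
                break
            ov = max(ov, min(e, row.end) - max(s, row.start))
        if ov >= min_overlap:
            hits += 1
    return hits / len(a)


def compare_peak_sets(
    a: pd.DataFrame, b: pd.DataFrame, min_overlap: int = 1
) -> dict:
    """Symmetric overlap statistics between two peak sets.

    Returns ``frac_a_in_b`` and ``frac_b_in_a`` (interval-level overlap
    fractions) and ``jaccard`` (base-pair Jaccard of the merged sets).
    """
    am, bm = _merge_intervals(a), _merge_intervals(b)
    inter = sum(
        _overlap_bp(am[c], bm[c]) for c in set(am) & set(bm)
    )
    len_a = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in am.values())
    len_b = sum(int((iv[:, 1] - iv[:, 0]).sum()) for iv in bm.values())
    union = len_a + len_b - inter
    return dict(
        frac_a_in_b=interval_overlap_fraction(a, b, min_overlap),
        frac_b_in_a=interval_overlap_fraction(b, a, min_overlap),
        jaccard=inter / union if union else 0.0,
    )


def heatmap_export(
    matrix, scale: float = 1.0, order_by=None, path=None, cmap: str = "viridis"
):
    """Scale a matrix for display (data untouched), optionally reorder
    rows by a rank vector and render to an image file."""
    arr = matrix.matrix if isinstance(matrix, DensityMatrix) else np.asarray(matrix)
    out = arr * scale
    if order_by is not None:
        out = out[np.argsort(np.asarray(order_by), kind="stable")]
    if path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 8))
        ax.imshow(out, aspect="auto", interpolation="nearest", cmap=cmap)
        ax.set_xlabel("bin")
        ax.set_ylabel("peak")
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return out
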
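"""Synthetic-data generators with planted ground truth.

Three generators emulate the statistical structure the downstream
analysis assumes:

* :func:`simulate_selex` -- iterative selection from a randomized 20-bp
  dsDNA library.  Reads are resampled between rounds with probability
  proportional to ``1 + stringency * occupancy``; stringency 0 gives the
  mock ("processed library") series used to fit the background model.
* :func:`simulate_genome` -- an i.i.d. background contig with planted,
  non-overlapping clusters of exact / 1-mismatch / 2-mismatch seed
  sites.  The background is scrubbed of accidental near-cognate windows
  so the emitted truth intervals are exact under rescanning.
* :func:`simulate_cosmic` -- crosslink-capture fragments whose midpoints
  are drawn proportional to the local affinity landscape smoothed by a
  fragment-length kernel, with an optional multiplicative bias for sites
  flanked by T (the photo-crosslinker's preferred pyrimidine) and a
  uniform noise floor.

All generators are pure functions of (config, model): the RNG is seeded
from ``rng_seed`` and nothing else is consulted.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import sequences as sq
from .affinity import SEED_LENGTH, AffinityModel, occupancy_2d

log = logging.getLogger(__name__)

DEFAULT_CONTIG = "chrS"


# ---------------------------------------------------------------------------
# configs


@dataclass(frozen=True)
class SelexSimConfig:
    """Conditions of one SELEX series.

    ``stringency`` is the selection-strength analog of ligand
    concentration (lambda); 0 yields the mock library series.
    ``pool_factor`` is the molecular complexity of the selection pool
    relative to the sequencing depth: each round selects among
    ``pool_factor * n_reads`` molecules and ``n_reads`` of them are
    sequenced, so reads are essentially duplicate-free, as in a real
    library whose complexity vastly exceeds the read count.
    """

    n_reads: int
    read_len: int = 20
    rounds: int = 3
    stringency: float = 0.0
    base_comp: tuple = (0.25, 0.25, 0.25, 0.25)
    pool_factor: int = 1
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if self.read_len < 8:
            raise ValueError("read_len must be >= 8")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.stringency < 0:
            raise ValueError("stringency must be >= 0")
        if self.pool_factor < 1:
            raise ValueError("pool_factor must be >= 1")
        if len(self.base_comp) != 4 or abs(sum(self.base_comp) - 1.0) > 1e-9:
            raise ValueError("base_comp must be 4 probabilities summing to 1")


@dataclass(frozen=True)
class GenomeSimConfig:
    length: int = 2_000_000
    n_clusters: int = 30
    cluster_width: int = 420
    sites_per_cluster: tuple = (3, 4, 6)
    gc: float = 0.41
    rng_seed: int = 7

    def __post_init__(self):
        if self.n_clusters < 0 or any(s < 0 for s in self.sites_per_cluster):
            raise ValueError("counts must be >= 0")
        if self.n_clusters * self.cluster_width > self.length / 2:
            raise ValueError("clusters would cover more than half the contig")
        if not (0.0 <= self.gc <= 1.0):
            raise ValueError("gc must be a fraction")
        if len(self.sites_per_cluster) != 3:
            raise ValueError("sites_per_cluster is (n_exact, n_1mm, n_2mm)")


@dataclass(frozen=True)
class CosmicSimConfig:
    """Crosslink-capture conditions.

    ``capture_exponent`` models the protocol's sequential stringent
    washes: the probability that a bound complex survives capture is a
    power of its equilibrium affinity, so tag weights are
    ``site_affinity ** capture_exponent``.  1.0 recovers plain
    occupancy-proportional capture.
    """

    n_tags: int = 100_000
    frag_mean: float = 200.0
    frag_sd: float = 50.0
    noise_frac: float = 0.1
    t_bias: float = 1.5
    bias_reach: int = 12
    capture_exponent: float = 3.0
    rng_seed: int = 11

    def __post_init__(self):
        if self.n_tags < 0:
            raise ValueError("n_tags must be >= 0")
        if self.frag_mean <= 0:
            raise ValueError("frag_mean must be positive")
        if not (0.0 <= self.noise_frac <= 1.0):
            raise ValueError("noise_frac must be a fraction")
        if self.t_bias < 1.0:
            raise ValueError("t_bias must be >= 1")
        if self.capture_exponent <= 0:
            raise ValueError("capture_exponent must be positive")


# ---------------------------------------------------------------------------
# SELEX


def simulate_selex(config: SelexSimConfig, model: AffinityModel) -> list:
    """Run an in-silico SELEX series.

    Returns a list of ``rounds + 1`` uint8 code arrays of shape
    ``(n_reads, read_len)``: the sequenced sample of the initial library
    (element 0) and of the pool after each round of
    selection-with-amplification.  Selection operates on a molecular
    pool ``pool_factor`` times deeper than the sequencing depth;
    molecules are resampled with replacement with probability
    proportional to ``1 + stringency * occupancy``.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_pool = config.n_reads * config.pool_factor
    pool = rng.choice(
        4, size=(n_pool, config.read_len), p=np.asarray(config.base_comp)
    ).astype(np.uint8)

    def sequence_sample(molecules):
        if config.pool_factor == 1:
            return molecules
        return molecules[rng.choice(n_pool, size=config.n_reads, replace=True)]

    samples = [sequence_sample(pool)]
    for _ in range(config.rounds):
        weights = 1.0 + config.stringency * occupancy_2d(pool, model)
        probs = weights / weights.sum()
        idx = rng.choice(n_pool, size=n_pool, replace=True, p=probs)
        pool = pool[idx]
        samples.append(sequence_sample(pool))
    return samples


def reads_to_strings(pool: np.ndarray) -> list:
    return [sq.decode(row) for row in pool]


# ---------------------------------------------------------------------------
# genome with planted clusters


@dataclass
class GenomeTruth:
    """Planted-cluster ground truth for one synthetic contig."""

    contig: str
    intervals: pd.DataFrame  # chrom start end name score strand n_exact n_1mm n_2mm
    site_starts: dict = field(default_factory=dict)  # seed -> np.ndarray of starts

    def intervals_for(self, seed: str) -> pd.DataFrame:
        return self.intervals[self.intervals["name"] == seed].reset_index(drop=True)


class ClusterPlacementError(RuntimeError):
    pass


def _forced_bases(models) -> list:
    """Per window position, a base that mismatches every model's seed on
    both strands -- the scrub's guaranteed repair move."""
    out = []
    for j in range(SEED_LENGTH):
        banned = set()
        for m in models:
            sets = [set(s) for s in sq.pattern_sets(m.seed)]
            banned |= sets[j]
            banned |= {3 - c for c in sets[SEED_LENGTH - 1 - j]}
        out.append(min(set(range(4)) - banned))
    return out


def _site_scrubbable(site, models, forced) -> bool:
    """Can every window straddling this planted site be repaired?

    Checks each shifted frame with the background positions set to
    forced-mismatch bases (the scrub's strongest move): the frame must
    then sit at distance >= 3 from every seed (the in-cluster scrub
    threshold is 2).  A mismatch site whose content recreates a shifted
    near-match fails and is resampled.
    """
    d_tabs = [m.distance_table for m in models]
    for shift in range(1, SEED_LENGTH):
        left = np.array(
            [forced[j] for j in range(shift)] + list(site[: SEED_LENGTH - shift]),
            dtype=np.uint8,
        )
        right = np.array(
            list(site[shift:]) +
            [forced[j] for j in range(SEED_LENGTH - shift, SEED_LENGTH)],
            dtype=np.uint8,
        )
        for win in (left, right):
            code = 0
            for c in win:
                code = (code << 2) | int(c)
            if any(int(dt[code]) <= 2 for dt in d_tabs):
                return False
    return True


def _sample_site(rng, sets, n_mismatch, model, models, forced, tries: int = 500):
    """Concrete hexamer codes with strand-minimal distance exactly
    ``n_mismatch`` from ``model``'s seed; resampled until the site's
    shifted frames are also repairable by the background scrub."""
    for _ in range(tries):
        site = np.array([rng.choice(sorted(s)) for s in sets], dtype=np.uint8)
        if n_mismatch:
            pos = rng.choice(SEED_LENGTH, size=n_mismatch, replace=False)
            for p in pos:
                off = sorted(set(range(4)) - sets[p])
                site[p] = rng.choice(off)
        code = 0
        for c in site:
            code = (code << 2) | int(c)
        # the reverse strand may sit closer to the seed than intended
        if int(model.distance_table[code]) != n_mismatch:
            continue
        # a mismatch site must not be an exact site of another target
        if any(
            m is not model and int(m.distance_table[code]) == 0
            for m in models
        ):
            continue
        if _site_scrubbable(site, models, forced):
            return site
    raise ClusterPlacementError("could not sample a scrubbable site")


def _place_nonoverlapping(rng, n, width, length, occupied, margin, tries=2000):
    starts = []
    for _ in range(n):
        for _attempt in range(tries):
            s = int(rng.integers(0, length - width + 1))
            if all(s + width + margin <= o or o2 + margin <= s for o, o2 in occupied):
                occupied.append((s, s + width))
                starts.append(s)
                break
        else:
            raise ClusterPlacementError(
                "could not place clusters without overlap; reduce n_clusters"
            )
    return starts


def simulate_genome(config: GenomeSimConfig, models, contig: str = DEFAULT_CONTIG):
    """Generate a synthetic contig with planted binding-site clusters.

    ``models`` may be a single :class:`AffinityModel` or a sequence; each
    model receives ``config.n_clusters`` clusters.  Returns
    ``(genome_codes, truth)`` where ``truth`` is a :class:`GenomeTruth`
    with 0-based half-open intervals.

    The emitted truth is exact by construction: after planting, every
    window outside a planted site is mutated until it sits at mismatch
    distance >= 2 from every seed genome-wide and >= 3 from the cluster's
    own seed inside cluster intervals, so rescanning a truth interval
    recovers exactly the planted 0/1/2-mismatch site counts.
    """
    if isinstance(models, AffinityModel):
        models = [models]
    models = list(models)
    rng = np.random.default_rng(config.rng_seed)
    L = config.length
    p_bg = np.array(
        [(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2]
    )
    genome = rng.choice(4, size=L, p=p_bg).astype(np.uint8)

    n_exact, n_1mm, n_2mm = config.sites_per_cluster
    per_cluster = [(0, n_exact), (1, n_1mm), (2, n_2mm)]

    occupied: list = []
    footprint = np.zeros(L, dtype=bool)
    clusters = []  # (model_idx, start) in planting order
    cluster_fill = {}  # (model_idx, start) -> list of (abs_start, d)

    width = config.cluster_width
    p_bg_choice = p_bg  # background base law, reused on cluster redraws

    forced = _forced_bases(models)

    def fill_cluster(mi, cs):
        """(Re)draw a cluster's local background and planted sites."""
        model = models[mi]
        sets = [set(s) for s in sq.pattern_sets(model.seed)]
        genome[cs : cs + width] = rng.choice(
            4, size=width, p=p_bg_choice
        ).astype(np.uint8)
        footprint[cs : cs + width] = False
        # non-overlapping site offsets with >= 6 bp gaps, so windows
        # straddling a site keep enough mutable bases for the scrub
        gap = SEED_LENGTH
        site_occ: list = []
        placed = []
        for d, count in per_cluster:
            for _ in range(count):
                for _attempt in range(2000):
                    off = int(rng.integers(0, width - SEED_LENGTH + 1))
                    if all(
                        off + SEED_LENGTH + gap <= o or o2 + gap <= off
                        for o, o2 in site_occ
                    ):
                        site_occ.append((off, off + SEED_LENGTH))
                        placed.append((cs + off, d))
                        break
                else:
                    raise ClusterPlacementError(
                        "could not place sites inside a cluster"
                    )
        for start, d in placed:
            site = _sample_site(rng, sets, d, model, models, forced)
            genome[start : start + SEED_LENGTH] = site
            footprint[start : start + SEED_LENGTH] = True
        cluster_fill[(mi, cs)] = placed

    for mi, model in enumerate(models):
        if config.n_clusters == 0:
            continue
        starts = _place_nonoverlapping(
            rng, config.n_clusters, width, L, occupied, margin=12
        )
        for cs in starts:
            clusters.append((mi, cs))
            fill_cluster(mi, cs)

    cluster_spans = {
        mi: [(cs, cs + width) for m2, cs in clusters if m2 == mi]
        for mi in range(len(models))
    }

    # scrub; clusters whose layout cannot be scrubbed (a planted
    # mismatch site may recreate a near-exact match in a shifted frame
    # with no repairable base) are redrawn and the scrub repeated
    for _redraw_round in range(10):
        planted_starts = {
            mi: [s for (m2, cs) in clusters if m2 == mi
                 for s, _d in cluster_fill[(m2, cs)]]
            for mi in range(len(models))
        }
        stuck = _scrub(genome, models, footprint, planted_starts,
                       cluster_spans, rng)
        if stuck.size == 0:
            break
        redrawn = set()
        for s in stuck:
            for mi, cs in clusters:
                if cs - SEED_LENGTH < s < cs + width and (mi, cs) not in redrawn:
                    fill_cluster(mi, cs)
                    redrawn.add((mi, cs))
        if not redrawn:
            raise ClusterPlacementError("background scrub did not converge")
    else:
        raise ClusterPlacementError("background scrub did not converge")

    rows = []
    planted_site_starts = {m.seed: [] for m in models}
    for mi, cs in sorted(clusters, key=lambda c: c[1]):
        model = models[mi]
        for start, d in cluster_fill[(mi, cs)]:
            if d == 0:
                planted_site_starts[model.seed].append(start)
        rows.append(
            dict(
                chrom=contig,
                start=cs,
                end=cs + width,
                name=model.seed,
                score=n_exact + n_1mm + n_2mm,
                strand="+",
                n_exact=n_exact,
                n_1mm=n_1mm,
                n_2mm=n_2mm,
            )
        )

    truth = GenomeTruth(
        contig=contig,
        intervals=pd.DataFrame(
            rows,
            columns=[
                "chrom", "start", "end", "name", "score", "strand",
                "n_exact", "n_1mm", "n_2mm",
            ],
        ).sort_values(["start"]).reset_index(drop=True),
        site_starts={
            seed: np.array(sorted(v), dtype=np.int64)
            for seed, v in planted_site_starts.items()
        },
    )
    _verify_truth(genome, models, truth, config)
    return genome, truth


def _scrub(genome, models, footprint, planted_starts, cluster_spans, rng,
           max_passes: int = 40):
    """Mutate accidental near-cognate windows away from every seed.

    Thresholds: mismatch distance <= 1 is repaired genome-wide, <= 2
    inside a model's own cluster intervals; planted windows keep their
    intended distance and only non-footprint bases are ever touched.
    A fast vectorized phase clears the bulk of the offenders, then a
    sequential phase repairs the residual window by window, escalating
    to multi-base "forced mismatch" edits (bases outside every seed's
    allowed set on both strands) whose effect on the distance is
    guaranteed.  Rare windows that cannot be repaired without corrupting
    a neighbour are tolerated in the open background; the starts of
    irreparable windows inside cluster intervals -- where they would
    falsify the emitted truth -- are returned to the caller so the
    affected clusters can be redrawn.
    """
    L = len(genome)
    nwin = L - SEED_LENGTH + 1
    if nwin <= 0:
        return np.zeros(0, dtype=np.int64)
    mutable = ~footprint
    cm = np.concatenate([[0], np.cumsum(mutable)])
    has_mutable = (cm[SEED_LENGTH:] - cm[:-SEED_LENGTH]) > 0

    thr = {}
    planted_mask = {}
    for mi, _model in enumerate(models):
        t = np.ones(nwin, dtype=np.int8)
        for cs, ce in cluster_spans[mi]:
            t[cs : max(cs, ce - SEED_LENGTH + 1)] = 2
        thr[mi] = t
        pm = np.zeros(nwin, dtype=bool)
        starts = np.array(planted_starts[mi], dtype=np.int64)
        if starts.size:
            pm[starts] = True
        planted_mask[mi] = pm

    d_tables = [m.distance_table.astype(np.int64) for m in models]
    min_d_all = np.minimum.reduce(d_tables)

    def offender_mask(wcodes):
        off = np.zeros(nwin, dtype=bool)
        for mi in range(len(models)):
            off |= (d_tables[mi][wcodes] <= thr[mi]) & ~planted_mask[mi]
        return off & has_mutable

    # ---- phase 1: vectorized bulk repair -------------------------------
    prev = np.inf
    for _pass in range(max_passes):
        wcodes, _ = sq.window_codes(genome, SEED_LENGTH)
        idx = np.flatnonzero(offender_mask(wcodes))
        if idx.size == 0:
            return np.zeros(0, dtype=np.int64)
        if idx.size >= 0.95 * prev:
            break  # plateau; hand the residual to the sequential phase
        prev = idx.size
        keep = []  # de-overlap so simultaneous edits stay independent
        last = -SEED_LENGTH
        for s in idx:
            if s >= last + SEED_LENGTH:
                keep.append(s)
                last = s
        idx = np.array(keep, dtype=np.int64)
        best_score = np.full(idx.size, -1, dtype=np.int64)
        best_pos = np.zeros(idx.size, dtype=np.int64)
        best_base = np.zeros(idx.size, dtype=np.uint8)
        for pos in range(SEED_LENGTH):
            p = idx + pos
            digit = genome[p].astype(np.int64)
            ok = mutable[p]
            for b in range(4):
                # judged by the worst resulting window among all windows
                # covering the mutated base
                score = np.full(idx.size, np.iinfo(np.int32).max, dtype=np.int64)
                for j in range(SEED_LENGTH):
                    ws = p - j
                    inb = (ws >= 0) & (ws < nwin)
                    wsc = np.clip(ws, 0, nwin - 1)
                    shift = 2 * (SEED_LENGTH - 1 - j)
                    w = wcodes[wsc]
                    nc = w - (((w >> shift) & 3) << shift) + (b << shift)
                    score = np.where(inb, np.minimum(score, min_d_all[nc]), score)
                score = np.where(ok & (b != digit), score, -1)
                upd = score > best_score
                best_score[upd] = score[upd]
                best_pos[upd] = pos
                best_base[upd] = b
        fixable = best_score >= 0
        genome[idx[fixable] + best_pos[fixable]] = best_base[fixable]

    # ---- phase 2: sequential residual repair ---------------------------
    forced_base = _forced_bases(models)

    def window_code(s):
        code = 0
        for c in genome[s : s + SEED_LENGTH]:
            code = (code << 2) | int(c)
        return code

    def clears(s):
        code = window_code(s)
        for mi in range(len(models)):
            if planted_mask[mi][s]:
                continue
            if d_tables[mi][code] <= thr[mi][s]:
                return False
        return True

    def n_bad_near(s):
        lo = max(0, s - SEED_LENGTH + 1)
        hi = min(nwin, s + SEED_LENGTH)
        return sum(
            0 if clears(w) or not has_mutable[w] else 1 for w in range(lo, hi)
        )

    import itertools as _it

    for _sweep in range(20):
        wcodes, _ = sq.window_codes(genome, SEED_LENGTH)
        idx = np.flatnonzero(offender_mask(wcodes))
        if idx.size == 0:
            return np.zeros(0, dtype=np.int64)
        progress = False
        for s in idx:
            if clears(s):
                continue  # repaired as a neighbour of an earlier fix
            mutpos = [j for j in range(SEED_LENGTH) if mutable[s + j]]
            candidates = [
                ((j,), (b,))
                for j in mutpos
                for b in range(4)
                if b != genome[s + j]
            ]
            candidates += [
                (js, tuple(forced_base[j] for j in js))
                for r in (2, 3)
                for js in _it.combinations(mutpos, r)
            ]
            best = None
            for js, bs in candidates:
                saved = genome[[s + j for j in js]].copy()
                for j, b in zip(js, bs):
                    genome[s + j] = b
                if clears(s):
                    badness = (n_bad_near(s), len(js))
                    if best is None or badness < best[0]:
                        best = (badness, js, bs)
                genome[[s + j for j in js]] = saved
            if best is not None:
                _, js, bs = best
                for j, b in zip(js, bs):
                    genome[s + j] = b
                progress = True
        if not progress:
            break

    # ---- tolerance check ----------------------------------------------
    wcodes, _ = sq.window_codes(genome, SEED_LENGTH)
    n_background = 0
    stuck = []
    for mi in range(len(models)):
        d = d_tables[mi][wcodes]
        off = (d <= thr[mi]) & ~planted_mask[mi] & has_mutable
        stuck.append(np.flatnonzero(off & (thr[mi] == 2)))
        n_background += int((off & (thr[mi] == 1)).sum())
    if n_background:
        log.warning(
            "%d near-cognate background window(s) left unscrubbed", n_background
        )
    return np.unique(np.concatenate(stuck))



def _verify_truth(genome, models, truth: GenomeTruth, config: GenomeSimConfig):
    for model in models:
        ivs = truth.intervals_for(model.seed)
        for _, row in ivs.iterrows():
            wcodes, _ = sq.window_codes(
                genome[row.start : row.end], SEED_LENGTH
            )
            d = model.distance_table[wcodes]
            got = tuple(int((d == i).sum()) for i in range(3))
            want = tuple(config.sites_per_cluster)
            if got != want:
                raise ClusterPlacementError(
                    f"truth self-check failed at {row.start}: {got} != {want}"
                )


# ---------------------------------------------------------------------------
# crosslink-capture tags


def simulate_cosmic(
    genome,
    truth,
    model: AffinityModel,
    config: CosmicSimConfig,
    contig: str | None = None,
) -> pd.DataFrame:
    """Draw crosslink-capture fragments over a synthetic contig.

    Midpoints of ``(1 - noise_frac) * n_tags`` fragments are sampled
    proportional to the per-position site-affinity landscape smoothed by
    a Gaussian kernel of scale ``frag_mean / 2`` (a fragment's midpoint
    can sit up to about half a fragment away from the crosslinked site);
    site weights are multiplied by ``t_bias`` when a T occurs within
    ``bias_reach`` bp of either site edge.  The remaining tags are
    uniform noise.  Returns a BED6-style DataFrame sorted by start.
    """
    from scipy.ndimage import gaussian_filter1d

    codes = sq.encode(genome) if isinstance(genome, str) else np.asarray(genome)
    L = len(codes)
    if L <= config.frag_mean:
        raise ValueError("contig shorter than the mean fragment length")
    if contig is None:
        contig = getattr(truth, "contig", DEFAULT_CONTIG)
    rng = np.random.default_rng(config.rng_seed)
    if config.n_tags == 0:
        return _tags_frame(contig, np.zeros(0, int), np.zeros(0, int), [])

    n_noise = int(round(config.noise_frac * config.n_tags))
    n_sig = config.n_tags - n_noise

    mids = []
    if n_sig > 0:
        wcodes, valid = sq.window_codes(codes, SEED_LENGTH)
        weights = np.where(
            valid, model.affinity_table[wcodes] ** config.capture_exponent, 0.0
        )
        if config.t_bias > 1.0 and config.bias_reach > 0:
            t_near = _t_near_edges(codes, config.bias_reach)
            weights = weights * np.where(t_near, config.t_bias, 1.0)
        density = np.zeros(L)
        density[: len(weights)] = weights
        density = np.roll(density, SEED_LENGTH // 2)  # centre on the site
        density = gaussian_filter1d(
            density, sigma=max(config.frag_mean / 2.0, 1.0), mode="constant"
        )
        total = density.sum()
        if total <= 0:
            log.warning(
                "no affinity anywhere on the contig; falling back to uniform "
                "placement for the signal fraction"
            )
            mids.append(rng.integers(0, L, size=n_sig))
        else:
            mids.append(
                rng.choice(L, size=n_sig, replace=True, p=density / total)
            )
    if n_noise > 0:
        mids.append(rng.integers(0, L, size=n_noise))
    mid = np.concatenate(mids) if mids else np.zeros(0, dtype=np.int64)

    lengths = rng.normal(config.frag_mean, config.frag_sd, size=config.n_tags)
    lengths = np.maximum(np.round(lengths), 50).astype(np.int64)  # sonication floor
    start = mid - lengths // 2
    end = start + lengths
    start = np.clip(start, 0, L)
    end = np.clip(end, 0, L)
    keep = end > start
    strand = rng.choice(np.array(["+", "-"]), size=config.n_tags)
    order = np.argsort(start[keep], kind="stable")
    return _tags_frame(contig, start[keep][order], end[keep][order],
                       strand[keep][order])


def _t_near_edges(codes: np.ndarray, reach: int) -> np.ndarray:
    """For every window start s: is there a T in [s-reach, s) or
    [s+6, s+6+reach)?"""
    L = len(codes)
    nwin = L - SEED_LENGTH + 1
    is_t = (codes == 3).astype(np.int64)
    ct = np.concatenate([[0], np.cumsum(is_t)])

    def span_count(lo, hi):  # number of Ts in [lo, hi) per window, clipped
        lo = np.clip(lo, 0, L)
        hi = np.clip(hi, 0, L)
        return ct[hi] - ct[lo]

    s = np.arange(nwin)
    up = span_count(s - reach, s)
    down = span_count(s + SEED_LENGTH, s + SEED_LENGTH + reach)
    return (up + down) > 0


def _tags_frame(contig, start, end, strand) -> pd.DataFrame:
    n = len(start)
    return pd.DataFrame(
        dict(
            chrom=[contig] * n,
            start=np.asarray(start, dtype=np.int64),
            end=np.asarray(end, dtype=np.int64),
            name=[f"tag_{i}" for i in range(n)],
            score=np.zeros(n, dtype=np.int64),
            strand=list(strand),
        )
    )
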
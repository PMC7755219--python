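"""Canonical study conditions for the synthetic analyses.

These constants define the simulated counterpart of the experimental
design: two eight-ring hairpin ligands whose degenerate 6-bp targets
differ at one position (WGWWCW vs WGGWCW), three rounds of selection
from a randomized 20-bp library, a 2-Mb contig with 30 planted site
clusters per ligand, and ~1e5 crosslink fragments per capture.  All
seeded entry points derive their streams from a single base seed so a
whole study is reproducible from one integer.
"""
from __future__ import annotations

from .affinity import AffinityModel
from .simulate import CosmicSimConfig, GenomeSimConfig, SelexSimConfig

#: ligand 1 target (androgen-response-element half site analog)
MODEL_1 = AffinityModel(seed="WGWWCW", theta=0.1, a0=1.0)
#: ligand 2 target (estrogen-response-element half site analog)
MODEL_2 = AffinityModel(seed="WGGWCW", theta=0.1, a0=1.0)

#: selection-strength analog of the high-concentration condition
STRINGENCY = 50.0

N_READS = 200_000
READ_LEN = 20
ROUNDS = 3

SELEX_SEED = 42
SELEX_SEED_2 = 52
GENOME_SEED = 7
COSMIC_SEED = 11
COSMIC_SEED_REP2 = 12
COSMIC_SEED_2 = 21

#: offset separating an enriched series' RNG stream from its mock series
MOCK_SEED_OFFSET = 101

#: pool complexity of the mock series relative to its sequencing depth.
#: The no-ligand series is not bottlenecked by selection, so its reads are
#: nearly duplicate-free; a clean mock keeps background-model noise from
#: propagating coherently into whole core families' expected counts.
MOCK_POOL_FACTOR = 10

K = 8
MARKOV_ORDER = 5
ALPHA = 1.0
EPSILON = 0.5
TOP_KMERS = 50
SOS_WINDOW = 420
SOS_STEP = 210
TOP_PEAKS = 1000
DENSITY_SPAN = 10_000
DENSITY_BIN = 25


def selex_config(
    seed: int = SELEX_SEED,
    stringency: float = STRINGENCY,
    n_reads: int = N_READS,
    rounds: int = ROUNDS,
) -> SelexSimConfig:
    return SelexSimConfig(
        n_reads=n_reads,
        read_len=READ_LEN,
        rounds=rounds,
        stringency=stringency,
        rng_seed=seed,
    )


def mock_config(enriched: SelexSimConfig) -> SelexSimConfig:
    """The matched mock (no-ligand) series for an enriched config.

    Same depth and rounds, stringency 0, RNG stream offset so the two
    series are independent.
    """
    return SelexSimConfig(
        n_reads=enriched.n_reads,
        read_len=enriched.read_len,
        rounds=enriched.rounds,
        stringency=0.0,
        base_comp=enriched.base_comp,
        pool_factor=MOCK_POOL_FACTOR,
        rng_seed=enriched.rng_seed + MOCK_SEED_OFFSET,
    )


def genome_config(seed: int = GENOME_SEED) -> GenomeSimConfig:
    return GenomeSimConfig(rng_seed=seed)


def cosmic_config(seed: int = COSMIC_SEED, **overrides) -> CosmicSimConfig:
    return CosmicSimConfig(rng_seed=seed, **overrides)
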
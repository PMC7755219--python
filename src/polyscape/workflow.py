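"""High-level helpers chaining simulation and enrichment stages.

These are the library-level building blocks the CLI, the test suite and
the reproduction script share: run an enriched + mock SELEX pair,
produce the per-round enrichment tables, and take a table through the
motif pipeline.
"""
from __future__ import annotations

from . import presets
from .affinity import AffinityModel
from .enrichment import (EnrichmentTable, count_kmers, enrich,
                         expected_counts, fit_markov)
from .motif import align_kmers, build_pwm, top_kmers
from .simulate import SelexSimConfig, simulate_selex


def run_selex_pair(model: AffinityModel, config: SelexSimConfig):
    """Simulate an enriched series and its matched mock series.

    Returns ``(enriched_pools, mock_pools)``, each a list of per-round
    read-code arrays (round 0 = initial library).
    """
    enriched = simulate_selex(config, model)
    mock = simulate_selex(presets.mock_config(config), model)
    return enriched, mock


def csi_tables(
    enriched_pools,
    mock_pools,
    k: int = presets.K,
    order: int = presets.MARKOV_ORDER,
    alpha: float = presets.ALPHA,
    epsilon: float = presets.EPSILON,
    meta: dict | None = None,
) -> list:
    """Per-round enrichment tables (index r-1 holds round r).

    Round r observed counts are normalized against an order-m background
    fitted on the mock pool processed the same number of rounds.
    """
    tables = []
    for r in range(1, len(enriched_pools)):
        observed = count_kmers(enriched_pools[r], k)
        background = fit_markov(mock_pools[r], order=order, alpha=alpha)
        expected = expected_counts(background, observed.n_windows, k)
        tables.append(
            enrich(
                observed, expected, epsilon=epsilon,
                meta=dict(meta or {}, round=r),
            )
        )
    return tables


def motif_pipeline(table: EnrichmentTable, n_top: int = presets.TOP_KMERS,
                   pseudocount: float = 0.25):
    """Top-k-mers -> alignment -> PWM for one enrichment table."""
    ranked = top_kmers(table, n_top)
    aligned = align_kmers(ranked)
    return ranked, aligned, build_pwm(aligned, pseudocount=pseudocount)
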
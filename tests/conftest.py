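"""Session-scoped fixtures reproducing the canonical synthetic study.

The heavy simulations (SELEX series, planted genome, crosslink tags)
are computed once per session and shared across test modules.
"""
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from polyscape import presets
from polyscape.simulate import simulate_cosmic, simulate_genome
from polyscape.workflow import csi_tables, run_selex_pair


@pytest.fixture(scope="session")
def study_m1():
    """Enriched + mock pools and per-round tables for the WGWWCW ligand."""
    enriched, mock = run_selex_pair(
        presets.MODEL_1, presets.selex_config(seed=presets.SELEX_SEED)
    )
    tables = csi_tables(enriched, mock)
    return dict(enriched=enriched, mock=mock, tables=tables,
                model=presets.MODEL_1)


@pytest.fixture(scope="session")
def study_m2():
    enriched, mock = run_selex_pair(
        presets.MODEL_2, presets.selex_config(seed=presets.SELEX_SEED_2)
    )
    tables = csi_tables(enriched, mock)
    return dict(enriched=enriched, mock=mock, tables=tables,
                model=presets.MODEL_2)


@pytest.fixture(scope="session")
def table_m1(study_m1):
    """Round-1 enrichment table for the WGWWCW ligand."""
    return study_m1["tables"][0]


@pytest.fixture(scope="session")
def table_m2(study_m2):
    return study_m2["tables"][0]


@pytest.fixture(scope="session")
def genome_truth():
    """2-Mb contig with 30 planted clusters per ligand."""
    return simulate_genome(
        presets.genome_config(), [presets.MODEL_1, presets.MODEL_2]
    )


@pytest.fixture(scope="session")
def tag_sets(genome_truth):
    genome, truth = genome_truth
    return dict(
        m1a=simulate_cosmic(genome, truth, presets.MODEL_1,
                            presets.cosmic_config(seed=presets.COSMIC_SEED)),
        m1b=simulate_cosmic(genome, truth, presets.MODEL_1,
                            presets.cosmic_config(seed=presets.COSMIC_SEED_REP2)),
        m2=simulate_cosmic(genome, truth, presets.MODEL_2,
                           presets.cosmic_config(seed=presets.COSMIC_SEED_2)),
    )
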
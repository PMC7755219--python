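"""End-to-end pipeline runner over a YAML/keyword configuration.

Chains the stages in dependency order on synthetic inputs -- simulate
(SELEX, genome, crosslink tags), CSI enrichment, SEL, motif, genomescape
and SOS, tag density and peak comparison -- writing every artifact plus
a JSON run manifest stamped with the configuration hash and seed.
Reruns with the same configuration are byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import io, presets
from .affinity import AffinityModel
from .cosmic import call_peaks_simple, compare_peak_sets, tag_density
from .genomescape import genomescape, sos, top_peaks
from .landscape import build_sel
from .motif import recovered_motif, site_width
from .simulate import (CosmicSimConfig, GenomeSimConfig, SelexSimConfig,
                       reads_to_strings, simulate_cosmic, simulate_genome,
                       simulate_selex)
from .workflow import csi_tables, motif_pipeline, run_selex_pair

log = logging.getLogger(__name__)

STAGES = ("csi", "sel", "sos", "cosmic")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated parameters of a full synthetic run."""

    outdir: str = "polyscape_out"
    seed1: str = "WGWWCW"
    seed2: str = "WGGWCW"
    theta: float = 0.1
    a0: float = 1.0
    stringency: float = presets.STRINGENCY
    n_reads: int = 20_000
    read_len: int = 20
    rounds: int = 1
    k: int = presets.K
    order: int = presets.MARKOV_ORDER
    alpha: float = presets.ALPHA
    epsilon: float = presets.EPSILON
    top_kmers: int = presets.TOP_KMERS
    genome_length: int = 400_000
    n_clusters: int = 8
    cluster_width: int = 420
    sites_per_cluster: tuple = (3, 4, 6)
    gc: float = 0.41
    n_tags: int = 40_000
    frag_mean: float = 200.0
    frag_sd: float = 50.0
    noise_frac: float = 0.1
    t_bias: float = 1.5
    bias_reach: int = 12
    capture_exponent: float = 3.0
    window: int = presets.SOS_WINDOW
    step: int = presets.SOS_STEP
    top_n: int = presets.TOP_PEAKS
    span: int = presets.DENSITY_SPAN
    bin: int = presets.DENSITY_BIN
    rng_seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k <= self.order:
            raise ValueError("k must exceed the background model order")
        if self.window % self.step != 0:
            raise ValueError("window must be a multiple of step")
        if self.span % self.bin != 0:
            raise ValueError("span must be divisible by bin")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sites_per_cluster" in data:
            data = dict(data, sites_per_cluster=tuple(data["sites_per_cluster"]))
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, which: str = "all") -> dict:
    """Execute the requested stage and everything it depends on.

    Returns the manifest dictionary (also written to
    ``<outdir>/manifest.json``).
    """
    if which not in STAGES + ("all",):
        raise ValueError(f"unknown stage {which!r}")
    wanted = set(STAGES) if which == "all" else {which}

    os.makedirs(config.outdir, exist_ok=True)
    outputs = {}
    summary = {}

    def out(name):
        path = os.path.join(config.outdir, name)
        outputs[name] = path
        return path

    model1 = AffinityModel(config.seed1, config.theta, config.a0)
    model2 = AffinityModel(config.seed2, config.theta, config.a0)

    # --- simulate + CSI (needed by every downstream stage) ---------------
    selex_cfg = SelexSimConfig(
        n_reads=config.n_reads, read_len=config.read_len, rounds=config.rounds,
        stringency=config.stringency, rng_seed=config.rng_seed + 1,
    )
    enriched, mock = run_selex_pair(model1, selex_cfg)
    io.write_sequences(reads_to_strings(enriched[-1]), out("reads_round%d.fa" % config.rounds))
    io.write_sequences(reads_to_strings(mock[-1]), out("mock_round%d.fa" % config.rounds))
    tables = csi_tables(
        enriched, mock, k=config.k, order=config.order,
        alpha=config.alpha, epsilon=config.epsilon,
        meta={"condition": config.seed1},
    )
    table = tables[-1]
    if "csi" in wanted or wanted & {"sel", "sos", "cosmic"}:
        table.write_tsv(out("enrichment.tsv"))
        ranked, aligned, pwm = motif_pipeline(table, config.top_kmers)
        with open(out("pwm_meme.txt"), "w") as fh:
            fh.write(pwm.to_meme(name=config.seed1))
        summary["site_width"] = site_width(pwm)
        summary["recovered_motif"] = recovered_motif(pwm)

    if "sel" in wanted:
        sel = build_sel(table, config.seed1)
        sel.write_tsv(out("sel.tsv"))
        summary["ring0_size"] = int((sel.entries["d"] == 0).sum())

    if wanted & {"sos", "cosmic"}:
        genome_cfg = GenomeSimConfig(
            length=config.genome_length, n_clusters=config.n_clusters,
            cluster_width=config.cluster_width,
            sites_per_cluster=config.sites_per_cluster, gc=config.gc,
            rng_seed=config.rng_seed + 2,
        )
        genome, truth = simulate_genome(genome_cfg, [model1, model2])
        io.write_fasta_genome({truth.contig: _decode(genome)}, out("genome.fa"))
        io.write_bed(truth.intervals, out("truth.bed"))
        track = genomescape(genome, table, contig=truth.contig)
        windows = sos(track, window=config.window, step=config.step)
        peaks_sos = top_peaks(windows, n=config.top_n)
        io.write_bedgraph(track, out("genomescape.bedgraph"))
        io.write_bed(peaks_sos.drop(columns=["rank"]), out("sos_peaks.bed"))
        summary["n_sos_windows"] = int(len(windows.frame))

    if "cosmic" in wanted:
        cosmic_cfg = CosmicSimConfig(
            n_tags=config.n_tags, frag_mean=config.frag_mean,
            frag_sd=config.frag_sd, noise_frac=config.noise_frac,
            t_bias=config.t_bias, bias_reach=config.bias_reach,
            capture_exponent=config.capture_exponent,
            rng_seed=config.rng_seed + 3,
        )
        tags = simulate_cosmic(genome, truth, model1, cosmic_cfg)
        io.write_bed(tags, out("tags.bed"))
        called = call_peaks_simple(
            tags, {truth.contig: len(genome)},
            window=config.window, step=config.step,
        )
        io.write_bed(called.drop(columns=["rank"]), out("called_peaks.bed"))
        dens = tag_density(tags, called.head(min(len(called), config.top_n)),
                           span=config.span, bin_size=config.bin)
        np.savetxt(out("tag_density.tsv"), dens.matrix, delimiter="\t", fmt="%.6g")
        stats = compare_peak_sets(called, peaks_sos)
        summary["peaks_called"] = int(len(called))
        summary["sos_vs_called_jaccard"] = round(stats["jaccard"], 6)

    manifest = dict(
        config=dataclasses.asdict(config),
        config_hash=config.digest(),
        seed=config.rng_seed,
        stage=which,
        outputs=sorted(outputs),
        summary=summary,
    )
    with open(os.path.join(config.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


def _decode(codes):
    from . import sequences as sq

    return sq.decode(codes)
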
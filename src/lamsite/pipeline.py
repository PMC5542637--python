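"""End-to-end pipeline orchestration.

Stages (simulate -> call -> map -> quantify -> test -> report) read and
write plain-text artifacts in an output directory, each alongside a JSON
manifest recording inputs, parameters and the seed, so any stage can be
re-run reproducibly.  The CLI in :mod:`lamsite.cli` is a thin wrapper
over these functions.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import pandas as pd

from . import clonality, io, junctions, mapping, simulate, stats
from .model import (
    DEFAULT_ENZYMES,
    CONCATEMER_KINDS,
    ConcatemerJunction,
    SimulationConfig,
)

STAGES = ("simulate", "call", "map", "quantify", "test", "report")


@dataclass
class PipelineConfig:
    """Flat configuration for every stage, parseable from key=value text."""

    # toy genome
    chrom_lengths: str = "1500000,500000"
    gc_content: float = 0.41
    n_genes: int = 120
    gene_length: int = 5000
    cancer_fraction: float = 0.3
    # simulation
    n_events: int = 200
    concatemer_fraction: float = 0.1
    abundance_model: str = "log-series"
    theta: float = 0.95
    error_rate: float = 0.002
    read_length: int = 150
    depth: int = 20000
    max_flank: int = 1000
    min_fragment: int = 20
    hotspot: str = ""  # "chrom:start:end:fraction" or empty
    # classification
    min_read_length: int = 36
    max_fraction_n: float = 0.05
    anchor_mismatches: int = 2
    k_vec: int = 12
    # mapping
    k: int = 16
    min_identity: float = 0.95
    min_aligned: int = 20
    score_margin: float = 5.0
    # clonality
    window_bp: int = 3
    sample_id: str = "sample1"
    time_point: str = "t0"
    dna_mass_ug: float = 0.0
    # statistics
    null_size: int = stats.DEFAULT_NULL_SIZE
    null_mode: str = "uniform"
    alpha: float = 0.05
    correction: str = "fdr_bh"
    # global
    seed: int = 42
    outdir: str = "lamsite_out"

    def lengths(self) -> list[int]:
        return [int(x) for x in self.chrom_lengths.split(",") if x]

    def hotspot_tuple(self) -> Optional[tuple[str, int, int, float]]:
        if not self.hotspot:
            return None
        chrom, s, e, f = self.hotspot.split(":")
        return (chrom, int(s), int(e), float(f))

    def science_parameters(self) -> dict:
        """All parameters that influence results (output location excluded)."""
        d = asdict(self)
        d.pop("outdir")
        return d

    def parameter_hash(self) -> str:
        payload = json.dumps(self.science_parameters(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Parse a key=value config file; unknown keys are errors."""
    known = {f.name: f.type for f in fields(PipelineConfig)}
    values: dict = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            values[key] = val
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = PipelineConfig()
    for key, val in values.items():
        current = getattr(cfg, key)
        if isinstance(current, bool):
            val = str(val).lower() in ("1", "true", "yes")
        elif isinstance(current, int):
            val = int(val)
        elif isinstance(current, float):
            val = float(val)
        setattr(cfg, key, val)
    return cfg


def _write_manifest(outdir: Path, stage: str, cfg: PipelineConfig, artifacts: list[str]) -> None:
    manifest = dict(
        stage=stage,
        seed=cfg.seed,
        parameter_hash=cfg.parameter_hash(),
        parameters=cfg.science_parameters(),
        artifacts=sorted(artifacts),
    )
    with open(outdir / f"manifest_{stage}.json", "w") as handle:
        json.dump(manifest, handle, indent=2, sort_keys=True)
        handle.write("\n")


def _require(outdir: Path, name: str, producer: str) -> Path:
    path = outdir / name
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {name!r}: run the {producer!r} stage first"
        )
    return path


def default_concatemers(
    events_abundance: float, fraction: float
) -> list[ConcatemerJunction]:
    """Concatemer junctions carrying ``fraction`` of total amplifiable
    abundance, split across the three junction kinds 60/20/20 (head-to-
    tail dominates episomal AAV multimers)."""
    if fraction <= 0:
        return []
    total = events_abundance * fraction / (1 - fraction)
    split = (0.6, 0.2, 0.2)
    return [
        ConcatemerJunction(kind=k, abundance=total * w)
        for k, w in zip(CONCATEMER_KINDS, split)
    ]


def stage_simulate(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lengths = cfg.lengths()
    genome, genes = simulate.make_toy_genome(
        n_chrom=len(lengths),
        lengths=lengths,
        gc_content=cfg.gc_content,
        n_genes=cfg.n_genes,
        gene_length=cfg.gene_length,
        cancer_fraction=cfg.cancer_fraction,
        seed=cfg.seed,
    )
    vector = simulate.default_vector()
    linker = simulate.DEFAULT_LINKER
    sim = SimulationConfig(
        n_events=cfg.n_events,
        hotspot=cfg.hotspot_tuple(),
        abundance_model=cfg.abundance_model,
        theta=cfg.theta,
        error_rate=cfg.error_rate,
        read_length=cfg.read_length,
        max_flank=cfg.max_flank,
        min_fragment=cfg.min_fragment,
        depth=cfg.depth,
        seed=cfg.seed,
    )
    events = simulate.plant_integrations(genome, sim)
    # base concatemer abundance on recoverable IS abundance so that
    # concatemer_fraction is the expected concatemer share of
    # vector-positive (IS + concatemer) reads
    recoverable = 0.0
    for ev in events:
        _, frag_len = simulate.event_amplicon(
            genome, ev, vector, linker, DEFAULT_ENZYMES, cfg.max_flank
        )
        if frag_len is not None and frag_len >= cfg.min_fragment:
            recoverable += ev.abundance
    concatemers = default_concatemers(recoverable, cfg.concatemer_fraction)
    reads, truth = simulate.lam_pcr_reads(
        events, concatemers, genome, vector, linker, DEFAULT_ENZYMES, sim
    )

    io.write_fasta(genome, outdir / "genome.fasta")
    io.write_fasta(
        type(genome)((("vector", vector.sequence),)), outdir / "vector.fasta"
    )
    io.write_bed(genes, outdir / "genes.bed")
    with open(outdir / "cancer_genes.txt", "w") as handle:
        for g in genes:
            if g.cancer_flag:
                handle.write(g.name + "\n")
    io.write_fastq(reads, outdir / "reads.fastq")
    io.write_tsv(truth, outdir / "truth.tsv")
    events_df = pd.DataFrame(
        [
            dict(chrom=e.chrom, pos=e.pos, orient=e.orient, abundance=e.abundance)
            for e in events
        ],
        columns=["chrom", "pos", "orient", "abundance"],
    )
    io.write_tsv(events_df, outdir / "planted_events.tsv")
    _write_manifest(
        outdir,
        "simulate",
        cfg,
        [
            "genome.fasta",
            "vector.fasta",
            "genes.bed",
            "cancer_genes.txt",
            "reads.fastq",
            "truth.tsv",
            "planted_events.tsv",
        ],
    )
    return outdir


def stage_call(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    reads = io.read_fastq(_require(outdir, "reads.fastq", "simulate"))
    vector = simulate.default_vector()
    linker = simulate.DEFAULT_LINKER
    retained, log = junctions.filter_quality(
        reads, cfg.min_read_length, cfg.max_fraction_n
    )
    params = junctions.ClassifyParams(
        max_mismatches=cfg.anchor_mismatches,
        k_vec=cfg.k_vec,
        min_fragment=cfg.min_fragment,
    )
    calls = junctions.classify_reads(retained, vector, linker, params)
    io.write_tsv(junctions.calls_to_frame(calls), outdir / "junction_calls.tsv")
    with open(outdir / "filter_log.json", "w") as handle:
        json.dump(log, handle, indent=2, sort_keys=True)
        handle.write("\n")
    with open(outdir / "is_fragments.fasta", "w") as handle:
        for c in calls:
            if c.category == "IS":
                handle.write(f">{c.read_id}\n{c.fragment}\n")
    _write_manifest(
        outdir, "call", cfg, ["junction_calls.tsv", "filter_log.json", "is_fragments.fasta"]
    )
    return outdir


def stage_map(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    genome = io.read_fasta(_require(outdir, "genome.fasta", "simulate"))
    calls_df = io.read_tsv(_require(outdir, "junction_calls.tsv", "call"))
    index = mapping.build_index(genome, cfg.k)
    params = mapping.MapParams(
        k=cfg.k,
        min_identity=cfg.min_identity,
        min_aligned=cfg.min_aligned,
        score_margin=cfg.score_margin,
    )
    from .model import JunctionCall

    calls = [
        JunctionCall(
            read_id=str(r.read_id),
            category=str(r.category),
            fragment=str(r.fragment) if isinstance(r.fragment, str) else "",
        )
        for r in calls_df.itertuples(index=False)
    ]
    mapped = mapping.map_junction_calls(calls, index, params)
    io.write_tsv(mapping.mapped_to_frame(mapped), outdir / "mapped_junctions.tsv")
    _write_manifest(outdir, "map", cfg, ["mapped_junctions.tsv"])
    return outdir


def _load_mapped(outdir: Path):
    from .model import MappedJunction

    df = io.read_tsv(_require(outdir, "mapped_junctions.tsv", "map"))
    out = []
    for r in df.itertuples(index=False):
        unmapped = r.status == "unmapped"
        out.append(
            MappedJunction(
                read_id=str(r.read_id),
                chrom=None if unmapped else str(r.chrom),
                pos=None if unmapped else int(r.pos),
                strand=None if unmapped else str(r.strand),
                score=float(r.score),
                n_best=int(r.n_best),
                status=str(r.status),
            )
        )
    return out


def stage_quantify(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    mapped = _load_mapped(outdir)
    calls_df = io.read_tsv(_require(outdir, "junction_calls.tsv", "call"))
    from .model import JunctionCall

    calls = [
        JunctionCall(read_id=str(r.read_id), category=str(r.category))
        for r in calls_df.itertuples(index=False)
    ]
    genes = io.read_annotation(
        _require(outdir, "genes.bed", "simulate"),
        "BED",
        cancer_list_path=outdir / "cancer_genes.txt",
    )
    sites = clonality.collapse_sites(mapped, cfg.window_bp)
    if sites:
        clonality.quantify(sites)
        clonality.annotate_nearest_gene(sites, genes)
    summary = clonality.summarize_sample(
        calls,
        mapped,
        sites,
        cfg.sample_id,
        cfg.time_point,
        cfg.dna_mass_ug or None,
    )
    io.write_tsv(clonality.sites_to_frame(sites), outdir / "sites.tsv")
    with open(outdir / "sites.bed", "w") as handle:
        for s in sites:
            handle.write(
                f"{s.chrom}\t{s.pos}\t{s.pos + 1}\tIS\t{s.read_count}\t{s.strand}\n"
            )
    io.write_tsv(pd.DataFrame([asdict(summary)]), outdir / "sample_summary.tsv")
    _write_manifest(
        outdir, "quantify", cfg, ["sites.tsv", "sites.bed", "sample_summary.tsv"]
    )
    return outdir


def stage_test(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    genome = io.read_fasta(_require(outdir, "genome.fasta", "simulate"))
    sites_df = io.read_tsv(_require(outdir, "sites.tsv", "quantify"))
    genes = io.read_annotation(
        _require(outdir, "genes.bed", "simulate"),
        "BED",
        cancer_list_path=outdir / "cancer_genes.txt",
    )
    from .model import IntegrationSite

    sites = [
        IntegrationSite(
            chrom=str(r.chrom),
            pos=int(r.pos),
            strand=str(r.strand),
            read_count=int(r.read_count),
        )
        for r in sites_df.itertuples(index=False)
    ]
    if not sites:
        raise ValueError("no sites to test: quantify produced an empty table")
    null = stats.random_null(
        genome,
        size=cfg.null_size,
        mode=cfg.null_mode,
        enzymes=DEFAULT_ENZYMES,
        seed=cfg.seed + 1,
    )
    hotspots = stats.chrom_hotspot_scan(sites, null, cfg.alpha, cfg.correction)
    sample_ctx = stats.gene_context([(s.chrom, s.pos) for s in sites], genes)
    null_ctx = stats.gene_context([(c, p) for c, p, _ in null.positions], genes)
    ctx_cmp = stats.compare_gene_context(sample_ctx, null_ctx, cfg.correction)
    enrich = stats.cancer_gene_enrichment(sites, genes, null)

    io.write_tsv(stats.enrichment_to_frame(hotspots), outdir / "hotspot_scan.tsv")
    sample_ctx["dataset"] = "sample"
    null_ctx["dataset"] = "null"
    io.write_tsv(
        pd.concat([sample_ctx, null_ctx], ignore_index=True),
        outdir / "gene_context.tsv",
    )
    io.write_tsv(stats.enrichment_to_frame(ctx_cmp), outdir / "gene_context_tests.tsv")
    io.write_tsv(
        stats.enrichment_to_frame([enrich]), outdir / "cancer_gene_enrichment.tsv"
    )
    null_df = pd.DataFrame(
        [dict(chrom=c, pos=p, strand=s) for c, p, s in null.positions],
        columns=["chrom", "pos", "strand"],
    )
    io.write_tsv(null_df, outdir / "null_dataset.tsv")
    _write_manifest(
        outdir,
        "test",
        cfg,
        [
            "hotspot_scan.tsv",
            "gene_context.tsv",
            "gene_context_tests.tsv",
            "cancer_gene_enrichment.tsv",
            "null_dataset.tsv",
        ],
    )
    return outdir


def stage_report(cfg: PipelineConfig) -> Path:
    outdir = Path(cfg.outdir)
    sites_df = io.read_tsv(_require(outdir, "sites.tsv", "quantify"))
    _require(outdir, "hotspot_scan.tsv", "test")
    top = sites_df.sort_values(
        ["read_count", "chrom", "pos"], ascending=[False, True, True]
    ).head(10)
    io.write_tsv(top.reset_index(drop=True), outdir / "report_top10_sites.tsv")

    # chromosomal distribution of sample vs null
    null_df = io.read_tsv(outdir / "null_dataset.tsv")
    sample_counts = sites_df["chrom"].value_counts().sort_index()
    null_counts = null_df["chrom"].value_counts().sort_index()
    chroms = sorted(set(sample_counts.index) | set(null_counts.index))
    dist = pd.DataFrame(
        dict(
            chrom=chroms,
            sample_sites=[int(sample_counts.get(c, 0)) for c in chroms],
            sample_fraction=[
                sample_counts.get(c, 0) / max(1, len(sites_df)) for c in chroms
            ],
            null_sites=[int(null_counts.get(c, 0)) for c in chroms],
            null_fraction=[
                null_counts.get(c, 0) / max(1, len(null_df)) for c in chroms
            ],
        )
    )
    io.write_tsv(dist, outdir / "report_chrom_distribution.tsv")
    _write_manifest(
        outdir,
        "report",
        cfg,
        ["report_top10_sites.tsv", "report_chrom_distribution.tsv"],
    )
    return outdir


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "call": stage_call,
    "map": stage_map,
    "quantify": stage_quantify,
    "test": stage_test,
    "report": stage_report,
}


def run(stage: str, cfg: PipelineConfig) -> Path:
    """Run one stage, or "all" to chain every stage in order."""
    if stage == "all":
        for name in STAGES:
            _STAGE_FUNCS[name](cfg)
        return Path(cfg.outdir)
    if stage not in _STAGE_FUNCS:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES + ('all',)}")
    return _STAGE_FUNCS[stage](cfg)
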
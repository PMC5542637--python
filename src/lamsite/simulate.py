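"""Ground-truthed LAM-PCR read simulation.

The simulator emulates the parts of the wet-lab protocol that are visible
in silico.  A LAM-PCR amplicon anchored at the vector terminus is

    vector anchor .. terminus | genomic flank truncated at the first
    MseI/MluCI cut | ligated linker

for an integration event, and

    vector anchor .. terminus | continuing vector sequence

for a vector-vector (concatemer) junction, with the continuation
orientation set by the junction kind.  Reads are the first ``read_length``
bases of the amplicon with i.i.d. substitution errors; clone sizes drive
a multinomial allocation of total depth across amplicons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import (
    ConcatemerJunction,
    GeneModel,
    IntegrationEvent,
    LinkerModel,
    ReferenceGenome,
    RestrictionEnzyme,
    SimulationConfig,
    VectorConstruct,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Shipped default linker (adaptor) sequence; real protocols use
#: proprietary adaptors, so this is a synthetic stand-in kept free of
#: MseI/MluCI sites and of any long match to the default vector anchor.
DEFAULT_LINKER = LinkerModel("GACCCGGGAGATCTGTCGACAGTGGCACAG")


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode()


def default_vector(seed: int = 20_240_101, length: int = 2400) -> VectorConstruct:
    """A synthetic stand-in for an scAAV expression cassette.

    The construct carries a 24-nt primer anchor ending at the sequenced
    terminus, so the amplicon prefix equals the anchor.  Any real construct
    sequence can be used instead.
    """
    rng = np.random.default_rng(seed)
    seq = _random_dna(rng, length)
    return VectorConstruct(
        sequence=seq, anchor=(length - 24, length), terminus_offset=length
    )


def make_toy_genome(
    n_chrom: int,
    lengths: Sequence[int],
    gc_content: float = 0.5,
    n_genes: int = 0,
    gene_length: int = 5000,
    cancer_fraction: float = 0.3,
    duplicated_segment: Optional[tuple[str, int, int, str, int]] = None,
    seed: int = 0,
) -> tuple[ReferenceGenome, list[GeneModel]]:
    """Generate a toy reference genome with non-overlapping gene spans.

    Bases are i.i.d. with the requested GC content.  ``duplicated_segment``
    = (src_chrom, start, end, dst_chrom, dst_start) copies a segment
    verbatim to a second locus, creating multi-mapping ground truth.
    A ``cancer_fraction`` of the genes (rounded down, at least one when
    n_genes > 0 and fraction > 0) is cancer-flagged.
    """
    if n_chrom != len(lengths):
        raise ValueError("n_chrom must match len(lengths)")
    if any(L <= 0 for L in lengths):
        raise ValueError("chromosome lengths must be positive")
    if not 0 < gc_content < 1:
        raise ValueError("gc_content must be in (0, 1)")

    rng = np.random.default_rng(seed)
    seqs = {
        f"chr{i + 1}": _random_dna(rng, L, gc_content)
        for i, L in enumerate(lengths)
    }

    if duplicated_segment is not None:
        src, s0, s1, dst, d0 = duplicated_segment
        segment = seqs[src][s0:s1]
        if d0 + len(segment) > len(seqs[dst]):
            raise ValueError("duplicated segment does not fit at destination")
        seqs[dst] = seqs[dst][:d0] + segment + seqs[dst][d0 + len(segment) :]

    genome = ReferenceGenome(tuple(seqs.items()))

    genes: list[GeneModel] = []
    if n_genes > 0:
        capacity = sum(max(0, L // (2 * gene_length)) for L in lengths)
        if n_genes > capacity:
            raise ValueError(
                f"cannot place {n_genes} non-overlapping genes of "
                f"{gene_length} bp; capacity is {capacity}"
            )
        # lay genes on a 2*gene_length grid, then subsample
        slots = []
        for name, seq in genome.records:
            for start in range(0, len(seq) - gene_length, 2 * gene_length):
                slots.append((name, start))
        chosen = rng.choice(len(slots), size=n_genes, replace=False)
        n_cancer = int(round(n_genes * cancer_fraction))
        if cancer_fraction > 0 and n_genes > 0:
            n_cancer = max(1, n_cancer)
        cancer_idx = set(rng.choice(n_genes, size=n_cancer, replace=False).tolist())
        for j, slot in enumerate(sorted(chosen.tolist())):
            chrom, start = slots[slot]
            genes.append(
                GeneModel(
                    chrom=chrom,
                    start=start,
                    end=start + gene_length,
                    strand="+" if rng.random() < 0.5 else "-",
                    name=f"gene{j + 1:04d}",
                    cancer_flag=j in cancer_idx,
                )
            )
    return genome, genes


def sample_abundances(
    rng: np.random.Generator, n: int, model: str, theta: float = 0.95
) -> np.ndarray:
    """Clone-size weights: uniform, or Fisher log-series (skewed clonality)."""
    if n == 0:
        return np.zeros(0)
    if model == "uniform":
        return np.ones(n)
    if model == "log-series":
        # inverse-CDF sampling of the log-series distribution
        u = rng.random(n)
        k = np.ones(n, dtype=int)
        norm = -1.0 / math.log(1.0 - theta)
        pmf = norm * theta
        cdf = np.full(n, pmf)
        active = cdf < u
        kk = 1
        while active.any() and kk < 100_000:
            kk += 1
            pmf = pmf * theta * (kk - 1) / kk
            cdf = cdf + np.where(active, pmf, 0.0)
            k = np.where(active, kk, k)
            active = cdf < u
        return k.astype(float)
    raise ValueError(f"unknown abundance model: {model}")


def plant_integrations(
    genome: ReferenceGenome, config: SimulationConfig
) -> list[IntegrationEvent]:
    """Plant integration events uniformly over the genome.

    With a hotspot (chrom, win_start, win_end, fraction), each event is
    independently placed uniformly inside the window with the stated
    probability, uniformly genome-wide otherwise.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_events == 0:
        return []

    lengths = genome.lengths
    names = genome.names
    cum = np.cumsum([lengths[n] for n in names])
    total = cum[-1]

    if config.hotspot is not None:
        h_chrom, h0, h1, frac = config.hotspot
        if h_chrom not in genome or h1 > lengths[h_chrom] or h0 < 0 or h0 >= h1:
            raise ValueError("hotspot window outside genome")
    else:
        frac = 0.0

    events = []
    in_hot = rng.random(config.n_events) < frac
    flat = rng.integers(0, total, size=config.n_events)
    strands = rng.random(config.n_events) < 0.5
    abund = sample_abundances(
        rng, config.n_events, config.abundance_model, config.theta
    )
    for i in range(config.n_events):
        if in_hot[i]:
            chrom = h_chrom
            pos = int(rng.integers(h0, h1))
        else:
            ci = int(np.searchsorted(cum, flat[i], side="right"))
            chrom = names[ci]
            pos = int(flat[i] - (cum[ci - 1] if ci else 0))
        events.append(
            IntegrationEvent(
                chrom=chrom,
                pos=pos,
                orient="+" if strands[i] else "-",
                abundance=float(abund[i]),
            )
        )
    return events


def truncate_at_enzyme(
    flank: str, enzymes: Sequence[RestrictionEnzyme], max_flank: int
) -> Optional[str]:
    """Truncate a genomic flank at the nearest restriction cut.

    Scans the first ``max_flank`` bases of the flank for the left-most
    recognition site of any provided enzyme and returns
    ``flank[:site_start + cut_offset]``; None when no site is present
    (the fragment would be lost to the protocol).
    """
    if not flank:
        raise ValueError("flank must be non-empty")
    window = flank[:max_flank]
    best: Optional[tuple[int, int]] = None  # (site_start, cut)
    for enz in enzymes:
        idx = window.find(enz.recognition)
        if idx >= 0 and (best is None or idx < best[0]):
            best = (idx, idx + enz.cut_offset)
    if best is None:
        return None
    return flank[: best[1]]


def _genomic_flank(genome: ReferenceGenome, ev: IntegrationEvent, span: int) -> str:
    seq = genome.sequence(ev.chrom)
    if ev.orient == "+":
        return seq[ev.pos : ev.pos + span]
    lo = max(0, ev.pos - span + 1)
    return revcomp(seq[lo : ev.pos + 1])


def event_amplicon(
    genome: ReferenceGenome,
    ev: IntegrationEvent,
    vector: VectorConstruct,
    linker: LinkerModel,
    enzymes: Sequence[RestrictionEnzyme],
    max_flank: int,
) -> tuple[str, Optional[int]]:
    """Build the amplicon for one event.

    Returns (amplicon, fragment_length); fragment_length is None when no
    enzyme site lies within ``max_flank`` — the event yields no product
    and is unrecoverable by the protocol.
    """
    flank = _genomic_flank(genome, ev, max_flank + 8)
    truncated = truncate_at_enzyme(flank, enzymes, max_flank)
    if truncated is None:
        return "", None
    return vector.amplicon_prefix + truncated + linker.sequence, len(truncated)


def concatemer_amplicon(
    cat: ConcatemerJunction, vector: VectorConstruct, read_length: int
) -> str:
    """Amplicon across a vector-vector junction.

    head-to-tail junctions continue into the next copy's start in the
    forward orientation; inverted junctions (head-to-head, tail-to-tail)
    continue into the reverse complement, i.e. reads re-enter the vector
    terminus backwards.  From the anchored end the two inverted kinds are
    indistinguishable.
    """
    if cat.kind == "head-to-tail":
        continuation = vector.sequence
    else:
        continuation = revcomp(vector.sequence)
    return (vector.amplicon_prefix + continuation)[: read_length + 8]


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < rate)[0]
    if len(hit) == 0:
        return seq
    # substitute with a uniformly chosen different base
    for i in hit:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def lam_pcr_reads(
    events: Sequence[IntegrationEvent],
    concatemers: Sequence[ConcatemerJunction],
    genome: ReferenceGenome,
    vector: VectorConstruct,
    linker: LinkerModel,
    enzymes: Sequence[RestrictionEnzyme],
    config: SimulationConfig,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate LAM-PCR reads and their ground-truth table.

    Reads are allocated to amplicons multinomially by abundance (events
    without an enzyme site within ``max_flank`` produce no product and
    receive no reads).  Each read is the first ``read_length`` bases of
    its amplicon with i.i.d. substitution errors; qualities are constant.

    Returns (reads as (id, seq, qual) triples, truth table).  Truth rows
    carry read_id, source_type (IS/concatemer), source index, chrom, pos,
    orient and the recoverability flag (enzyme site found AND retained
    genomic fragment >= min_fragment).
    """
    if len(vector.amplicon_prefix) > config.read_length:
        raise ValueError("vector amplicon prefix longer than read_length")
    linker.validate_against(vector)
    rng = np.random.default_rng(config.seed + 1)

    sources = []  # (amplicon, weight, truth-metadata)
    for i, ev in enumerate(events):
        if ev.chrom not in genome or ev.pos >= genome.lengths[ev.chrom]:
            raise ValueError(f"event {i} outside genome: {ev.chrom}:{ev.pos}")
        amplicon, frag_len = event_amplicon(
            genome, ev, vector, linker, enzymes, config.max_flank
        )
        recoverable = frag_len is not None and frag_len >= config.min_fragment
        weight = ev.abundance if frag_len is not None else 0.0
        sources.append(
            (
                amplicon,
                weight,
                dict(
                    source_type="IS",
                    source_index=i,
                    chrom=ev.chrom,
                    pos=ev.pos,
                    orient=ev.orient,
                    recoverable=recoverable,
                ),
            )
        )
    for j, cat in enumerate(concatemers):
        amplicon = concatemer_amplicon(cat, vector, config.read_length)
        sources.append(
            (
                amplicon,
                cat.abundance,
                dict(
                    source_type="concatemer",
                    source_index=j,
                    chrom="",
                    pos=-1,
                    orient="",
                    recoverable=False,
                ),
            )
        )

    weights = np.array([w for _, w, _ in sources], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("no amplifiable sources (all events unrecoverable)")
    counts = rng.multinomial(config.depth, weights / weights.sum())

    reads: list[tuple[str, str, str]] = []
    truth_rows = []
    rid = 0
    for (amplicon, _, meta), n in zip(sources, counts):
        template = amplicon[: config.read_length]
        for _ in range(int(n)):
            seq = _apply_errors(rng, template, config.error_rate)
            read_id = f"read{rid:07d}"
            reads.append((read_id, seq, "I" * len(seq)))
            truth_rows.append(dict(read_id=read_id, **meta))
            rid += 1

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "source_type",
            "source_index",
            "chrom",
            "pos",
            "orient",
            "recoverable",
        ],
    )
    return reads, truth
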
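"""Site collapsing, clonal quantification and per-sample composition.

Uniquely mapped junctions within a small window on the same chromosome
and strand collapse into one integration site; read counts per site are
the semiquantitative clone-size proxy, reported relative to all uniquely
mapped IS reads.  Multi-mapped reads are excluded from quantification.
"""

from __future__ import annotations

from collections import Counter
from typing import Optional, Sequence

import pandas as pd

from .model import (
    GeneModel,
    IntegrationSite,
    JunctionCall,
    MappedJunction,
    SampleSummary,
)


def collapse_sites(
    mapped: Sequence[MappedJunction], window_bp: int = 3, status: str = "unique"
) -> list[IntegrationSite]:
    """Collapse junctions of one mapping status into integration sites.

    Junctions on the same chromosome and strand chain-merge while
    consecutive (sorted) positions are within ``window_bp``.  Site
    position is the mode of member positions (smallest on ties); the
    read count is the member count.  By default only uniquely mapped
    junctions are collapsed; ``status="multi"`` collapses multi-mapped
    junctions at their best placement (used for site accounting only,
    never for clonal quantification).
    """
    uniques = [m for m in mapped if m.status == status and m.chrom is not None]
    by_key: dict[tuple[str, str], list[int]] = {}
    for m in uniques:
        by_key.setdefault((m.chrom, m.strand), []).append(m.pos)

    sites: list[IntegrationSite] = []
    for (chrom, strand), positions in sorted(by_key.items()):
        positions.sort()
        cluster: list[int] = []
        for pos in positions:
            if cluster and pos - cluster[-1] > window_bp:
                sites.append(_finish_cluster(chrom, strand, cluster))
                cluster = []
            cluster.append(pos)
        if cluster:
            sites.append(_finish_cluster(chrom, strand, cluster))
    sites.sort(key=lambda s: (s.chrom, s.pos, s.strand))
    return sites


def _finish_cluster(chrom: str, strand: str, members: list[int]) -> IntegrationSite:
    counts = Counter(members)
    top = max(counts.values())
    pos = min(p for p, c in counts.items() if c == top)
    return IntegrationSite(chrom=chrom, pos=pos, strand=strand, read_count=len(members))


def quantify(sites: Sequence[IntegrationSite]) -> list[IntegrationSite]:
    """Fill relative_count = read_count / total uniquely mapped IS reads."""
    if not sites:
        raise ValueError("no sites")
    total = sum(s.read_count for s in sites)
    for s in sites:
        s.relative_count = s.read_count / total
    return list(sites)


def top_n(sites: Sequence[IntegrationSite], n: int = 10) -> list[IntegrationSite]:
    """The n most prominent sites by read count (ties by chrom, pos)."""
    ranked = sorted(sites, key=lambda s: (-s.read_count, s.chrom, s.pos))
    return ranked[:n]


def annotate_nearest_gene(
    sites: Sequence[IntegrationSite], genes: Sequence[GeneModel]
) -> list[IntegrationSite]:
    """Attach nearest-gene name, signed distance and in-gene flag.

    Distance is 0 inside a gene span, positive downstream of the gene
    end, negative upstream of the gene start.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for s in sites:
        best: Optional[tuple[int, int, GeneModel]] = None
        for g in by_chrom.get(s.chrom, []):
            if g.start <= s.pos < g.end:
                d = 0
            elif s.pos >= g.end:
                d = s.pos - g.end + 1
            else:
                d = s.pos - g.start
            key = (abs(d), g.start)
            if best is None or key < (best[0], best[1]):
                best = (abs(d), g.start, g)
                signed = d
        if best is not None:
            s.nearest_gene = best[2].name
            s.distance_to_gene = signed
            s.in_gene = signed == 0
    return list(sites)


def summarize_sample(
    calls: Sequence[JunctionCall],
    mapped: Sequence[MappedJunction],
    sites: Sequence[IntegrationSite],
    sample_id: str,
    time_point: str = "",
    dna_mass_ug: Optional[float] = None,
) -> SampleSummary:
    """Per-sample composition in the shape of a per-biopsy IS table.

    pct_is and pct_concatemer are relative sequence counts with respect
    to vector-positive reads (IS + concatemer); with zero vector-positive
    reads both are None (undefined), never 0.
    """
    cat = Counter(c.category for c in calls)
    is_reads = cat.get("IS", 0)
    concat = cat.get("concatemer", 0)
    vp = is_reads + concat
    pct_is = 100.0 * is_reads / vp if vp else None
    pct_concat = 100.0 * concat / vp if vp else None

    n_unique_sites = len(sites)
    # multi-mapped fragments never enter quantification, but they are
    # still distinct ISs for the total/unique/multi site accounting
    n_multi_sites = len(collapse_sites(mapped, status="multi"))
    n_total = n_unique_sites + n_multi_sites

    return SampleSummary(
        sample_id=sample_id,
        time_point=time_point,
        total_is_reads=is_reads,
        concatemer_reads=concat,
        internal_reads=cat.get("internal", 0),
        unclassified_reads=cat.get("unclassified", 0),
        n_sites_total=n_total,
        n_sites_unique=n_unique_sites,
        n_sites_multi=n_multi_sites,
        pct_is=pct_is,
        pct_concatemer=pct_concat,
        is_per_ug=(n_total / dna_mass_ug) if dna_mass_ug else None,
    )


def serial_persistence(
    site_sets: dict[str, Sequence[IntegrationSite]], window_bp: int = 3
) -> pd.DataFrame:
    """Track site recurrence across serial samples (time points).

    For every distinct site observed at any time point, lists the time
    points at which a site within ``window_bp`` (same chromosome and
    strand) appears.  Persistent sites are those seen at >= 2 points.
    """
    if len(site_sets) < 2:
        raise ValueError(">=2 time points required")
    time_points = list(site_sets.keys())

    # canonical site list: union, collapsed across time points
    all_sites: list[tuple[str, int, str]] = []
    for tp in time_points:
        all_sites.extend((s.chrom, s.pos, s.strand) for s in site_sets[tp])
    all_sites = sorted(set(all_sites))

    rows = []
    for chrom, pos, strand in all_sites:
        seen = [
            tp
            for tp in time_points
            if any(
                s.chrom == chrom and s.strand == strand and abs(s.pos - pos) <= window_bp
                for s in site_sets[tp]
            )
        ]
        rows.append(
            dict(
                chrom=chrom,
                pos=pos,
                strand=strand,
                n_time_points=len(seen),
                time_points=",".join(seen),
                persistent=len(seen) >= 2,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "n_time_points", "time_points", "persistent"],
    )


def sites_to_frame(sites: Sequence[IntegrationSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                chrom=s.chrom,
                pos=s.pos,
                strand=s.strand,
                read_count=s.read_count,
                relative_count=s.relative_count,
                nearest_gene=s.nearest_gene or "",
                distance_to_gene=s.distance_to_gene
                if s.distance_to_gene is not None
                else "",
                in_gene=s.in_gene,
            )
            for s in sites
        ],
        columns=[
            "chrom",
            "pos",
            "strand",
            "read_count",
            "relative_count",
            "nearest_gene",
            "distance_to_gene",
            "in_gene",
        ],
    )
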
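"""Synthetic random controls and comparative integration statistics.

The genotoxicity questions are comparative: do observed integration
sites concentrate on particular chromosomes (hotspots), near genes, or
in cancer-associated genes, beyond what a random-placement null shows?
The null is a computer-generated dataset of random genomic positions —
uniform over the genome, or restricted to restriction-enzyme cut loci to
model the recovery bias of restriction-based LAM-PCR.  Comparisons use
Fisher's exact test on 2x2 count tables with Benjamini-Hochberg control
across chromosomes or distance bins.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .model import (
    EnrichmentResult,
    GeneModel,
    IntegrationSite,
    NullDataset,
    ReferenceGenome,
    RestrictionEnzyme,
)

#: Null-dataset size used for the comparison distribution.
DEFAULT_NULL_SIZE = 8628

DEFAULT_BIN_EDGES = (10_000, 100_000)
BIN_LABELS = ("in_gene", "le_10kb", "10_100kb", "gt_100kb")


def enzyme_cut_positions(
    genome: ReferenceGenome, enzymes: Sequence[RestrictionEnzyme]
) -> list[tuple[str, int]]:
    """All plus-strand cut positions of the given enzymes.

    Both LAM-PCR enzymes (MseI T^TAA, MluCI ^AATT) have palindromic
    recognition words, so a plus-strand scan covers both strands.
    """
    out = []
    for name, seq in genome.records:
        for enz in enzymes:
            start = seq.find(enz.recognition)
            while start >= 0:
                out.append((name, start + enz.cut_offset))
                start = seq.find(enz.recognition, start + 1)
    out.sort()
    return out


def random_null(
    genome: ReferenceGenome,
    size: int = DEFAULT_NULL_SIZE,
    mode: str = "uniform",
    enzymes: Optional[Sequence[RestrictionEnzyme]] = None,
    seed: int = 0,
) -> NullDataset:
    """Generate a synthetic random integration dataset.

    ``uniform`` samples positions uniformly over the concatenated genome;
    ``site_matched`` samples uniformly among all enzyme cut positions,
    modelling the restriction-based recovery bias.  Strands are assigned
    by fair coin; all downstream tests ignore strand.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    rng = np.random.default_rng(seed)
    names = genome.names
    if mode == "uniform":
        lengths = np.array([genome.lengths[n] for n in names], dtype=np.int64)
        cum = np.cumsum(lengths)
        flat = rng.integers(0, cum[-1], size=size)
        ci = np.searchsorted(cum, flat, side="right")
        offs = flat - np.concatenate(([0], cum[:-1]))[ci]
        positions = [(names[int(c)], int(o)) for c, o in zip(ci, offs)]
    elif mode == "site_matched":
        if not enzymes:
            raise ValueError("site_matched mode requires enzymes")
        cuts = enzyme_cut_positions(genome, enzymes)
        if not cuts:
            raise ValueError("no enzyme cut sites in genome")
        idx = rng.integers(0, len(cuts), size=size)
        positions = [cuts[int(i)] for i in idx]
    else:
        raise ValueError("mode must be 'uniform' or 'site_matched'")
    strands = rng.random(size) < 0.5
    return NullDataset(
        positions=tuple(
            (c, p, "+" if s else "-") for (c, p), s in zip(positions, strands)
        ),
        mode=mode,
        seed=seed,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table: (odds_ratio, two-sided p).

    The two-sided p sums hypergeometric probabilities, at fixed margins,
    of all tables no more probable than the observed one (with a small
    relative tolerance against floating-point ties).  The odds ratio is
    the sample (a*d)/(b*c); 0/0 yields NaN, x/0 yields inf.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")

    ad, bc = a * d, b * c
    if bc == 0:
        odds = math.nan if ad == 0 else math.inf
    else:
        odds = ad / bc

    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    if n <= 2000:
        # exact integer arithmetic: table probabilities share the
        # denominator C(n, c1), so "no more probable than observed" is an
        # exact comparison of integer numerators — no floating-point ties
        nums = [
            math.comb(r1, k) * math.comb(n - r1, c1 - k) for k in range(lo, hi + 1)
        ]
        obs = nums[a - lo]
        total = sum(v for v in nums if v <= obs)
        p = float(Fraction(total, math.comb(n, c1)))
    else:
        support = np.arange(lo, hi + 1)
        pmf = sps.hypergeom.pmf(support, n, c1, r1)
        p_obs = pmf[a - lo]
        p = float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
    return odds, min(p, 1.0)


def _bh_adjust(results: list[EnrichmentResult], method: str = "fdr_bh") -> None:
    if not results:
        return
    if method == "none":
        for r in results:
            r.q = r.p_two_sided
        return
    pvals = [r.p_two_sided for r in results]
    _, qvals, _, _ = multipletests(pvals, method=method)
    for r, q in zip(results, qvals):
        r.q = float(q)


def chrom_hotspot_scan(
    sites: Sequence[IntegrationSite],
    null: NullDataset,
    alpha: float = 0.05,
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Per-chromosome integration-frequency comparison against the null.

    For each chromosome the 2x2 table is (sample on/off chromosome vs
    null on/off); q-values control the FDR across chromosomes
    (``correction`` in none / bonferroni / fdr_bh).  A chromosome is a
    hotspot when q < alpha.
    """
    if not sites:
        raise ValueError("empty site list")
    n_s = len(sites)
    n_0 = null.size
    chroms = sorted(
        {s.chrom for s in sites} | {c for c, _, _ in null.positions}
    )
    results = []
    for chrom in chroms:
        a = sum(1 for s in sites if s.chrom == chrom)
        c = sum(1 for ch, _, _ in null.positions if ch == chrom)
        odds, p = fisher_exact([[a, n_s - a], [c, n_0 - c]])
        results.append(
            EnrichmentResult(
                label=chrom,
                counts=(a, n_s - a, c, n_0 - c),
                odds_ratio=odds,
                p_two_sided=p,
            )
        )
    _bh_adjust(results, correction)
    return results


def _gene_distance(
    pos: int, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Distance from pos to the nearest gene span (0 if inside).

    ``starts``/``ends`` are sorted, non-overlapping spans on the
    position's chromosome.
    """
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    best = None
    if i >= 0:
        if pos < ends[i]:
            return 0
        best = pos - int(ends[i]) + 1
    if i + 1 < len(starts):
        d = int(starts[i + 1]) - pos
        best = d if best is None else min(best, d)
    return best if best is not None else -1


def gene_context(
    positions: Sequence[tuple[str, int]],
    genes: Sequence[GeneModel],
    bin_edges: Sequence[int] = DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Distribution of positions over gene-distance bins.

    Default bins: inside a gene, within 10 kb, 10-100 kb, beyond 100 kb.
    With no genes every position lands in the farthest bin.  Fractions
    sum to 1.
    """
    labels = _bin_labels(bin_edges)
    counts = dict.fromkeys(labels, 0)

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {g.chrom for g in genes}:
        spans = sorted(
            (g.start, g.end) for g in genes if g.chrom == chrom
        )
        by_chrom[chrom] = (
            np.array([s for s, _ in spans]),
            np.array([e for _, e in spans]),
        )

    for chrom, pos in positions:
        if chrom not in by_chrom:
            counts[labels[-1]] += 1
            continue
        d = _gene_distance(pos, *by_chrom[chrom])
        if d < 0:
            counts[labels[-1]] += 1
        elif d == 0:
            counts[labels[0]] += 1
        else:
            for edge, label in zip(bin_edges, labels[1:-1]):
                if d <= edge:
                    counts[label] += 1
                    break
            else:
                counts[labels[-1]] += 1

    total = max(1, len(positions))
    return pd.DataFrame(
        dict(
            bin=list(counts.keys()),
            count=list(counts.values()),
            fraction=[v / total for v in counts.values()],
        )
    )


def _bin_labels(bin_edges: Sequence[int]) -> list[str]:
    if tuple(bin_edges) == DEFAULT_BIN_EDGES:
        return list(BIN_LABELS)
    labels = ["in_gene"]
    prev = 0
    for e in bin_edges:
        labels.append(f"{prev}_{e}bp" if prev else f"le_{e}bp")
        prev = e
    labels.append(f"gt_{prev}bp")
    return labels


def compare_gene_context(
    sample_dist: pd.DataFrame,
    null_dist: pd.DataFrame,
    correction: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Per-bin Fisher comparison of two gene-context distributions."""
    n_s = int(sample_dist["count"].sum())
    n_0 = int(null_dist["count"].sum())
    results = []
    for (_, srow), (_, nrow) in zip(sample_dist.iterrows(), null_dist.iterrows()):
        a, c = int(srow["count"]), int(nrow["count"])
        odds, p = fisher_exact([[a, n_s - a], [c, n_0 - c]])
        results.append(
            EnrichmentResult(
                label=str(srow["bin"]),
                counts=(a, n_s - a, c, n_0 - c),
                odds_ratio=odds,
                p_two_sided=p,
            )
        )
    _bh_adjust(results, correction)
    return results


def positions_in_cancer_genes(
    positions: Sequence[tuple[str, int]], genes: Sequence[GeneModel]
) -> int:
    """Count positions falling inside cancer-flagged gene spans."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        if g.cancer_flag:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    n = 0
    for chrom, pos in positions:
        for s, e in by_chrom.get(chrom, []):
            if s <= pos < e:
                n += 1
                break
    return n


def cancer_gene_enrichment(
    sites: Sequence[IntegrationSite],
    genes: Sequence[GeneModel],
    null: NullDataset,
) -> EnrichmentResult:
    """Cancer-gene integration fraction: sample vs random null.

    The 2x2 table counts positions inside cancer-flagged gene spans for
    the observed sites and for the null dataset; Fisher's exact test
    decides whether the observed fraction differs from random.
    """
    if not any(g.cancer_flag for g in genes):
        raise ValueError("no cancer-flagged genes in annotation")
    s_pos = [(s.chrom, s.pos) for s in sites]
    n_pos = [(c, p) for c, p, _ in null.positions]
    a = positions_in_cancer_genes(s_pos, genes)
    c = positions_in_cancer_genes(n_pos, genes)
    odds, p = fisher_exact([[a, len(s_pos) - a], [c, len(n_pos) - c]])
    return EnrichmentResult(
        label="cancer_genes",
        counts=(a, len(s_pos) - a, c, len(n_pos) - c),
        odds_ratio=odds,
        p_two_sided=p,
        q=p,
    )


def enrichment_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                label=r.label,
                sample_in=r.counts[0],
                sample_out=r.counts[1],
                null_in=r.counts[2],
                null_out=r.counts[3],
                odds_ratio=r.odds_ratio,
                p_two_sided=r.p_two_sided,
                q=r.q,
                significant=r.q < 0.05,
            )
            for r in results
        ],
        columns=[
            "label",
            "sample_in",
            "sample_out",
            "null_in",
            "null_out",
            "odds_ratio",
            "p_two_sided",
            "q",
            "significant",
        ],
    )
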
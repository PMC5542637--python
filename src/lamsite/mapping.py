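"""Seed-and-extend fragment mapping and unique/multi resolution.

A desk-scale aligner for short junction fragments: exact k-mer seeds on
both strands (2-bit-packed, sorted-array lookup), ungapped extension over
the full fragment, identity-scored hits, and a score-margin rule
separating uniquely mappable fragments from multi-locus ones.  Fragments
needing gapped alignment count as unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import JunctionCall, MappedJunction, ReferenceGenome, revcomp

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A=0,C=1,G=2,T=3, other=-1)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Packed 2-bit k-mer codes for every window, plus a validity mask."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.uint64), np.zeros(0, dtype=bool)
    out = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        col = codes[j : j + n]
        valid &= col >= 0
        out = (out << np.uint64(2)) | col.astype(np.uint64)
    return out, valid


@dataclass(frozen=True)
class Hit:
    """One candidate placement of a fragment."""

    chrom: str
    start: int  # reference start of the aligned span (plus-strand coords)
    strand: str
    identity: float
    aligned: int

    @property
    def score(self) -> float:
        return self.identity * self.aligned

    @property
    def junction_pos(self) -> int:
        """Reference coordinate of the junction-adjacent fragment base.

        For minus-strand placements this is the last base of the aligned
        span, so plus/minus recoveries of the same event collapse.
        """
        return self.start if self.strand == "+" else self.start + self.aligned - 1


@dataclass
class MapParams:
    k: int = 16
    min_identity: float = 0.95
    min_aligned: int = 20
    score_margin: float = 5.0


class KmerIndex:
    """Exact k-mer -> positions table over both genome strands.

    Plus-strand entries record each window's start on the reference; the
    minus strand is covered by indexing each window's reverse complement
    at the same reference start.  Windows containing N are skipped.
    """

    def __init__(self, genome: ReferenceGenome, k: int) -> None:
        if k < 11:
            raise ValueError("k must be >= 11")
        if k > 31:
            raise ValueError("k must be <= 31 (2-bit packing)")
        shortest = min(genome.lengths.values())
        if k > shortest:
            raise ValueError(f"k={k} exceeds shortest chromosome length {shortest}")
        self.k = k
        self.genome = genome
        self._chrom_names = genome.names

        code_parts, chrom_parts, pos_parts, strand_parts = [], [], [], []
        for ci, (name, seq) in enumerate(genome.records):
            L = len(seq)
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                kc, valid = _kmer_codes(_encode(s), k)
                idx = np.nonzero(valid)[0]
                code_parts.append(kc[idx])
                chrom_parts.append(np.full(len(idx), ci, dtype=np.int32))
                if strand == "+":
                    pos_parts.append(idx.astype(np.int64))
                else:
                    pos_parts.append((L - k - idx).astype(np.int64))
                strand_parts.append(
                    np.full(len(idx), 0 if strand == "+" else 1, dtype=np.int8)
                )
        codes = np.concatenate(code_parts)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._chrom = np.concatenate(chrom_parts)[order]
        self._pos = np.concatenate(pos_parts)[order]
        self._strand = np.concatenate(strand_parts)[order]

    def _range(self, code: np.uint64) -> tuple[int, int]:
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        return lo, hi

    def lookup(self, word: str) -> list[tuple[str, int, str]]:
        """All (chrom, pos, strand) occurrences of an exact k-mer."""
        kc, valid = _kmer_codes(_encode(word), self.k)
        if len(kc) != 1 or not valid[0]:
            return []
        lo, hi = self._range(kc[0])
        return [
            (
                self._chrom_names[self._chrom[i]],
                int(self._pos[i]),
                "+" if self._strand[i] == 0 else "-",
            )
            for i in range(lo, hi)
        ]


def build_index(genome: ReferenceGenome, k: int = 16) -> KmerIndex:
    return KmerIndex(genome, k)


def _extend(fragment: str, chrom_seq: str, start: int) -> Optional[tuple[int, float, int]]:
    """Ungapped comparison of fragment vs reference at start.

    Returns (clipped_start, identity, aligned_length); None if the
    placement falls entirely off the chromosome.
    """
    m = len(fragment)
    lo = max(0, start)
    hi = min(len(chrom_seq), start + m)
    if hi <= lo:
        return None
    ref = chrom_seq[lo:hi]
    frag = fragment[lo - start : hi - start]
    matches = sum(1 for a, b in zip(frag, ref) if a == b)
    return lo, matches / len(ref), len(ref)


def map_fragment(
    fragment: str,
    index: KmerIndex,
    params: Optional[MapParams] = None,
) -> list[Hit]:
    """Map one fragment: k-mer seeds, ungapped extension, scored hits.

    Hits require identity >= min_identity over >= min_aligned bases and
    are sorted by score descending, ties broken by (chrom, pos, strand).
    """
    params = params or MapParams()
    k = index.k
    m = len(fragment)
    if m < k:
        return []

    kc, valid = _kmer_codes(_encode(fragment), k)
    offs = np.nonzero(valid)[0]
    los = np.searchsorted(index._codes, kc[offs], side="left")
    his = np.searchsorted(index._codes, kc[offs], side="right")
    candidates: set[tuple[int, int, int]] = set()  # (chrom_idx, start, strand)
    for off, lo, hi in zip(offs, los, his):
        for i in range(int(lo), int(hi)):
            ci = int(index._chrom[i])
            pos = int(index._pos[i])
            if index._strand[i] == 0:
                candidates.add((ci, pos - int(off), 0))
            else:
                # fragment k-mer hits a revcomp window at reference pos:
                # rc(fragment) aligns forward, this k-mer sits at rc-offset
                # m - k - off
                candidates.add((ci, pos - (m - k - int(off)), 1))

    genome = index.genome
    rc_fragment = revcomp(fragment)
    hits: list[Hit] = []
    for ci, start, strand in candidates:
        chrom = index._chrom_names[ci]
        seq = genome.sequence(chrom)
        probe = fragment if strand == 0 else rc_fragment
        ext = _extend(probe, seq, start)
        if ext is None:
            continue
        clipped_start, identity, aligned = ext
        if identity >= params.min_identity and aligned >= params.min_aligned:
            hits.append(
                Hit(chrom, clipped_start, "+" if strand == 0 else "-", identity, aligned)
            )
    hits.sort(key=lambda h: (-h.score, h.chrom, h.start, h.strand))
    return hits


def resolve_uniqueness(
    read_id: str, hits: Sequence[Hit], score_margin: float = 5.0
) -> MappedJunction:
    """Turn a sorted hit list into a unique/multi/unmapped junction.

    A fragment is uniquely mappable when its best hit beats the runner-up
    by at least ``score_margin``; otherwise every hit within the margin
    of the best is a co-optimal locus.
    """
    if not hits:
        return MappedJunction(
            read_id=read_id,
            chrom=None,
            pos=None,
            strand=None,
            score=0.0,
            n_best=0,
            status="unmapped",
        )
    best = hits[0]
    n_best = sum(1 for h in hits if best.score - h.score < score_margin)
    status = "unique" if n_best == 1 else "multi"
    return MappedJunction(
        read_id=read_id,
        chrom=best.chrom,
        pos=best.junction_pos,
        strand=best.strand,
        score=best.score,
        n_best=n_best,
        status=status,
    )


def map_junction_calls(
    calls: Sequence[JunctionCall],
    index: KmerIndex,
    params: Optional[MapParams] = None,
) -> list[MappedJunction]:
    """Map the IS fragments of a call set (identical fragments cached)."""
    params = params or MapParams()
    cache: dict[str, list[Hit]] = {}
    out = []
    for call in calls:
        if call.category != "IS":
            continue
        if call.fragment not in cache:
            cache[call.fragment] = map_fragment(call.fragment, index, params)
        out.append(
            resolve_uniqueness(call.read_id, cache[call.fragment], params.score_margin)
        )
    return out


def mapped_to_frame(mapped: Sequence[MappedJunction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                read_id=m.read_id,
                chrom=m.chrom if m.chrom is not None else "",
                pos=m.pos if m.pos is not None else -1,
                strand=m.strand if m.strand is not None else "",
                score=m.score,
                n_best=m.n_best,
                status=m.status,
            )
            for m in mapped
        ],
        columns=["read_id", "chrom", "pos", "strand", "score", "n_best", "status"],
    )
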
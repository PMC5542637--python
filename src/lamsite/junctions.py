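"""Per-read quality filtering, vector trimming and junction classification.

Every quality-passing read falls in exactly one category:

* ``unclassified`` — no vector anchor at the 5' end;
* ``concatemer``   — vector sequence (either orientation) continues past
  the vector terminus: a vector-vector junction from an episomal multimer;
* ``IS``           — a genomic fragment of mappable length follows the
  terminus: a candidate vector-genome junction;
* ``internal``     — vector-positive but the post-vector part is too short
  to map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import JunctionCall, LinkerModel, VectorConstruct, revcomp


@dataclass
class ClassifyParams:
    """Tunables of the read classifier.

    k_vec
        Number of post-terminus bases that must match the vector (either
        strand) to call a concatemer; shorter matches collide with random
        genome at toy-genome scales.
    min_fragment
        Minimum genomic fragment length for an IS call; shorter fragments
        are unmappable and become ``internal``.
    """

    max_mismatches: int = 2
    k_vec: int = 12
    # exact 12-mer matching: a 1-mismatch budget would put ~1% of random
    # genomic flanks inside the vector k-mer neighbourhood; an erroneous
    # concatemer read that misses the exact probe falls through to IS but
    # its vector-derived fragment cannot map to the genome
    k_vec_mismatches: int = 0
    linker_prefix: int = 10
    linker_mismatches: int = 1
    min_fragment: int = 20


def filter_quality(
    reads: Iterable[tuple[str, str, str]],
    min_length: int = 36,
    max_fraction_n: float = 0.05,
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Retain reads of sufficient length and acceptable N content.

    Returns (retained reads, rejection log keyed by reason).  A read
    failing both criteria is logged once, as ``short``.
    """
    retained = []
    log = {"short": 0, "n_rich": 0}
    for read in reads:
        _, seq, _ = read
        if len(seq) < min_length:
            log["short"] += 1
        elif seq.count("N") > max_fraction_n * len(seq):
            log["n_rich"] += 1
        else:
            retained.append(read)
    return retained, log


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, capped at limit+1."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def find_vector_anchor(
    read_seq: str, anchor: str, max_mismatches: int = 2, max_shift: int = 0
) -> Optional[tuple[int, int, int]]:
    """Locate the vector anchor at the read 5' end.

    Scans start offsets 0..max_shift and returns (start, end, mismatches)
    for the best (fewest-mismatch, left-most) qualifying occurrence, or
    None.  The default ``max_shift=0`` requires the anchor to begin the
    read, as LAM-PCR amplicons do.
    """
    if len(anchor) > len(read_seq):
        return None
    best: Optional[tuple[int, int, int]] = None
    for off in range(max_shift + 1):
        if off + len(anchor) > len(read_seq):
            break
        d = _hamming(read_seq[off : off + len(anchor)], anchor, max_mismatches)
        if d <= max_mismatches and (best is None or d < best[2]):
            best = (off, off + len(anchor), d)
            if d == 0:
                break
    return best


def _kmer_neighbors(word: str, budget: int) -> set[str]:
    out = {word}
    if budget >= 1:
        for i in range(len(word)):
            for b in "ACGT":
                if b != word[i]:
                    out.add(word[: i] + b + word[i + 1 :])
    return out


class VectorKmerSet:
    """Exact k-mer membership over both strands of the vector sequence."""

    def __init__(self, vector: VectorConstruct, k: int) -> None:
        self.k = k
        seq = vector.sequence
        rc = revcomp(seq)
        self.words = {
            s[i : i + k] for s in (seq, rc) for i in range(len(s) - k + 1)
        }

    def contains(self, word: str, mismatches: int = 0) -> bool:
        if len(word) != self.k:
            return False
        if mismatches == 0:
            return word in self.words
        return any(w in self.words for w in _kmer_neighbors(word, mismatches))


def _find_linker(seq: str, linker: str, prefix: int, mismatches: int) -> int:
    """Left-most start of the linker prefix in seq (with mismatch budget);
    -1 if absent or seq shorter than the prefix."""
    probe = linker[:prefix]
    if len(seq) < len(probe):
        return -1
    for i in range(len(seq) - len(probe) + 1):
        if _hamming(seq[i : i + len(probe)], probe, mismatches) <= mismatches:
            return i
    return -1


def classify_read(
    read: tuple[str, str, str],
    vector: VectorConstruct,
    linker: LinkerModel,
    params: ClassifyParams,
    kmers: Optional[VectorKmerSet] = None,
) -> JunctionCall:
    """Classify one quality-passing read.

    The read is anchored on the vector amplicon prefix (primer anchor
    through the vector terminus).  Past the terminus: continuing vector
    sequence means concatemer; otherwise the linker is trimmed from the
    3' end and the remaining genomic fragment decides IS versus internal.
    A missing linker is allowed for IS calls — the read may simply have
    ended inside the genomic flank before the restriction cut.
    """
    read_id, seq, _ = read
    if kmers is None:
        kmers = VectorKmerSet(vector, params.k_vec)

    hit = find_vector_anchor(seq, vector.amplicon_prefix, params.max_mismatches)
    if hit is None:
        return JunctionCall(read_id=read_id, category="unclassified")
    anchor_end = hit[1]
    rest = seq[anchor_end:]

    probe = rest[: params.k_vec]
    if len(probe) == params.k_vec and kmers.contains(
        probe, params.k_vec_mismatches
    ):
        return JunctionCall(
            read_id=read_id, category="concatemer", anchor_end=anchor_end
        )

    linker_at = _find_linker(
        rest, linker.sequence, params.linker_prefix, params.linker_mismatches
    )
    fragment = rest[:linker_at] if linker_at >= 0 else rest
    if len(fragment) >= params.min_fragment:
        return JunctionCall(
            read_id=read_id,
            category="IS",
            fragment=fragment,
            anchor_end=anchor_end,
            linker_found=linker_at >= 0,
        )
    return JunctionCall(
        read_id=read_id,
        category="internal",
        anchor_end=anchor_end,
        linker_found=linker_at >= 0,
    )


def classify_reads(
    reads: Sequence[tuple[str, str, str]],
    vector: VectorConstruct,
    linker: LinkerModel,
    params: Optional[ClassifyParams] = None,
) -> list[JunctionCall]:
    """Classify a batch of reads (shared vector k-mer set)."""
    params = params or ClassifyParams()
    kmers = VectorKmerSet(vector, params.k_vec)
    return [classify_read(r, vector, linker, params, kmers) for r in reads]


def calls_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                read_id=c.read_id,
                category=c.category,
                fragment=c.fragment,
                anchor_end=c.anchor_end,
                linker_found=c.linker_found,
            )
            for c in calls
        ],
        columns=["read_id", "category", "fragment", "anchor_end", "linker_found"],
    )
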
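"""Core domain types for LAM-PCR integration-site analysis.

All genomic coordinates are 0-based, half-open.  The strand of an
integration site is the orientation of the genomic flank relative to the
reference plus strand: ``+`` means the flank continues downstream
(increasing coordinates) of the junction base, ``-`` means it continues
upstream on the reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")

#: picograms of genomic DNA per diploid cell, used for vector-copy-number
#: normalisation (qPCR copies -> copies per cell).
PG_DNA_PER_DIPLOID_CELL = 6.6


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N, case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ReferenceGenome:
    """An in-memory reference genome: ordered named chromosome sequences."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.records]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate record names: {', '.join(dupes)}")
        total = 0
        for name, seq in self.records:
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(
                    f"record {name!r} contains non-DNA characters: {sorted(bad)}"
                )
            total += len(seq)
        if total == 0:
            raise FormatError("genome has zero total length")

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.records]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.records)

    def sequence(self, chrom: str) -> str:
        for name, seq in self.records:
            if name == chrom:
                return seq
        raise KeyError(chrom)

    def __contains__(self, chrom: str) -> bool:
        return any(name == chrom for name, _ in self.records)


@dataclass(frozen=True)
class GeneModel:
    """A gene span with an optional cancer-association flag.

    ``cancer_flag`` generalises membership in curated cancer-gene lists
    (e.g. Cancer Gene Census / cBio / retroviral-tagged cancer gene
    databases) to a user-supplied name list.
    """

    chrom: str
    start: int
    end: int
    strand: str
    name: str
    cancer_flag: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.name!r}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.name!r}: strand must be + or -")


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme as recognition word plus cut offset.

    ``cut_offset`` is the number of bases from the start of the
    recognition word to the cut position on the top strand.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"enzyme {self.name!r}: empty recognition site")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside "
                f"recognition word of length {len(self.recognition)}"
            )


#: The two 4-cutters used to truncate LAM-PCR amplicons: MseI cuts T^TAA,
#: MluCI cuts ^AATT.
MSEI = RestrictionEnzyme("MseI", "TTAA", 1)
MLUCI = RestrictionEnzyme("MluCI", "AATT", 0)
DEFAULT_ENZYMES = (MSEI, MLUCI)


@dataclass(frozen=True)
class VectorConstruct:
    """The proviral vector sequence with LAM-PCR landmarks.

    anchor
        (start, end) span of the vector-specific primer-proximal segment
        expected at read 5' ends.  Must be at least 15 nt.
    terminus_offset
        Position in the vector sequence at which genomic (or next vector
        copy) sequence begins in an amplicon; normally the end of the
        sequenced ITR.
    """

    sequence: str
    anchor: tuple[int, int]
    terminus_offset: int

    def __post_init__(self) -> None:
        a0, a1 = self.anchor
        if not (0 <= a0 < a1 <= len(self.sequence)):
            raise ValueError("anchor span outside vector sequence")
        if a1 - a0 < 15:
            raise ValueError("vector anchor must be >= 15 nt")
        if not (0 <= self.terminus_offset <= len(self.sequence)):
            raise ValueError("terminus_offset outside vector sequence")

    @property
    def anchor_seq(self) -> str:
        return self.sequence[self.anchor[0] : self.anchor[1]]

    @property
    def amplicon_prefix(self) -> str:
        """Vector bases appearing 5' of the junction in every amplicon."""
        return self.sequence[self.anchor[0] : self.terminus_offset]


def _longest_shared_substring(a: str, b: str, threshold: int) -> bool:
    """True if a and b share an exact substring of >= threshold nt."""
    if len(a) < threshold or len(b) < threshold:
        return False
    words = {a[i : i + threshold] for i in range(len(a) - threshold + 1)}
    return any(b[i : i + threshold] in words for i in range(len(b) - threshold + 1))


@dataclass(frozen=True)
class LinkerModel:
    """The ligated adaptor appearing at amplicon 3' ends."""

    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("linker sequence must be non-empty")

    def validate_against(self, vector: VectorConstruct) -> None:
        """Reject linkers sharing a >=10-nt exact substring with the anchor."""
        if _longest_shared_substring(self.sequence, vector.anchor_seq, 10):
            raise ValueError(
                "linker shares a >=10-nt substring with the vector anchor; "
                "reads could not be unambiguously oriented"
            )


@dataclass(frozen=True)
class IntegrationEvent:
    """A ground-truth planted vector-genome junction.

    ``pos`` is the first genomic base joined to the vector terminus;
    ``abundance`` is the clone-size weight driving read allocation.
    """

    chrom: str
    pos: int
    orient: str
    abundance: float

    def __post_init__(self) -> None:
        if self.orient not in ("+", "-"):
            raise ValueError("orient must be + or -")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


CONCATEMER_KINDS = ("head-to-tail", "head-to-head", "tail-to-tail")


@dataclass(frozen=True)
class ConcatemerJunction:
    """A vector-vector junction from an episomal multimer."""

    kind: str
    abundance: float

    def __post_init__(self) -> None:
        if self.kind not in CONCATEMER_KINDS:
            raise ValueError(f"kind must be one of {CONCATEMER_KINDS}")
        if self.abundance <= 0:
            raise ValueError("abundance must be positive")


JUNCTION_CATEGORIES = ("IS", "concatemer", "internal", "unclassified")


@dataclass(frozen=True)
class JunctionCall:
    """Per-read classification outcome.

    Categories are mutually exclusive and exhaustive over filtered reads:
    ``IS`` (vector-genome junction with a mappable genomic fragment),
    ``concatemer`` (vector-vector junction), ``internal`` (vector-positive
    but genomic part too short to map), ``unclassified`` (no vector
    anchor).
    """

    read_id: str
    category: str
    fragment: str = ""
    anchor_end: int = -1
    linker_found: bool = False

    def __post_init__(self) -> None:
        if self.category not in JUNCTION_CATEGORIES:
            raise ValueError(f"category must be one of {JUNCTION_CATEGORIES}")
        if self.category != "IS" and self.fragment:
            raise ValueError("only IS calls carry a genomic fragment")


MAPPING_STATUSES = ("unique", "multi", "unmapped")


@dataclass(frozen=True)
class MappedJunction:
    """A genomically placed junction fragment."""

    read_id: str
    chrom: Optional[str]
    pos: Optional[int]
    strand: Optional[str]
    score: float
    n_best: int
    status: str

    def __post_init__(self) -> None:
        if self.status not in MAPPING_STATUSES:
            raise ValueError(f"status must be one of {MAPPING_STATUSES}")
        if self.status == "unique" and self.n_best != 1:
            raise ValueError("unique status requires n_best == 1")
        if self.status == "multi" and self.n_best < 2:
            raise ValueError("multi status requires n_best >= 2")


@dataclass
class IntegrationSite:
    """A collapsed integration site with clonal quantification."""

    chrom: str
    pos: int
    strand: str
    read_count: int
    relative_count: float = 0.0
    nearest_gene: Optional[str] = None
    distance_to_gene: Optional[int] = None
    in_gene: bool = False


@dataclass
class SampleSummary:
    """Per-sample junction composition, shaped like a per-biopsy IS table.

    ``pct_is`` and ``pct_concatemer`` are percentages of vector-positive
    reads (IS + concatemer); both are None when no vector-positive reads
    were observed.
    """

    sample_id: str
    time_point: str
    total_is_reads: int
    concatemer_reads: int
    internal_reads: int
    unclassified_reads: int
    n_sites_total: int
    n_sites_unique: int
    n_sites_multi: int
    pct_is: Optional[float]
    pct_concatemer: Optional[float]
    is_per_ug: Optional[float] = None


@dataclass(frozen=True)
class NullDataset:
    """Synthetic random integration positions used as a comparison null."""

    positions: tuple[tuple[str, int, str], ...]
    mode: str
    seed: int

    def __post_init__(self) -> None:
        if self.mode not in ("uniform", "site_matched"):
            raise ValueError("mode must be 'uniform' or 'site_matched'")

    @property
    def size(self) -> int:
        return len(self.positions)


@dataclass
class EnrichmentResult:
    """A 2x2-count comparison outcome (Fisher's exact test)."""

    label: str
    counts: tuple[int, int, int, int]  # sample_in, sample_out, null_in, null_out
    odds_ratio: float
    p_two_sided: float
    q: float = field(default=float("nan"))

    @property
    def significant(self) -> bool:
        return self.q < 0.05


@dataclass
class SimulationConfig:
    """Parameters of the LAM-PCR read simulator.

    Defaults emulate a desk-scale study: a few hundred clones with
    log-series-skewed abundances, MiSeq-length reads, and a low
    substitution error rate.
    """

    n_events: int = 200
    hotspot: Optional[tuple[str, int, int, float]] = None
    abundance_model: str = "log-series"
    theta: float = 0.95
    error_rate: float = 0.0
    read_length: int = 150
    max_flank: int = 1000
    min_fragment: int = 20
    depth: int = 20000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hotspot is not None and not 0 <= self.hotspot[3] <= 1:
            raise ValueError("hotspot fraction must be in [0, 1]")
        if not 0 <= self.error_rate <= 0.2:
            raise ValueError("error_rate must be in [0, 0.2]")
        if self.read_length < 36:
            raise ValueError("read_length must be >= 36")
        if self.abundance_model not in ("uniform", "log-series"):
            raise ValueError("abundance_model must be 'uniform' or 'log-series'")
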
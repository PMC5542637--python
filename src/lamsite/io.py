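"""Readers and writers for the formats the pipeline touches.

FASTA and FASTQ go through Biopython; BED and GFF3 through pyranges.
Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) is
converted on the way in and out.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (
    PG_DNA_PER_DIPLOID_CELL,
    FormatError,
    GeneModel,
    ReferenceGenome,
)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Read a (possibly gzipped) FASTA file into a ReferenceGenome.

    Sequences are uppercased; record order follows the file.  Raises
    FormatError on empty files, duplicate names, or non-DNA characters.
    """
    with _open_text(path) as handle:
        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return ReferenceGenome(tuple(records))


def write_fasta(genome: ReferenceGenome, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.records
    ]
    with _open_text(path, "wt") as handle:
        SeqIO.write(records, handle, "fasta")


def read_cancer_list(path: str | Path) -> frozenset[str]:
    """Read a plain-text gene-name list (one name per line, # comments)."""
    names = set()
    with _open_text(path) as handle:
        for line in handle:
            line = line.strip()
            if line and not line.startswith("#"):
                names.add(line)
    return frozenset(names)


def read_annotation(
    path: str | Path,
    fmt: str = "BED",
    cancer_list_path: Optional[str | Path] = None,
    genome: Optional[ReferenceGenome] = None,
) -> list[GeneModel]:
    """Read gene models from BED or GFF3.

    BED coordinates are used as-is (0-based half-open); GFF3 is converted
    from 1-based inclusive.  If ``cancer_list_path`` is given, genes whose
    name appears in the list are cancer-flagged.  If ``genome`` is given,
    features are validated against chromosome bounds.
    """
    import pyranges

    fmt = fmt.upper()
    if fmt == "BED":
        df = pyranges.read_bed(str(path), as_df=True)
        name_col = "Name" if "Name" in df.columns else None
    elif fmt == "GFF3":
        df = pyranges.read_gff3(str(path), as_df=True)
        # pyranges already converts GFF3 1-based inclusive to 0-based half-open
        if "Feature" in df.columns:
            genes = df[df["Feature"] == "gene"]
            if len(genes):
                df = genes
        name_col = next(
            (c for c in ("Name", "ID", "gene_id") if c in df.columns), None
        )
    else:
        raise ValueError(f"unsupported annotation format: {fmt}")

    cancer = read_cancer_list(cancer_list_path) if cancer_list_path else frozenset()

    out: list[GeneModel] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = row._asdict()
        name = str(d.get(name_col, f"feature_{i}")) if name_col else f"feature_{i}"
        strand = str(d.get("Strand", "+"))
        if strand not in ("+", "-"):
            strand = "+"
        gene = GeneModel(
            chrom=str(d["Chromosome"]),
            start=int(d["Start"]),
            end=int(d["End"]),
            strand=strand,
            name=name,
            cancer_flag=name in cancer,
        )
        if genome is not None:
            if gene.chrom not in genome:
                raise FormatError(
                    f"feature {gene.name!r}: chromosome {gene.chrom!r} "
                    "not in genome"
                )
            if gene.end > genome.lengths[gene.chrom]:
                raise FormatError(
                    f"feature {gene.name!r}: span [{gene.start}, {gene.end}) "
                    f"exceeds {gene.chrom} length {genome.lengths[gene.chrom]}"
                )
        out.append(gene)
    return out


def write_bed(genes: Sequence[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for g in genes:
            handle.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\n"
            )


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        handle.write("##gff-version 3\n")
        for g in genes:
            handle.write(
                f"{g.chrom}\tlamsite\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\tID={g.name};Name={g.name}\n"
            )


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    """Read FASTQ into (read_id, sequence, quality-string) triples."""
    out = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for read_id, seq, qual in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def vcn_per_cell(measured_copies: float, dna_mass_pg: float) -> float:
    """Vector copy number per diploid cell.

    qPCR-measured vector copies are normalised to the number of diploid
    genome equivalents in the assayed DNA mass, at 6.6 pg of DNA per
    diploid cell.
    """
    if dna_mass_pg <= 0:
        raise ValueError("dna_mass_pg must be positive")
    if measured_copies < 0:
        raise ValueError("measured_copies must be non-negative")
    return measured_copies / (dna_mass_pg / PG_DNA_PER_DIPLOID_CELL)
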
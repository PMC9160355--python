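"""Sequences, gene annotations and terminator-zone interval selection.

The analyzed sequence for each gene is the RNA-sense (non-template DNA)
strand of its terminator zone.  Which genomic interval that is depends on
where the qPCR probe sits in the operon:

* first gene of an operon — from the transcription start site (TSS) to the
  transcription-direction distal end of the gene's reverse-primer (RP)
  probe;
* a downstream gene — the interval between the gene's own RP probe and the
  RP probe of the upstream gene (probe sequences themselves excluded).

Internal coordinates are 0-based half-open throughout; files and reports
use the 1-based inclusive genome-browser convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import (
    ConfigurationError,
    CoordinateError,
    ParseError,
    TooShortError,
    ValidationError,
)

#: IUPAC nucleotide codes accepted on input (after U->T normalization).
IUPAC_DNA = set("ACGTNRYSWKMBDHV")

#: Minimum analyzable interval: one full descriptor window.
MIN_REGION_NT = 78


class SelectionRule(str, Enum):
    FIRST_GENE = "first_gene"
    DOWNSTREAM_GENE = "downstream_gene"
    EXPLICIT = "explicit"


@dataclass(frozen=True)
class SequenceRecord:
    """An uppercase IUPAC DNA sequence, optionally anchored to a contig.

    ``origin`` is ``(contig, start, end, strand)`` in 0-based half-open
    plus-strand contig coordinates of the source interval.
    """

    id: str
    residues: str
    origin: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        bad = next(
            (i for i, c in enumerate(self.residues) if c not in IUPAC_DNA), None
        )
        if bad is not None:
            raise ValidationError(
                f"record {self.id!r}: non-IUPAC character "
                f"{self.residues[bad]!r} at offset {bad}"
            )
        if self.origin is not None:
            contig, start, end, strand = self.origin
            if end - start != len(self.residues):
                raise ValidationError(
                    f"record {self.id!r}: origin span {end - start} != "
                    f"sequence length {len(self.residues)}"
                )
            if strand not in "+-":
                raise ValidationError(f"record {self.id!r}: bad strand {strand!r}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            residues=str(Seq(self.residues).reverse_complement()),
            origin=self.origin,
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene's TSS, strand and qPCR primer-probe coordinates on a contig.

    Intervals are 0-based half-open.  ``upstream_rp_interval`` is the RP
    probe of the gene immediately upstream in the operon; it is required for
    genes that are not first in their operon.
    """

    gene: str
    contig: str
    strand: str
    tss: Optional[int] = None
    fp_interval: Optional[tuple[int, int]] = None
    rp_interval: Optional[tuple[int, int]] = None
    is_first_in_operon: bool = True
    upstream_rp_interval: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene!r}: strand must be + or -")
        for name in ("fp_interval", "rp_interval", "upstream_rp_interval"):
            iv = getattr(self, name)
            if iv is not None and iv[0] >= iv[1]:
                raise ValidationError(f"gene {self.gene!r}: empty {name} {iv}")
        if self.fp_interval and self.rp_interval:
            a, b = sorted([self.fp_interval, self.rp_interval])
            if a[1] > b[0]:
                raise ValidationError(
                    f"gene {self.gene!r}: primer intervals overlap"
                )


@dataclass(frozen=True)
class RegionSpec:
    """The genomic interval analyzed for one gene; its length is L_t."""

    gene: str
    contig: str
    start: int
    end: int
    strand: str
    rule_applied: SelectionRule = SelectionRule.EXPLICIT

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise CoordinateError(
                f"gene {self.gene!r}: start {self.start} >= end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def to_report_coords(self) -> tuple[int, int]:
        """Return (start, end) 1-based inclusive, as written to reports."""
        return self.start + 1, self.end

    @classmethod
    def from_report_coords(
        cls,
        gene: str,
        contig: str,
        start1: int,
        end1: int,
        strand: str,
        rule_applied: SelectionRule = SelectionRule.EXPLICIT,
    ) -> "RegionSpec":
        return cls(gene, contig, start1 - 1, end1, strand, rule_applied)


def _normalize(residues: str) -> str:
    return residues.upper().replace("U", "T")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Residues are uppercased and U is mapped to T; order is preserved.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = _normalize(str(rec.seq))
        if not residues:
            raise ParseError(f"{path}: record {rec.id!r} has an empty sequence")
        try:
            records.append(SequenceRecord(id=rec.id, residues=residues))
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def select_analysis_interval(
    ann: GeneAnnotation, min_length: int = MIN_REGION_NT
) -> RegionSpec:
    """Apply the operon-position rule to pick a gene's analyzed interval.

    First-in-operon genes span TSS -> distal end of the RP probe; downstream
    genes span the gap between their own RP probe and the upstream gene's RP
    probe (excluding both probes).
    """
    if ann.is_first_in_operon:
        if ann.tss is None:
            raise ConfigurationError(f"gene {ann.gene!r}: first in operon but no TSS")
        if ann.rp_interval is None:
            raise ConfigurationError(f"gene {ann.gene!r}: missing RP interval")
        if ann.strand == "+":
            start, end = ann.tss, ann.rp_interval[1]
        else:
            start, end = ann.rp_interval[0], ann.tss
        rule = SelectionRule.FIRST_GENE
    else:
        if ann.upstream_rp_interval is None:
            raise ConfigurationError(
                f"gene {ann.gene!r}: downstream gene but no upstream RP interval"
            )
        if ann.rp_interval is None:
            raise ConfigurationError(f"gene {ann.gene!r}: missing RP interval")
        left, right = sorted([ann.rp_interval, ann.upstream_rp_interval])
        start, end = left[1], right[0]
        rule = SelectionRule.DOWNSTREAM_GENE
    if start >= end:
        raise CoordinateError(
            f"gene {ann.gene!r}: selection rule produced empty interval "
            f"[{start}, {end})"
        )
    if end - start < min_length:
        raise TooShortError(
            f"gene {ann.gene!r}: interval [{start}, {end}) is "
            f"{end - start} nt, shorter than the {min_length} nt minimum"
        )
    return RegionSpec(ann.gene, ann.contig, start, end, ann.strand, rule)


def extract_region(genome: SequenceRecord, region: RegionSpec) -> SequenceRecord:
    """Extract the RNA-sense subsequence for ``region`` from ``genome``.

    Minus-strand regions are reverse-complemented so the returned residues
    read 5'->3' along the transcript.  The returned length equals
    ``end - start`` and is the transcript-length quantity L_t.
    """
    if region.start < 0 or region.end > len(genome):
        raise CoordinateError(
            f"region [{region.start}, {region.end}) outside contig "
            f"{genome.id!r} of length {len(genome)}"
        )
    sub = genome.residues[region.start : region.end]
    if region.strand == "-":
        sub = str(Seq(sub).reverse_complement())
    return SequenceRecord(
        id=region.gene,
        residues=sub,
        origin=(region.contig, region.start, region.end, region.strand),
    )


# Annotation TSV I/O (1-based inclusive coordinates in files).

ANNOTATION_COLUMNS = [
    "gene", "contig", "strand", "tss", "fp_start", "fp_end",
    "rp_start", "rp_end", "first_in_operon", "upstream_rp_start",
    "upstream_rp_end",
]


def _file_interval(row: pd.Series, start_col: str, end_col: str) -> Optional[tuple[int, int]]:
    s, e = row.get(start_col), row.get(end_col)
    if pd.isna(s) or pd.isna(e):
        return None
    return int(s) - 1, int(e)


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV (columns per :data:`ANNOTATION_COLUMNS`)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(ANNOTATION_COLUMNS[:9]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        strand = str(row["strand"])
        # File TSS is the 1-based first transcribed base.  Internally a plus
        # strand TSS is the interval start (subtract 1); a minus-strand TSS
        # is the exclusive end, numerically equal to the 1-based coordinate.
        if pd.isna(row["tss"]):
            tss = None
        else:
            tss = int(row["tss"]) - 1 if strand == "+" else int(row["tss"])
        first = str(row["first_in_operon"]).strip().lower() in ("true", "1", "yes")
        out.append(
            GeneAnnotation(
                gene=str(row["gene"]),
                contig=str(row["contig"]),
                strand=strand,
                tss=tss,
                fp_interval=_file_interval(row, "fp_start", "fp_end"),
                rp_interval=_file_interval(row, "rp_start", "rp_end"),
                is_first_in_operon=first,
                upstream_rp_interval=_file_interval(
                    row, "upstream_rp_start", "upstream_rp_end"
                ),
            )
        )
    return out
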
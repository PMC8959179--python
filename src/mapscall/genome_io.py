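"""Standard-format readers/writers and the shared coordinate model.

All coordinates inside the package are 0-based half-open on the forward
strand.  Each reader performs its own conversion at the boundary:

* GFF3 is 1-based inclusive -> subtract 1 from the start;
* bedGraph is already 0-based half-open;
* TSS tables default to 1-based positions (configurable).

Coverage is stored as one value per genomic base (1-nt bins) per
read-orientation class, together with the library's total fragment count,
which is the denominator of the reads-per-million (RPM) transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "ValidationError",
    "ParseError",
    "Orientation",
    "GenomeSequence",
    "GeneAnnotation",
    "TSSRecord",
    "CoverageTrack",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_bedgraph",
    "write_bedgraph",
    "read_tss_table",
    "write_tss_table",
    "read_table",
    "write_table",
    "reverse_complement",
]

_ALLOWED = set("ACGTN")


class ValidationError(ValueError):
    """Input violates a documented invariant (coordinates, duplicates...)."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class Orientation(str, Enum):
    """Read-pair orientation class of a stranded paired-end library.

    ``PLUS_SET`` holds pairs with SAM flags 99/147, ``MINUS_SET`` pairs
    with flags 83/163; anything else is ``EXCLUDED`` from coverage.
    """

    PLUS_SET = "PLUS_SET"
    MINUS_SET = "MINUS_SET"
    EXCLUDED = "EXCLUDED"


@dataclass(frozen=True)
class GenomeSequence:
    """A single reference sequence (bacterial chromosome scale)."""

    seq_id: str
    residues: str
    circular: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - _ALLOWED
        if bad:
            raise ValidationError(
                f"genome {self.seq_id!r} contains residues outside A/C/G/T/N: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    def fragment(self, start: int, end: int) -> str:
        """Forward-strand subsequence [start, end).

        Out-of-range coordinates are allowed only on a circular genome,
        where indexing wraps modulo the length.
        """
        if start >= end:
            raise ValidationError(f"empty or inverted fragment [{start}, {end})")
        if 0 <= start and end <= self.length:
            return self.residues[start:end]
        if not self.circular:
            raise ValidationError(
                f"fragment [{start}, {end}) outside linear genome of length {self.length}"
            )
        L = self.length
        return "".join(self.residues[i % L] for i in range(start, end))


def reverse_complement(seq: str) -> str:
    """DNA reverse complement; RNA input (U) is accepted and mapped to DNA."""
    return str(Seq(seq.upper().replace("U", "T")).reverse_complement())


@dataclass(frozen=True)
class GeneAnnotation:
    """A stranded gene feature (CDS or ncRNA) in internal coordinates."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    feature_class: str = "CDS"
    product: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    @property
    def atg(self) -> int:
        """Genomic coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TSSRecord:
    """Experimentally determined transcription start site (+1 nucleotide)."""

    gene_id: str
    tss_position: int
    strand: str


@dataclass
class CoverageTrack:
    """Per-base coverage (1-nt bins) for one orientation class.

    ``library_total`` is the total number of aligned fragments in the
    library the track came from; RPM = value * 1e6 / library_total.
    """

    seq_id: str
    values: np.ndarray
    orientation_class: Orientation
    library_total: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.library_total <= 0:
            raise ValidationError("library_total must be positive")
        if np.any(self.values < 0):
            raise ValidationError("coverage values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, circular: bool = False) -> GenomeSequence:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ParseError(f"{path}: no FASTA records")
    if len(records) > 1:
        raise ValidationError(f"{path}: expected a single-contig genome")
    rec = records[0]
    return GenomeSequence(seq_id=rec.id, residues=str(rec.seq), circular=circular)


def write_fasta(genome: GenomeSequence, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.seq_id}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" in item:
            key, val = item.split("=", 1)
            out[key.strip()] = val.strip()
    return out


def read_gff(
    path: str | Path,
    genome: GenomeSequence,
    feature_types: Sequence[str] = ("CDS", "ncRNA"),
    id_attribute: str = "locus_tag",
) -> list[GeneAnnotation]:
    """Read CDS/ncRNA features from a GFF3 file.

    GFF coordinates (1-based inclusive) are converted to 0-based
    half-open.  ``id_attribute`` names the attribute carrying the gene
    identifier (``ID`` is used as a fallback).
    """
    wanted = set(feature_types)
    out: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _frame, attrs = fields
            if ftype not in wanted:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end1 < start1:
                raise ValidationError(f"{path}:{lineno}: end < start")
            start, end = start1 - 1, end1
            if end > genome.length and not genome.circular:
                raise ValidationError(
                    f"{path}:{lineno}: feature ends at {end1} beyond genome length {genome.length}"
                )
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get(id_attribute) or attributes.get("ID")
            if gene_id is None:
                raise ParseError(
                    f"{path}:{lineno}: no {id_attribute!r} or 'ID' attribute"
                )
            if gene_id in seen:
                raise ValidationError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            out.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_class=ftype,
                    product=attributes.get("product"),
                )
            )
    return out


def write_gff(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotations:
            attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [
                        g.seq_id,
                        "mapscall",
                        g.feature_class,
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(
    path: str | Path,
    genome: GenomeSequence,
    orientation_class: Orientation,
    library_total: float,
) -> CoverageTrack:
    """Expand a bedGraph (0-based half-open intervals) to a per-base vector.

    Unlisted positions are 0.  Overlapping intervals or intervals beyond
    the genome length are rejected.
    """
    values = np.zeros(genome.length, dtype=float)
    intervals: list[tuple[int, int, float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed interval") from exc
            if not (0 <= start < end <= genome.length):
                raise ValidationError(
                    f"{path}:{lineno}: interval [{start}, {end}) outside genome"
                )
            intervals.append((start, end, value, lineno))
    intervals.sort(key=lambda t: t[0])
    prev_end = 0
    for start, end, value, lineno in intervals:
        if start < prev_end:
            raise ValidationError(f"{path}:{lineno}: overlapping bedGraph intervals")
        values[start:end] = value
        prev_end = end
    return CoverageTrack(
        seq_id=genome.seq_id,
        values=values,
        orientation_class=orientation_class,
        library_total=library_total,
    )


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Run-length encode the per-base vector; zero runs are omitted."""
    values = track.values
    with open(path, "w") as fh:
        if values.size:
            breaks = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate(([0], breaks))
            ends = np.concatenate((breaks, [values.size]))
            for s, e in zip(starts, ends):
                v = values[s]
                if v != 0:
                    fh.write(f"{track.seq_id}\t{s}\t{e}\t{v:g}\n")


# ---------------------------------------------------------------------------
# tables


def read_tss_table(
    path: str | Path,
    annotations: Sequence[GeneAnnotation] | None = None,
    one_based: bool = True,
) -> dict[str, TSSRecord]:
    """Read a per-gene TSS table (columns: gene_id, position, strand).

    One record per gene; duplicates are rejected (multi-TSS resolution is
    left to the caller).  Positions default to a 1-based input convention.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    required = {"gene_id", "position", "strand"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: TSS table must have columns {sorted(required)}")
    if df["gene_id"].duplicated().any():
        dup = df.loc[df["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate gene_id {dup!r} in TSS table")
    by_gene = {g.gene_id: g for g in annotations} if annotations is not None else None
    out: dict[str, TSSRecord] = {}
    for row in df.itertuples(index=False):
        pos = int(row.position) - (1 if one_based else 0)
        rec = TSSRecord(gene_id=str(row.gene_id), tss_position=pos, strand=str(row.strand))
        if by_gene is not None:
            gene = by_gene.get(rec.gene_id)
            if gene is not None and gene.strand != rec.strand:
                raise ValidationError(
                    f"{path}: TSS strand of {rec.gene_id!r} disagrees with annotation"
                )
        out[rec.gene_id] = rec
    return out


def write_tss_table(
    records: Mapping[str, TSSRecord] | Iterable[TSSRecord],
    path: str | Path,
    one_based: bool = True,
) -> None:
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    rows = [
        {
            "gene_id": r.gene_id,
            "position": r.tss_position + (1 if one_based else 0),
            "strand": r.strand,
        }
        for r in recs
    ]
    write_table(pd.DataFrame(rows, columns=["gene_id", "position", "strand"]), path)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(rows: pd.DataFrame | Iterable[Mapping], path: str | Path) -> None:
    """Write tab-separated text with a header row."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, sep="\t", index=False)


def read_library_totals(path: str | Path) -> dict[str, float]:
    with open(path) as fh:
        data = json.load(fh)
    return {k: float(v) for k, v in data.items()}


def write_library_totals(totals: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(dict(totals), fh, indent=1, sort_keys=True)
        fh.write("\n")
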
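"""Per-gene region model: 5'UTR, gene body, 3'UTR.

The 5'UTR of a gene is anchored at an experimentally determined TSS when
one is available and lies at least ``utr5_min_len`` nt upstream of the
start codon; otherwise it falls back to the fixed ``utr5_default_len`` nt
immediately upstream.  The 3'UTR is a fixed window running from
``utr3_into_gene`` nt inside the annotated 3' end to ``utr3_downstream``
nt beyond it (250 nt total by default).  The gene body is the annotated
extent itself.  Regions of neighbouring genes may overlap: each region is
scored independently downstream, so no de-overlapping is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genome_io import (
    GeneAnnotation,
    GenomeSequence,
    TSSRecord,
    ValidationError,
    reverse_complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RegionKind",
    "RegionRules",
    "Region",
    "RegionSet",
    "define_utr5",
    "define_utr3",
    "build_region_set",
    "region_sequence",
]


class RegionKind(str, Enum):
    UTR5 = "UTR5"
    BODY = "BODY"
    UTR3 = "UTR3"


@dataclass(frozen=True)
class RegionRules:
    """Window lengths (nt) of the region model.

    Defaults: 100-nt 5'UTR fallback and minimum, 3'UTR from 50 nt inside
    the stop to 200 nt downstream (250 nt total).
    """

    utr5_default_len: int = 100
    utr5_min_len: int = 100
    utr3_into_gene: int = 50
    utr3_downstream: int = 200

    def __post_init__(self) -> None:
        for name in ("utr5_default_len", "utr5_min_len", "utr3_into_gene", "utr3_downstream"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"RegionRules.{name} must be > 0")

    @property
    def utr3_span(self) -> int:
        return self.utr3_into_gene + self.utr3_downstream


@dataclass(frozen=True)
class Region:
    """A stranded genomic interval tied to a gene.

    Coordinates are 0-based half-open on the forward strand.  On a
    circular genome with wrapping enabled they may run past the contig
    bounds; consumers index modulo the genome length.
    """

    gene_id: str
    kind: RegionKind
    seq_id: str
    start: int
    end: int
    strand: str
    truncated: bool = False
    wrapped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_id}/{self.kind.value}: empty region [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _fit_window(
    start: int,
    end: int,
    genome: GenomeSequence,
    wrap: bool,
    label: str,
) -> tuple[int, int, bool, bool]:
    """Clip a window to the contig, or keep raw coordinates when wrapping.

    Returns (start, end, truncated, wrapped).
    """
    if 0 <= start and end <= genome.length:
        return start, end, False, False
    if wrap and genome.circular:
        return start, end, False, True
    clipped_start = max(start, 0)
    clipped_end = min(end, genome.length)
    if clipped_start >= clipped_end:
        raise ValidationError(f"{label}: window [{start}, {end}) lies entirely off-contig")
    logger.warning(
        "%s: window [%d, %d) truncated to [%d, %d) at contig edge",
        label, start, end, clipped_start, clipped_end,
    )
    return clipped_start, clipped_end, True, False


def define_utr5(
    gene: GeneAnnotation,
    tss: TSSRecord | None,
    rules: RegionRules,
    genome: GenomeSequence,
    wrap: bool = False,
) -> Region:
    """5'UTR from the TSS when long enough, else the fixed upstream window.

    The gene start base is excluded (half-open at the start codon), so
    the UTR5 and the gene body are always disjoint.
    """
    if tss is not None and tss.strand != gene.strand:
        raise ValidationError(f"{gene.gene_id}: TSS strand differs from gene strand")
    if gene.strand == "+":
        if tss is not None:
            if tss.tss_position > gene.start:
                raise ValidationError(
                    f"{gene.gene_id}: TSS at {tss.tss_position} downstream of gene start"
                )
            distance = gene.start - tss.tss_position
            if distance >= rules.utr5_min_len:
                start, end = tss.tss_position, gene.start
            else:
                start, end = gene.start - rules.utr5_default_len, gene.start
        else:
            start, end = gene.start - rules.utr5_default_len, gene.start
    else:
        if tss is not None:
            if tss.tss_position < gene.end - 1:
                raise ValidationError(
                    f"{gene.gene_id}: TSS at {tss.tss_position} downstream of gene start"
                )
            distance = tss.tss_position - (gene.end - 1)
            if distance >= rules.utr5_min_len:
                start, end = gene.end, tss.tss_position + 1
            else:
                start, end = gene.end, gene.end + rules.utr5_default_len
        else:
            start, end = gene.end, gene.end + rules.utr5_default_len
    start, end, truncated, wrapped = _fit_window(
        start, end, genome, wrap, f"{gene.gene_id}/UTR5"
    )
    return Region(gene.gene_id, RegionKind.UTR5, gene.seq_id, start, end, gene.strand,
                  truncated=truncated, wrapped=wrapped)


def define_utr3(
    gene: GeneAnnotation,
    rules: RegionRules,
    genome: GenomeSequence,
    wrap: bool = False,
) -> Region:
    """Fixed 3' window: 50 nt inside the annotated 3' end to 200 nt beyond.

    For genes shorter than ``utr3_into_gene`` the in-gene part is clipped
    at the start codon and the region flagged truncated.
    """
    truncated = False
    if gene.strand == "+":
        start, end = gene.end - rules.utr3_into_gene, gene.end + rules.utr3_downstream
        if start < gene.start:
            start, truncated = gene.start, True
    else:
        start, end = gene.start - rules.utr3_downstream, gene.start + rules.utr3_into_gene
        if end > gene.end:
            end, truncated = gene.end, True
    start, end, clipped, wrapped = _fit_window(
        start, end, genome, wrap, f"{gene.gene_id}/UTR3"
    )
    return Region(gene.gene_id, RegionKind.UTR3, gene.seq_id, start, end, gene.strand,
                  truncated=truncated or clipped, wrapped=wrapped)


@dataclass
class RegionSet:
    """Exactly one UTR5, BODY and UTR3 region per annotated gene."""

    regions: dict[tuple[str, RegionKind], Region] = field(default_factory=dict)

    def add(self, region: Region) -> None:
        key = (region.gene_id, region.kind)
        if key in self.regions:
            raise ValidationError(f"duplicate region {key}")
        self.regions[key] = region

    def get(self, gene_id: str, kind: RegionKind) -> Region:
        return self.regions[(gene_id, kind)]

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.sorted())

    def sorted(self) -> list[Region]:
        return [self.regions[k] for k in sorted(self.regions, key=lambda t: (t[0], t[1].value))]

    @property
    def gene_ids(self) -> list[str]:
        return sorted({gid for gid, _ in self.regions})

    def by_gene(self, gene_id: str) -> dict[RegionKind, Region]:
        return {kind: r for (gid, kind), r in self.regions.items() if gid == gene_id}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gene_id": r.gene_id,
                "kind": r.kind.value,
                "seq_id": r.seq_id,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "truncated": r.truncated,
            }
            for r in self.sorted()
        ]
        return pd.DataFrame(
            rows,
            columns=["gene_id", "kind", "seq_id", "start", "end", "strand", "truncated"],
        )

    def to_bed6(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.sorted():
                fh.write(
                    f"{r.seq_id}\t{r.start}\t{r.end}\t{r.gene_id}|{r.kind.value}\t0\t{r.strand}\n"
                )


def build_region_set(
    annotations: Sequence[GeneAnnotation],
    tss_table: Mapping[str, TSSRecord] | None,
    rules: RegionRules | None = None,
    genome: GenomeSequence | None = None,
    wrap: bool = False,
) -> RegionSet:
    """One UTR5/BODY/UTR3 triple per gene; BODY is the annotated extent."""
    if not annotations:
        raise ValidationError("annotation set is empty")
    if genome is None:
        raise ValidationError("a genome is required to bound the regions")
    rules = rules or RegionRules()
    tss_table = tss_table or {}
    out = RegionSet()
    for gene in annotations:
        out.add(define_utr5(gene, tss_table.get(gene.gene_id), rules, genome, wrap=wrap))
        out.add(
            Region(gene.gene_id, RegionKind.BODY, gene.seq_id, gene.start, gene.end, gene.strand)
        )
        out.add(define_utr3(gene, rules, genome, wrap=wrap))
    return out


def region_sequence(region: Region, genome: GenomeSequence) -> str:
    """Region sequence in transcript orientation (minus strand is
    reverse-complemented)."""
    seq = genome.fragment(region.start, region.end)
    return seq if region.strand == "+" else reverse_complement(seq)
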
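"""Differential-expression selection, ChIP promoter coverage, and the
per-gene evidence matrix.

The DE table is consumed, not produced: the upstream model fit
(dispersion estimation, shrinkage) happens in a dedicated DE package.
Selection is a strict FDR cut (default adjusted p < 0.01) with no fold
change filter by default.  The evidence matrix fuses, per annotated
gene: DEG status and direction, the number of pull-down experiments
calling the gene, TF-box flags, upstream seed-motif counts, ChIP
promoter-window means, and opaque binary side annotations (essentiality,
cell-cycle regulation, methylation dependence, COG class).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GeneAnnotation, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DegSelectionConfig",
    "ChipWindowConfig",
    "DegSummary",
    "select_degs",
    "deg_summary",
    "chip_window_mean",
    "build_matrix",
]


@dataclass(frozen=True)
class DegSelectionConfig:
    """Strict FDR threshold; lfc_threshold 0 disables fold-change filtering."""

    fdr_threshold: float = 0.01
    lfc_threshold: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.fdr_threshold < 1):
            raise ValidationError("fdr_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValidationError("lfc_threshold must be >= 0")


@dataclass(frozen=True)
class ChipWindowConfig:
    """Promoter window for ChIP averaging: upstream nt before the ATG and
    into_gene nt inside the coding sequence (defaults 200 and 50)."""

    upstream: int = 200
    into_gene: int = 50

    def __post_init__(self) -> None:
        if self.upstream <= 0 or self.into_gene <= 0:
            raise ValidationError("ChIP window lengths must be > 0")


def select_degs(
    table: pd.DataFrame,
    cfg: DegSelectionConfig | None = None,
) -> pd.DataFrame:
    """Select DEGs at adjusted p < fdr_threshold (strict).

    ``table`` needs columns gene_id, log2fc, p_adj.  Records with missing
    adjusted p (independent filtering) are never selected.  Returns the
    selected rows with a ``direction`` column ('up'/'down').
    """
    cfg = cfg or DegSelectionConfig()
    required = {"gene_id", "log2fc", "p_adj"}
    if not required.issubset(table.columns):
        raise ValidationError(f"DE table must have columns {sorted(required)}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene_id {dup!r} in DE table")
    p = pd.to_numeric(table["p_adj"], errors="coerce")
    if ((p < 0) | (p > 1)).any():
        raise ValidationError("adjusted p-values must lie in [0, 1]")
    mask = p.notna() & (p < cfg.fdr_threshold)
    if cfg.lfc_threshold > 0:
        mask &= table["log2fc"].abs() >= cfg.lfc_threshold
    n_missing = int(p.isna().sum())
    if n_missing:
        logger.info("select_degs: %d records with missing adjusted p excluded", n_missing)
    selected = table.loc[mask].copy()
    selected["direction"] = np.where(selected["log2fc"] > 0, "up", "down")
    return selected.sort_values("gene_id").reset_index(drop=True)


@dataclass(frozen=True)
class DegSummary:
    total: int
    up: int
    down: int
    up_pct: int | None  # rounded to nearest integer; None when total == 0
    min_abs_lfc: float | None
    max_abs_lfc: float | None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def deg_summary(selected: pd.DataFrame) -> DegSummary:
    """Counts, up-regulated percentage (rounded to nearest integer), and
    the |log2fc| extremes of a selected DEG set."""
    total = len(selected)
    if total == 0:
        return DegSummary(0, 0, 0, None, None, None)
    up = int((selected["log2fc"] > 0).sum())
    down = total - up
    abs_lfc = selected["log2fc"].abs()
    return DegSummary(
        total=total,
        up=up,
        down=down,
        up_pct=_round_half_away(100.0 * up / total),
        min_abs_lfc=float(abs_lfc.min()),
        max_abs_lfc=float(abs_lfc.max()),
    )


def chip_window_mean(
    track: CoverageTrack,
    gene: GeneAnnotation,
    cfg: ChipWindowConfig | None = None,
) -> float:
    """Mean per-base ChIP coverage over the strand-aware promoter window
    [ATG - upstream, ATG + into_gene), clipped at contig edges."""
    cfg = cfg or ChipWindowConfig()
    if gene.strand == "+":
        start, end = gene.start - cfg.upstream, gene.start + cfg.into_gene
    else:
        start, end = gene.end - cfg.into_gene, gene.end + cfg.upstream
    start = max(start, 0)
    end = min(end, track.length)
    if start >= end:
        raise ValidationError(f"{gene.gene_id}: ChIP window lies entirely off-contig")
    return float(track.values[start:end].mean())


def build_matrix(
    annotations: Sequence[GeneAnnotation],
    deg_table: pd.DataFrame | None = None,
    candidate_sets: Sequence[Iterable[str]] = (),
    ctra_full_site: Mapping[str, bool] | None = None,
    ctra_half_site: Mapping[str, bool] | None = None,
    motif_counts: Mapping[str, int] | None = None,
    chip_means: Mapping[str, float] | None = None,
    side_tables: Mapping[str, Mapping[str, object]] | None = None,
) -> pd.DataFrame:
    """One row per annotated gene fusing every line of evidence.

    ``candidate_sets`` holds one gene set per pull-down experiment;
    ``side_tables`` maps column name (essential, cell_cycle_regulated,
    methylation_dependent, cog) to per-gene values.  Missing keys default
    to False/0/NaN and are tolerated by contract.
    """
    deg_lookup: dict[str, float] = {}
    if deg_table is not None and len(deg_table):
        deg_lookup = dict(zip(deg_table["gene_id"], deg_table["log2fc"]))
    candidate_sets = [set(s) for s in candidate_sets]
    ctra_full_site = ctra_full_site or {}
    ctra_half_site = ctra_half_site or {}
    motif_counts = motif_counts or {}
    chip_means = chip_means or {}
    side_tables = side_tables or {}

    rows = []
    for gene in sorted(annotations, key=lambda g: g.gene_id):
        gid = gene.gene_id
        is_deg = gid in deg_lookup
        lfc = deg_lookup.get(gid, float("nan"))
        if not is_deg:
            direction = "none"
        else:
            direction = "up" if lfc > 0 else "down"
        row = {
            "gene_id": gid,
            "is_deg": is_deg,
            "log2fc": lfc,
            "direction": direction,
            "maps_positive_count": sum(gid in s for s in candidate_sets),
            "ctra_full_site": bool(ctra_full_site.get(gid, False)),
            "ctra_half_site": bool(ctra_half_site.get(gid, False)),
            "gggg_upstream_count": int(motif_counts.get(gid, 0)),
            "chip_mean": float(chip_means.get(gid, float("nan"))),
            "essential": bool(side_tables.get("essential", {}).get(gid, False)),
            "cell_cycle_regulated": bool(
                side_tables.get("cell_cycle_regulated", {}).get(gid, False)
            ),
            "methylation_dependent": bool(
                side_tables.get("methylation_dependent", {}).get(gid, False)
            ),
            "cog": str(side_tables.get("cog", {}).get(gid, "")),
        }
        rows.append(row)
    return pd.DataFrame(rows)
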
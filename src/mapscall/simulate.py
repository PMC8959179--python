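"""Synthetic MAPS study generator with known ground truth.

Emulates the statistical structure the pipeline assumes: a small
bacterial genome of non-overlapping stranded genes, stranded per-base
fragment-count coverage with Poisson noise around a baseline mean,
fold-enrichment planted in chosen regions of the pull-down (MS) library
only, a seed motif planted in a controlled fraction of 5'UTRs, TF-box
consensus sites planted upstream of chosen ATGs, a DE table with known
true positives, and random binary side annotations.

All randomness flows from one master seed through per-artifact
sub-streams (genome, MS library, control library, DE, side tables), so
regenerating one artifact never perturbs another.

Within the simulated 5'UTR windows, chance occurrences of the planted
motif are scrubbed (one base of each spontaneous occurrence is mutated)
before planting, so the foreground/background presence fractions of the
ground truth are exact rather than inflated by background composition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import (
    CoverageTrack,
    GeneAnnotation,
    GenomeSequence,
    Orientation,
    TSSRecord,
    ValidationError,
    reverse_complement,
    write_bedgraph,
    write_fasta,
    write_gff,
    write_library_totals,
    write_table,
    write_tss_table,
)
from .regions import RegionKind, RegionRules, RegionSet, build_region_set
from .motif import Pwm, PwmSite, assign_sites_to_genes, write_pwm

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SyntheticDataset",
    "default_pwm",
    "simulate_genome",
    "simulate_library",
    "simulate_de_table",
    "simulate_side_tables",
    "simulate_dataset",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of the synthetic experiment.

    Defaults describe a desk-scale bacterial chromosome: 150 genes of
    300-1500 nt packed on 200 kb with >= 300 nt intergenic gaps, 60% of
    genes with an experimentally known TSS 20-250 nt upstream, baseline
    sense coverage 20x with 5% antisense/intergenic bleed-through,
    Poisson count noise, 12 planted pull-down targets at 8-fold 5'UTR
    enrichment, seed-motif presence 0.6 in target vs 0.1 in background
    UTRs, 8 planted TF consensus sites, and a DE truth of 29 up / 1 down
    with |log2fc| in [0.48, 2.9].
    """

    seed: int = 0
    genome_length: int = 200_000
    n_genes: int = 150
    gene_length: tuple[int, int] = (300, 1500)
    min_intergenic_gap: int = 300
    tss_fraction: float = 0.6
    tss_distance: tuple[int, int] = (20, 250)
    baseline_mean: float = 20.0
    antisense_fraction: float = 0.05
    n_planted_targets: int = 12
    planted_kind: RegionKind = RegionKind.UTR5
    planted_fold: float = 8.0
    motif: str = "GGGG"
    motif_foreground_fraction: float = 0.6
    motif_background_fraction: float = 0.1
    n_planted_pwm_sites: int = 8
    pwm_offset: tuple[int, int] = (60, 180)
    n_true_up: int = 29
    n_true_down: int = 1
    lfc_range: tuple[float, float] = (0.48, 2.9)
    side_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "essential": 0.15,
            "cell_cycle_regulated": 0.30,
            "methylation_dependent": 0.10,
        }
    )

    def __post_init__(self) -> None:
        for frac in (self.tss_fraction, self.motif_foreground_fraction,
                     self.motif_background_fraction, self.antisense_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValidationError("fractions must lie in [0, 1]")
        if self.planted_fold < 1:
            raise ValidationError("planted_fold must be >= 1")


@dataclass
class GroundTruth:
    """What was planted, keyed the way the pipeline reports results."""

    target_regions: dict[tuple[str, str], float] = field(default_factory=dict)
    motif_genes: set[str] = field(default_factory=set)
    pwm_sites: list[tuple[str, int, str]] = field(default_factory=list)  # gene, position, strand
    true_up: set[str] = field(default_factory=set)
    true_down: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "target_regions": {f"{g}|{k}": f for (g, k), f in self.target_regions.items()},
            "motif_genes": sorted(self.motif_genes),
            "pwm_sites": [list(t) for t in self.pwm_sites],
            "true_up": sorted(self.true_up),
            "true_down": sorted(self.true_down),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genome: GenomeSequence
    annotations: list[GeneAnnotation]
    tss_table: dict[str, TSSRecord]
    region_set: RegionSet
    pwm: Pwm
    truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit every input file the pipeline consumes, plus the truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fasta"
        write_fasta(self.genome, paths["genome"])
        paths["annotation"] = outdir / "annotation.gff3"
        write_gff(self.annotations, paths["annotation"])
        paths["tss"] = outdir / "tss.tsv"
        write_tss_table(self.tss_table, paths["tss"])
        paths["pwm"] = outdir / "pwm.tsv"
        write_pwm(self.pwm, paths["pwm"])
        totals: dict[str, float] = {}
        for role in ("ms", "control"):
            tracks = simulate_library(self, role)
            for orient, suffix in ((Orientation.PLUS_SET, "plus"), (Orientation.MINUS_SET, "minus")):
                key = f"{role}_{suffix}"
                paths[key] = outdir / f"{key}.bedgraph"
                write_bedgraph(tracks[orient], paths[key])
            totals[role] = tracks[Orientation.PLUS_SET].library_total
        paths["totals"] = outdir / "library_totals.json"
        write_library_totals(totals, paths["totals"])
        paths["de"] = outdir / "de_table.tsv"
        write_table(simulate_de_table(self), paths["de"])
        for name, df in simulate_side_tables(self).items():
            paths[name] = outdir / f"{name}.tsv"
            write_table(df, paths[name])
        chip = simulate_chip_track(self)
        paths["chip"] = outdir / "chip.bedgraph"
        write_bedgraph(chip, paths["chip"])
        paths["truth"] = outdir / "ground_truth.json"
        self.truth.to_json(paths["truth"])
        return paths


def default_pwm(threshold_fraction: float = 0.70) -> Pwm:
    """A strong synthetic TF-box matrix (stand-in for an unpublished
    regulator matrix) built from counts around the consensus TTAACGCATTAA,
    a palindromic-box-like motif with no G runs (so planted boxes never
    create spurious seed-motif hits)."""
    consensus = "TTAACGCATTAA"
    counts = np.full((len(consensus), 4), 5.0)
    index = {b: i for i, b in enumerate("ACGT")}
    for pos, base in enumerate(consensus):
        counts[pos, index[base]] = 85.0
    return Pwm.from_counts(counts, pseudocount=1.0, threshold_fraction=threshold_fraction)


def _rng_streams(seed: int, names: Sequence[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


_STREAMS = ("genome", "ms", "control", "de", "side", "chip")


def _mutate_motif_occurrences(seq: list[str], motif: str, rng: np.random.Generator) -> None:
    """Destroy every occurrence of motif in seq (in place) by mutating the
    last base of the occurrence to a different random base."""
    text = "".join(seq)
    start = 0
    while True:
        idx = text.find(motif, start)
        if idx < 0:
            return
        pos = idx + len(motif) - 1
        choices = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = choices[rng.integers(len(choices))]
        text = "".join(seq)
        start = idx + 1


def simulate_genome(cfg: SimulationConfig, pwm: Pwm | None = None) -> SyntheticDataset:
    """Genome + annotation + TSS table + plantings, deterministic per seed."""
    rng = _rng_streams(cfg.seed, _STREAMS)["genome"]
    pwm = pwm or default_pwm()
    lo, hi = cfg.gene_length
    lengths = rng.integers(lo, hi + 1, size=cfg.n_genes)
    margin = cfg.min_intergenic_gap
    required = int(lengths.sum()) + (cfg.n_genes + 1) * margin
    if required > cfg.genome_length:
        raise ValidationError(
            f"cannot pack {cfg.n_genes} genes into {cfg.genome_length} nt "
            f"(need {required})"
        )
    # distribute the slack over the n+1 gaps
    slack = cfg.genome_length - required
    cuts = np.sort(rng.integers(0, slack + 1, size=cfg.n_genes))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    residues = list(_BASES[rng.integers(0, 4, size=cfg.genome_length)])
    annotations: list[GeneAnnotation] = []
    pos = 0
    n_digits = len(str(cfg.n_genes))
    for i, length in enumerate(lengths):
        pos += margin + int(extra[i])
        gid = f"gene{i + 1:0{n_digits}d}"
        strand = "+" if rng.random() < 0.5 else "-"
        annotations.append(
            GeneAnnotation(gene_id=gid, seq_id="synthchr", start=pos,
                           end=pos + int(length), strand=strand)
        )
        pos += int(length)

    tss_table: dict[str, TSSRecord] = {}
    t_lo, t_hi = cfg.tss_distance
    for gene in annotations:
        if rng.random() < cfg.tss_fraction:
            dist = int(rng.integers(t_lo, t_hi + 1))
            if gene.strand == "+":
                tss = gene.start - dist
            else:
                tss = gene.end - 1 + dist
            tss_table[gene.gene_id] = TSSRecord(gene.gene_id, tss, gene.strand)

    genome = GenomeSequence(seq_id="synthchr", residues="".join(residues))
    region_set = build_region_set(annotations, tss_table, RegionRules(), genome)

    truth = GroundTruth()

    # planted pull-down targets
    order = rng.permutation(cfg.n_genes)
    target_idx = order[: cfg.n_planted_targets]
    for i in target_idx:
        gid = annotations[i].gene_id
        truth.target_regions[(gid, cfg.planted_kind.value)] = cfg.planted_fold

    # seed motif: scrub chance occurrences in every 5'UTR, then plant at the
    # configured foreground/background presence fractions
    target_ids = {annotations[i].gene_id for i in target_idx}
    for gene in annotations:
        region = region_set.get(gene.gene_id, RegionKind.UTR5)
        window = residues[region.start : region.end]
        sense = window if gene.strand == "+" else list(reverse_complement("".join(window)))
        _mutate_motif_occurrences(sense, cfg.motif, rng)
        frac = (
            cfg.motif_foreground_fraction
            if gene.gene_id in target_ids
            else cfg.motif_background_fraction
        )
        if rng.random() < frac:
            # plant within the 40 nt nearest the start codon, clear of
            # planted TF boxes further upstream
            span = len(sense)
            hi_off = min(40, span) - len(cfg.motif)
            if hi_off >= 0:
                off = int(rng.integers(0, hi_off + 1))
                pos0 = span - len(cfg.motif) - off
                sense[pos0 : pos0 + len(cfg.motif)] = list(cfg.motif)
                truth.motif_genes.add(gene.gene_id)
        window = sense if gene.strand == "+" else list(reverse_complement("".join(sense)))
        residues[region.start : region.end] = window

    # planted TF-box consensus sites upstream of chosen ATGs
    pwm_idx = order[cfg.n_planted_targets : cfg.n_planted_targets + cfg.n_planted_pwm_sites]
    consensus = pwm.consensus()
    o_lo, o_hi = cfg.pwm_offset
    occupied: list[tuple[int, int]] = []
    for i in pwm_idx:
        gene = annotations[i]
        for _attempt in range(10):
            offset = int(rng.integers(o_lo, o_hi + 1))
            if gene.strand == "+":
                start = gene.start - offset - len(consensus)
                insert = consensus
                site_strand = "+"
            else:
                start = gene.end - 1 + offset + 1
                insert = reverse_complement(consensus)
                site_strand = "-"
            end = start + len(consensus)
            if start < 0 or end > cfg.genome_length:
                continue
            if any(start < e and s < end for s, e in occupied):
                continue  # would overwrite an earlier planted box
            # only plant where the planting gene is the closest ATG, so the
            # closest-gene assignment rule maps the site back to its gene
            probe = PwmSite("synthchr", start, site_strand, 0.0)
            (assigned,), _ = assign_sites_to_genes(
                [probe], annotations, site_width=len(consensus)
            )
            if assigned.assigned_gene != gene.gene_id:
                continue
            residues[start:end] = list(insert)
            occupied.append((start, end))
            truth.pwm_sites.append((gene.gene_id, start, site_strand))
            break

    genome = GenomeSequence(seq_id="synthchr", residues="".join(residues))
    # TSS-anchored regions depend only on coordinates, no need to rebuild
    return SyntheticDataset(
        config=cfg,
        genome=genome,
        annotations=annotations,
        tss_table=tss_table,
        region_set=region_set,
        pwm=pwm,
        truth=truth,
    )


def simulate_library(
    dataset: SyntheticDataset, role: str
) -> dict[Orientation, CoverageTrack]:
    """Stranded Poisson coverage pair for one library.

    Sense bases of each gene's regions draw at the baseline mean;
    everything else (antisense, intergenic) at baseline * bleed-through.
    In the MS library, planted target regions draw at baseline * fold on
    their sense strand.  The shared library total is the sum of all
    counts on both tracks.
    """
    if role not in ("ms", "control"):
        raise ValidationError("library role must be 'ms' or 'control'")
    cfg = dataset.config
    rng = _rng_streams(cfg.seed, _STREAMS)[role]
    L = dataset.genome.length
    background = cfg.baseline_mean * cfg.antisense_fraction
    means = {
        "+": np.full(L, background),
        "-": np.full(L, background),
    }
    for gene in dataset.annotations:
        for kind in RegionKind:
            region = dataset.region_set.get(gene.gene_id, kind)
            means[gene.strand][region.start : region.end] = cfg.baseline_mean
    if role == "ms":
        for (gid, kind), fold in dataset.truth.target_regions.items():
            region = dataset.region_set.get(gid, RegionKind(kind))
            means[region.strand][region.start : region.end] = cfg.baseline_mean * fold
    plus = rng.poisson(means["+"]).astype(float)
    minus = rng.poisson(means["-"]).astype(float)
    total = float(plus.sum() + minus.sum())
    return {
        Orientation.PLUS_SET: CoverageTrack("synthchr", plus, Orientation.PLUS_SET, total),
        Orientation.MINUS_SET: CoverageTrack("synthchr", minus, Orientation.MINUS_SET, total),
    }


def simulate_de_table(dataset: SyntheticDataset) -> pd.DataFrame:
    """DE table with known true positives.

    True up/down genes draw |log2fc| in the configured range with
    adjusted p below the 0.01 selection threshold; null genes sit near
    log2fc 0 with adjusted p uniform on (0.05, 1]."""
    cfg = dataset.config
    rng = _rng_streams(cfg.seed, _STREAMS)["de"]
    gene_ids = [g.gene_id for g in dataset.annotations]
    n_sig = cfg.n_true_up + cfg.n_true_down
    if n_sig > len(gene_ids):
        raise ValidationError("more true DEGs requested than genes")
    chosen = rng.permutation(len(gene_ids))[:n_sig]
    up_ids = {gene_ids[i] for i in chosen[: cfg.n_true_up]}
    down_ids = {gene_ids[i] for i in chosen[cfg.n_true_up :]}
    dataset.truth.true_up = set(up_ids)
    dataset.truth.true_down = set(down_ids)
    lo, hi = cfg.lfc_range
    rows = []
    for gid in gene_ids:
        if gid in up_ids or gid in down_ids:
            lfc = float(rng.uniform(lo, hi))
            if gid in down_ids:
                lfc = -lfc
            p_adj = float(rng.uniform(1e-6, 0.009))
        else:
            lfc = float(rng.normal(0.0, 0.1))
            p_adj = float(rng.uniform(0.05, 1.0))
        rows.append({"gene_id": gid, "log2fc": lfc, "p_adj": p_adj})
    return pd.DataFrame(rows)


def simulate_side_tables(dataset: SyntheticDataset) -> dict[str, pd.DataFrame]:
    """Random binary annotation tables plus a COG class per gene."""
    cfg = dataset.config
    rng = _rng_streams(cfg.seed, _STREAMS)["side"]
    gene_ids = [g.gene_id for g in dataset.annotations]
    out: dict[str, pd.DataFrame] = {}
    for name, prevalence in cfg.side_prevalence.items():
        flags = rng.random(len(gene_ids)) < prevalence
        out[name] = pd.DataFrame({"gene_id": gene_ids, "value": flags})
    cogs = rng.choice(list("JKLDMNOTUV"), size=len(gene_ids))
    out["cog"] = pd.DataFrame({"gene_id": gene_ids, "value": cogs})
    return out


def simulate_chip_track(dataset: SyntheticDataset, enriched_mean: float = 15.0,
                        background_mean: float = 3.0) -> CoverageTrack:
    """Unstranded ChIP-style coverage with promoter-proximal enrichment for
    cell-cycle-regulated genes (reuses the side-table truth)."""
    cfg = dataset.config
    rng = _rng_streams(cfg.seed, _STREAMS)["chip"]
    side = simulate_side_tables(dataset)["cell_cycle_regulated"]
    flagged = set(side.loc[side["value"], "gene_id"])
    means = np.full(dataset.genome.length, background_mean)
    for gene in dataset.annotations:
        if gene.gene_id not in flagged:
            continue
        if gene.strand == "+":
            start, end = gene.start - 200, gene.start + 50
        else:
            start, end = gene.end - 50, gene.end + 200
        means[max(start, 0) : min(end, dataset.genome.length)] = enriched_mean
    values = rng.poisson(means).astype(float)
    return CoverageTrack("synthchr", values, Orientation.PLUS_SET, float(values.sum()))


def simulate_dataset(cfg: SimulationConfig | None = None, pwm: Pwm | None = None) -> SyntheticDataset:
    return simulate_genome(cfg or SimulationConfig(), pwm=pwm)
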
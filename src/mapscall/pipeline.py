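"""High-level pipeline stages shared by the CLI and by scripts.

Each stage reads the standard input formats, runs one analysis layer,
and writes deterministic, sorted TSV tables.  ``run_all`` chains the
stages and records a run manifest (config hash, seed, output checksums)
so repeated runs are verifiable byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import genome_io
from .genome_io import Orientation, ValidationError
from .regions import RegionKind, RegionRules, RegionSet, build_region_set, region_sequence
from .coverage import (
    MapsCallerConfig,
    OrientationProtocol,
    call_candidates,
    calls_to_frame,
    compute_region_coverages,
)
from .motif import (
    MotifQuery,
    count_motif_occurrences,
    motif_enrichment,
    read_pwm,
    sample_background_utrs,
    scan_pwm,
    assign_sites_to_genes,
    site_set_enrichment,
    sites_to_bed6,
)
from .integration import (
    ChipWindowConfig,
    DegSelectionConfig,
    build_matrix,
    chip_window_mean,
    deg_summary,
    select_degs,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineRun", "load_config"]


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; defaults hold the published
    constants of the method (100-nt UTR5, 50/200 UTR3, log2 >= 2, 25%
    floor, 70% PWM threshold, 250-nt site window, -200/+50 ChIP window,
    FDR < 0.01)."""

    paths: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    tss_one_based: bool = True
    region_rules: RegionRules = field(default_factory=RegionRules)
    caller: MapsCallerConfig = field(default_factory=MapsCallerConfig)
    protocol: OrientationProtocol = field(default_factory=OrientationProtocol)
    motif: MotifQuery = field(default_factory=MotifQuery)
    background_n: int | None = None
    pwm_kind: str = "scores"
    pwm_threshold_fraction: float = 0.70
    pwm_threshold_mode: str = "absolute"
    upstream_window: int = 250
    deg: DegSelectionConfig = field(default_factory=DegSelectionConfig)
    chip_window: ChipWindowConfig = field(default_factory=ChipWindowConfig)

    def path(self, key: str, required: bool = True) -> Path | None:
        value = self.paths.get(key)
        if value is None:
            if required:
                raise ValidationError(f"config is missing required path {key!r}")
            return None
        p = Path(value)
        if not p.exists():
            raise ValidationError(f"input path for {key!r} does not exist: {p}")
        return p

    @property
    def outdir(self) -> Path:
        out = Path(self.paths.get("outdir", "results"))
        out.mkdir(parents=True, exist_ok=True)
        return out

    def to_dict(self) -> dict:
        def unpack(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: unpack(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Orientation):
                return obj.value
            return obj

        return {
            "paths": dict(self.paths),
            "seed": self.seed,
            "tss_one_based": self.tss_one_based,
            "region_rules": unpack(self.region_rules),
            "caller": unpack(self.caller),
            "protocol": {
                "plus_strand": self.protocol.plus_strand.value,
                "minus_strand": self.protocol.minus_strand.value,
            },
            "motif": self.motif.motif,
            "background_n": self.background_n,
            "pwm": {
                "kind": self.pwm_kind,
                "threshold_fraction": self.pwm_threshold_fraction,
                "threshold_mode": self.pwm_threshold_mode,
                "upstream_window": self.upstream_window,
            },
            "deg": unpack(self.deg),
            "chip_window": unpack(self.chip_window),
        }


def load_config(source: str | Path | Mapping) -> PipelineConfig:
    """Build a PipelineConfig from a YAML/JSON file or a mapping."""
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            data = yaml.safe_load(fh) or {}
    else:
        data = dict(source)
    if not isinstance(data, dict):
        raise ValidationError("config must be a mapping")
    cfg = PipelineConfig()
    cfg.paths = dict(data.get("paths", {}))
    cfg.seed = int(data.get("seed", 0))
    cfg.tss_one_based = bool(data.get("tss_one_based", True))
    if "region_rules" in data:
        cfg.region_rules = RegionRules(**data["region_rules"])
    if "caller" in data:
        cfg.caller = MapsCallerConfig(**data["caller"])
    if "protocol" in data:
        proto = data["protocol"]
        cfg.protocol = OrientationProtocol(
            plus_strand=Orientation(proto.get("plus_strand", "PLUS_SET")),
            minus_strand=Orientation(proto.get("minus_strand", "MINUS_SET")),
        )
    if "motif" in data:
        cfg.motif = MotifQuery(motif=data["motif"])
    cfg.background_n = data.get("background_n")
    pwm_cfg = data.get("pwm", {})
    cfg.pwm_kind = pwm_cfg.get("kind", "scores")
    cfg.pwm_threshold_fraction = float(pwm_cfg.get("threshold_fraction", 0.70))
    cfg.pwm_threshold_mode = pwm_cfg.get("threshold_mode", "absolute")
    cfg.upstream_window = int(pwm_cfg.get("upstream_window", 250))
    if "deg" in data:
        cfg.deg = DegSelectionConfig(**data["deg"])
    if "chip_window" in data:
        cfg.chip_window = ChipWindowConfig(**data["chip_window"])
    return cfg


class PipelineRun:
    """Lazy-loading context over one configuration."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self._genome = None
        self._annotations = None
        self._region_set: RegionSet | None = None
        self.outputs: dict[str, Path] = {}

    # ---------------- inputs

    @property
    def genome(self):
        if self._genome is None:
            self._genome = genome_io.read_fasta(self.config.path("genome"))
        return self._genome

    @property
    def annotations(self):
        if self._annotations is None:
            self._annotations = genome_io.read_gff(self.config.path("annotation"), self.genome)
        return self._annotations

    @property
    def region_set(self) -> RegionSet:
        if self._region_set is None:
            tss_path = self.config.path("tss", required=False)
            tss = (
                genome_io.read_tss_table(
                    tss_path, self.annotations, one_based=self.config.tss_one_based
                )
                if tss_path
                else {}
            )
            self._region_set = build_region_set(
                self.annotations, tss, self.config.region_rules, self.genome
            )
        return self._region_set

    def _load_tracks(self, role: str):
        totals = genome_io.read_library_totals(self.config.path("library_totals"))
        if role not in totals:
            raise ValidationError(f"library_totals is missing the {role!r} total")
        return {
            Orientation.PLUS_SET: genome_io.read_bedgraph(
                self.config.path(f"{role}_plus"), self.genome,
                Orientation.PLUS_SET, totals[role],
            ),
            Orientation.MINUS_SET: genome_io.read_bedgraph(
                self.config.path(f"{role}_minus"), self.genome,
                Orientation.MINUS_SET, totals[role],
            ),
        }

    def _write(self, key: str, df: pd.DataFrame, name: str) -> Path:
        path = self.config.outdir / name
        genome_io.write_table(df, path)
        self.outputs[key] = path
        return path

    # ---------------- stages

    def run_regions(self) -> pd.DataFrame:
        df = self.region_set.to_frame()
        self._write("regions", df, "regions.tsv")
        self.region_set.to_bed6(self.config.outdir / "regions.bed")
        self.outputs["regions_bed"] = self.config.outdir / "regions.bed"
        return df

    def run_call(self) -> tuple[pd.DataFrame, list[str]]:
        ms = compute_region_coverages(self.region_set, self._load_tracks("ms"), self.config.protocol)
        control = compute_region_coverages(
            self.region_set, self._load_tracks("control"), self.config.protocol
        )
        calls, genes = call_candidates(ms, control, self.config.caller)
        df = calls_to_frame(calls)
        self._write("calls", df, "region_calls.tsv")
        gene_df = pd.DataFrame({"gene_id": sorted(genes)})
        self._write("candidates", gene_df, "candidate_genes.tsv")
        return df, sorted(genes)

    def run_motif(self, candidate_genes: list[str] | None = None) -> pd.DataFrame:
        if candidate_genes is None:
            path = self.outputs.get("candidates") or (self.config.outdir / "candidate_genes.tsv")
            if not Path(path).exists():
                raise ValidationError("motif stage needs candidate genes; run 'call' first")
            candidates_df = genome_io.read_table(path)
            candidate_genes = [str(g) for g in candidates_df["gene_id"]]
        fg = [
            region_sequence(self.region_set.get(g, RegionKind.UTR5), self.genome)
            for g in sorted(candidate_genes)
        ]
        n_bg = self.config.background_n or len(self.region_set.gene_ids)
        bg = sample_background_utrs(self.region_set, self.genome, n_bg, seed=self.config.seed)
        result = motif_enrichment(fg, bg, self.config.motif)
        df = pd.DataFrame([result.to_row()])
        df.insert(0, "seed", self.config.seed)
        self._write("motif_enrichment", df, "motif_enrichment.tsv")
        return df

    def run_pwm(self, gene_set: list[str] | None = None) -> pd.DataFrame:
        pwm = read_pwm(
            self.config.path("pwm"),
            kind=self.config.pwm_kind,
            threshold_fraction=self.config.pwm_threshold_fraction,
            threshold_mode=self.config.pwm_threshold_mode,
        )
        sites = scan_pwm(self.genome, pwm)
        sites, has_site = assign_sites_to_genes(
            sites, self.annotations, self.config.upstream_window, site_width=pwm.width
        )
        bed = self.config.outdir / "pwm_sites.bed"
        sites_to_bed6(sites, pwm.width, bed)
        self.outputs["pwm_sites"] = bed
        flags = pd.DataFrame(
            {"gene_id": sorted(has_site), "has_site": [has_site[g] for g in sorted(has_site)]}
        )
        self._write("pwm_gene_flags", flags, "pwm_gene_flags.tsv")
        if gene_set:
            result = site_set_enrichment(
                gene_set, [g.gene_id for g in self.annotations], has_site
            )
            df = pd.DataFrame([result.to_row()])
            self._write("pwm_enrichment", df, "pwm_enrichment.tsv")
        return flags

    def run_integrate(self) -> pd.DataFrame:
        de_path = self.config.path("de_table", required=False)
        deg_selected = None
        if de_path:
            deg_selected = select_degs(genome_io.read_table(de_path), self.config.deg)
            summary = deg_summary(deg_selected)
            self._write(
                "deg_summary",
                pd.DataFrame([dataclasses.asdict(summary)]),
                "deg_summary.tsv",
            )
        candidate_path = self.config.outdir / "candidate_genes.tsv"
        candidate_sets = []
        if candidate_path.exists():
            candidate_sets = [list(genome_io.read_table(candidate_path)["gene_id"].astype(str))]
        flags_path = self.config.outdir / "pwm_gene_flags.tsv"
        full_site = {}
        if flags_path.exists():
            flags = genome_io.read_table(flags_path)
            full_site = dict(zip(flags["gene_id"].astype(str), flags["has_site"].astype(bool)))
        motif_counts = {
            g.gene_id: count_motif_occurrences(
                region_sequence(self.region_set.get(g.gene_id, RegionKind.UTR5), self.genome),
                self.config.motif,
            )
            for g in self.annotations
        }
        chip_means = {}
        chip_path = self.config.path("chip", required=False)
        if chip_path:
            track = genome_io.read_bedgraph(chip_path, self.genome, Orientation.PLUS_SET, 1.0)
            chip_means = {
                g.gene_id: chip_window_mean(track, g, self.config.chip_window)
                for g in self.annotations
            }
        side_tables = {}
        for name in ("essential", "cell_cycle_regulated", "methylation_dependent", "cog"):
            p = self.config.path(name, required=False)
            if p:
                df = genome_io.read_table(p)
                side_tables[name] = dict(zip(df["gene_id"].astype(str), df["value"]))
        matrix = build_matrix(
            self.annotations,
            deg_table=deg_selected,
            candidate_sets=candidate_sets,
            ctra_full_site=full_site,
            motif_counts=motif_counts,
            chip_means=chip_means,
            side_tables=side_tables,
        )
        self._write("matrix", matrix, "gene_matrix.tsv")
        if deg_selected is not None:
            deg_rows = matrix[matrix["is_deg"]]
            self._write("matrix_degs", deg_rows, "gene_matrix_degs.tsv")
        return matrix

    def run_all(self) -> dict[str, Path]:
        self.run_regions()
        _, genes = self.run_call()
        self.run_motif(genes)
        if self.config.path("pwm", required=False):
            deg_genes: list[str] | None = None
            de_path = self.config.path("de_table", required=False)
            if de_path:
                deg_genes = list(
                    select_degs(genome_io.read_table(de_path), self.config.deg)["gene_id"]
                )
            self.run_pwm(deg_genes)
        self.run_integrate()
        self.write_manifest()
        return dict(self.outputs)

    def write_manifest(self) -> Path:
        manifest = {
            "config": self.config.to_dict(),
            "config_sha256": hashlib.sha256(
                json.dumps(self.config.to_dict(), sort_keys=True).encode()
            ).hexdigest(),
            "seed": self.config.seed,
            "outputs": {
                key: {
                    "path": str(path),
                    "sha256": hashlib.sha256(Path(path).read_bytes()).hexdigest(),
                }
                for key, path in sorted(self.outputs.items())
            },
        }
        path = self.config.outdir / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
            fh.write("\n")
        return path
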
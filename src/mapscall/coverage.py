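"""Strand-aware region coverage and MAPS candidate calling.

The coverage of a region is the SUM of the 1-nt coverage values falling
inside it, taken from the track whose read-orientation class matches the
region's strand under the library protocol, then scaled to reads per
million (RPM) with the library's total fragment count.

A region is called as an sRNA pull-down candidate when

* log2((ms_rpm + pc) / (control_rpm + pc)) >= 2  (a 4-fold increase), and
* ms_rpm exceeds the lower-quartile floor of all MS region RPM values
  (nearest-rank percentile, zeros included),

and a gene is a candidate when at least one of its three regions is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import CoverageTrack, GenomeSequence, Orientation, ValidationError
from .regions import Region, RegionSet

__all__ = [
    "classify_pair_orientation",
    "OrientationProtocol",
    "RegionCoverage",
    "MapsCallerConfig",
    "CandidateCall",
    "region_coverage",
    "compute_region_coverages",
    "nearest_rank_quantile",
    "call_candidates",
    "calls_to_frame",
    "coverage_from_alignments",
]

#: SAM flags of properly-paired mates aligned in forward orientation.
_PLUS_FLAGS = frozenset({99, 147})
#: SAM flags of properly-paired mates aligned in reverse orientation.
_MINUS_FLAGS = frozenset({83, 163})


def classify_pair_orientation(sam_flag: int) -> Orientation:
    """Map a SAM FLAG to its orientation class.

    Flags 99/147 -> PLUS_SET, 83/163 -> MINUS_SET; every other flag is
    excluded (unmapped, discordant, secondary...).
    """
    if sam_flag < 0:
        raise ValidationError(f"SAM flag must be non-negative, got {sam_flag}")
    if sam_flag in _PLUS_FLAGS:
        return Orientation.PLUS_SET
    if sam_flag in _MINUS_FLAGS:
        return Orientation.MINUS_SET
    return Orientation.EXCLUDED


@dataclass(frozen=True)
class OrientationProtocol:
    """Which orientation class carries the sense reads of each strand.

    The default maps PLUS_SET reads to + strand transcripts, matching a
    standard stranded paired-end kit; flip it for a reverse protocol.
    """

    plus_strand: Orientation = Orientation.PLUS_SET
    minus_strand: Orientation = Orientation.MINUS_SET

    def for_strand(self, strand: str) -> Orientation:
        return self.plus_strand if strand == "+" else self.minus_strand


@dataclass(frozen=True)
class RegionCoverage:
    region: Region
    raw_sum: float
    rpm: float


@dataclass(frozen=True)
class MapsCallerConfig:
    """Thresholds of the candidate caller.

    log2_threshold 2 is a 4-fold linear increase; coverage_quantile 0.25
    is the lower-quartile floor on MS region RPM.  The pseudocount (in
    RPM units, added to both numerator and denominator) keeps ratios
    finite when the control is empty; set it to 0 for the pure ratio.
    """

    log2_threshold: float = 2.0
    coverage_quantile: float = 0.25
    pseudocount_rpm: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.coverage_quantile < 1):
            raise ValidationError("coverage_quantile must be in (0, 1)")
        if self.log2_threshold <= 0:
            raise ValidationError("log2_threshold must be > 0")
        if self.pseudocount_rpm < 0:
            raise ValidationError("pseudocount_rpm must be >= 0")


@dataclass(frozen=True)
class CandidateCall:
    region: Region
    ms_rpm: float
    control_rpm: float
    log2_ratio: float
    passed_ratio: bool
    passed_floor: bool

    @property
    def gene_id(self) -> str:
        return self.region.gene_id

    @property
    def is_candidate_region(self) -> bool:
        return self.passed_ratio and self.passed_floor


def _region_slice_sum(values: np.ndarray, region: Region) -> float:
    L = values.shape[0]
    if region.wrapped:
        idx = np.arange(region.start, region.end) % L
        return float(values[idx].sum())
    if region.start < 0 or region.end > L:
        raise ValidationError(
            f"{region.gene_id}/{region.kind.value}: region outside coverage track"
        )
    return float(values[region.start : region.end].sum())


def region_coverage(
    region: Region,
    tracks: Mapping[Orientation, CoverageTrack],
    protocol: OrientationProtocol | None = None,
) -> RegionCoverage:
    """Sum the 1-nt values over the region from its sense-orientation track."""
    protocol = protocol or OrientationProtocol()
    wanted = protocol.for_strand(region.strand)
    if wanted not in tracks:
        raise ValidationError(f"no track for orientation class {wanted.value}")
    track = tracks[wanted]
    raw = _region_slice_sum(track.values, region)
    return RegionCoverage(region=region, raw_sum=raw, rpm=raw * 1e6 / track.library_total)


def compute_region_coverages(
    region_set: RegionSet,
    tracks: Mapping[Orientation, CoverageTrack],
    protocol: OrientationProtocol | None = None,
) -> list[RegionCoverage]:
    return [region_coverage(r, tracks, protocol) for r in region_set.sorted()]


def nearest_rank_quantile(values: Sequence[float], q: float) -> float:
    """Nearest-rank percentile: the ceil(q*N)-th smallest observed value."""
    data = sorted(values)
    if not data:
        raise ValidationError("cannot take a quantile of an empty set")
    rank = max(1, math.ceil(q * len(data)))
    return data[rank - 1]


def call_candidates(
    ms: Sequence[RegionCoverage],
    control: Sequence[RegionCoverage],
    cfg: MapsCallerConfig | None = None,
) -> tuple[list[CandidateCall], set[str]]:
    """Apply the ratio and quantile-floor filters to paired region coverages.

    ``ms`` and ``control`` must cover the same regions (same order).
    Returns the per-region calls (sorted by gene then region kind) and
    the set of candidate genes (>= 1 candidate region).
    """
    cfg = cfg or MapsCallerConfig()
    if len(ms) != len(control):
        raise ValidationError("MS and control cover different region sets")
    key = lambda rc: (rc.region.gene_id, rc.region.kind.value)
    ms = sorted(ms, key=key)
    control = sorted(control, key=key)
    for a, b in zip(ms, control):
        if (a.region.gene_id, a.region.kind) != (b.region.gene_id, b.region.kind):
            raise ValidationError("MS and control cover different region sets")
    floor = nearest_rank_quantile([rc.rpm for rc in ms], cfg.coverage_quantile)
    calls: list[CandidateCall] = []
    genes: set[str] = set()
    pc = cfg.pseudocount_rpm
    for m, c in zip(ms, control):
        num, den = m.rpm + pc, c.rpm + pc
        if num == 0:
            ratio = -math.inf
        elif den == 0:
            ratio = math.inf
        else:
            ratio = math.log2(num / den)
        passed_ratio = ratio >= cfg.log2_threshold
        passed_floor = m.rpm > floor
        call = CandidateCall(
            region=m.region,
            ms_rpm=m.rpm,
            control_rpm=c.rpm,
            log2_ratio=ratio,
            passed_ratio=passed_ratio,
            passed_floor=passed_floor,
        )
        calls.append(call)
        if call.is_candidate_region:
            genes.add(m.region.gene_id)
    return calls, genes


def calls_to_frame(calls: Iterable[CandidateCall]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "kind": c.region.kind.value,
            "ms_rpm": c.ms_rpm,
            "control_rpm": c.control_rpm,
            "log2_ratio": c.log2_ratio,
            "passed_ratio": c.passed_ratio,
            "passed_floor": c.passed_floor,
            "is_candidate_region": c.is_candidate_region,
        }
        for c in calls
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "kind", "ms_rpm", "control_rpm", "log2_ratio",
            "passed_ratio", "passed_floor", "is_candidate_region",
        ],
    )
    return df.sort_values(["gene_id", "kind"]).reset_index(drop=True)


def coverage_from_alignments(
    sam_path: str | Path,
    genome: GenomeSequence,
) -> dict[Orientation, CoverageTrack]:
    """Build stranded 1-nt coverage tracks from a SAM/BAM of paired reads.

    Only properly-paired mates with the listed flags (99/147 forward,
    83/163 reverse) contribute; each aligned reference base adds 1.  The
    shared library total is the number of contributing fragments (pairs),
    counted once per leftmost mate.
    """
    import pysam

    plus = np.zeros(genome.length, dtype=float)
    minus = np.zeros(genome.length, dtype=float)
    fragments = 0
    with pysam.AlignmentFile(str(sam_path), check_sq=False) as fh:
        for read in fh:
            cls = classify_pair_orientation(read.flag)
            if cls is Orientation.EXCLUDED:
                continue
            if read.flag in (99, 83):  # leftmost/first-in-pair proxy per fragment
                fragments += 1
            arr = plus if cls is Orientation.PLUS_SET else minus
            for _qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if 0 <= rpos < genome.length:
                    arr[rpos] += 1
    if fragments == 0:
        raise ValidationError(f"{sam_path}: no properly-paired fragments with usable flags")
    return {
        Orientation.PLUS_SET: CoverageTrack(genome.seq_id, plus, Orientation.PLUS_SET, fragments),
        Orientation.MINUS_SET: CoverageTrack(genome.seq_id, minus, Orientation.MINUS_SET, fragments),
    }
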
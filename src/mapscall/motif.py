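"""Sequence-motif and PWM analyses of candidate targets and regulons.

Two statistics share one machinery:

* presence of a short seed motif (default ``GGGG``, the complement of the
  sRNA's exposed C-rich loop) in candidate 5'UTRs versus randomly chosen
  background UTRs;
* presence of a transcription-factor box (PWM hit within 250 nt upstream
  of the ATG, assigned to the closest gene) in a differentially
  expressed gene set versus all genes.

Both are tested with the one-sided upper-tail exact binomial test: the
background fraction is the null success probability for the foreground
count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import (
    GeneAnnotation,
    GenomeSequence,
    ValidationError,
    reverse_complement,
)
from .regions import RegionKind, RegionSet, region_sequence

__all__ = [
    "MotifQuery",
    "EnrichmentResult",
    "Pwm",
    "PwmSite",
    "utr_has_motif",
    "loop_complement_motif",
    "sample_background_utrs",
    "binomial_upper_tail",
    "motif_enrichment",
    "scan_pwm",
    "assign_sites_to_genes",
    "site_set_enrichment",
    "count_motif_occurrences",
    "read_pwm",
    "write_pwm",
    "sites_to_bed6",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class MotifQuery:
    """A short DNA motif searched in transcript orientation."""

    motif: str = "GGGG"

    def __post_init__(self) -> None:
        motif = _normalize_seq(self.motif)
        if not motif:
            raise ValidationError("motif must be non-empty")
        if set(motif) - set(_BASES):
            raise ValidationError(f"motif {self.motif!r} has characters outside A/C/G/T/U")
        object.__setattr__(self, "motif", motif)


def utr_has_motif(utr_sequence: str, q: MotifQuery) -> bool:
    """True iff the motif occurs at least once (presence, not count)."""
    return q.motif in _normalize_seq(utr_sequence)


def count_motif_occurrences(sequence: str, q: MotifQuery) -> int:
    """Number of (possibly overlapping) motif occurrences."""
    seq = _normalize_seq(sequence)
    count = start = 0
    while True:
        idx = seq.find(q.motif, start)
        if idx < 0:
            return count
        count += 1
        start = idx + 1


def loop_complement_motif(ncrna_sequence: str, loop_interval: tuple[int, int]) -> MotifQuery:
    """Motif complementary to an sRNA loop: the reverse complement of the
    loop subsequence, searched in target UTRs (a CCCC loop yields GGGG)."""
    start, end = loop_interval
    seq = _normalize_seq(ncrna_sequence)
    if not (0 <= start < end <= len(seq)):
        raise ValidationError(f"loop interval [{start}, {end}) outside sequence of length {len(seq)}")
    return MotifQuery(motif=reverse_complement(seq[start:end]))


def sample_background_utrs(
    region_set: RegionSet,
    genome: GenomeSequence,
    n: int,
    seed: int,
    replace_: bool = False,
) -> list[str]:
    """Randomly chosen 5'UTR sequences (transcript orientation), the
    background set for motif enrichment.  Deterministic given the seed."""
    if n <= 0:
        raise ValidationError("background sample size must be positive")
    utrs = [r for r in region_set.sorted() if r.kind is RegionKind.UTR5]
    if n > len(utrs) and not replace_:
        raise ValidationError(
            f"cannot sample {n} UTRs from {len(utrs)} genes without replacement"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(utrs), size=n, replace=replace_)
    return [region_sequence(utrs[i], genome) for i in idx]


# ---------------------------------------------------------------------------
# exact binomial test


@dataclass(frozen=True)
class EnrichmentResult:
    """One-sided upper-tail exact binomial outcome: P(X >= k), X~Bin(n, p0)."""

    k: int
    n: int
    p0: float
    p_value: float
    description: str = ""

    @property
    def fraction(self) -> float:
        return self.k / self.n

    def to_row(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "p0": self.p0,
            "fraction": self.fraction,
            "p_value": self.p_value,
            "test": self.description or "one-sided upper-tail exact binomial",
        }


def binomial_upper_tail(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValidationError(f"k={k} outside [0, n={n}]")
    if not (0.0 <= p0 <= 1.0):
        raise ValidationError(f"p0={p0} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p0))


def motif_enrichment(
    foreground_utrs: Sequence[str],
    background_utrs: Sequence[str],
    q: MotifQuery | None = None,
) -> EnrichmentResult:
    """Motif-presence enrichment of foreground UTRs over background UTRs.

    The background fraction containing the motif is the null probability.
    """
    q = q or MotifQuery()
    if not foreground_utrs or not background_utrs:
        raise ValidationError("foreground and background must be non-empty")
    k = sum(utr_has_motif(s, q) for s in foreground_utrs)
    n = len(foreground_utrs)
    p0 = sum(utr_has_motif(s, q) for s in background_utrs) / len(background_utrs)
    return EnrichmentResult(
        k=k, n=n, p0=p0,
        p_value=binomial_upper_tail(k, n, p0),
        description=f"motif {q.motif} presence in 5'UTRs",
    )


# ---------------------------------------------------------------------------
# PWM scanning


@dataclass(frozen=True)
class Pwm:
    """Position weight matrix with per-position scores for A, C, G, T.

    ``threshold_fraction`` sets the site cut-off at a fraction of the
    maximum attainable score.  Two threshold conventions are supported:
    ``absolute`` compares raw window scores against
    threshold_fraction * max_score; ``minmax`` rescales window scores to
    [0, 1] between the minimum and maximum attainable score first (useful
    when the matrix holds log-odds with negative entries).
    """

    scores: np.ndarray  # shape (width, 4), column order A C G T
    threshold_fraction: float = 0.70
    threshold_mode: str = "absolute"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 2 or scores.shape[1] != 4 or scores.shape[0] < 1:
            raise ValidationError("PWM scores must have shape (width, 4)")
        if self.threshold_mode not in ("absolute", "minmax"):
            raise ValidationError("threshold_mode must be 'absolute' or 'minmax'")
        if not (0 < self.threshold_fraction <= 1):
            raise ValidationError("threshold_fraction must be in (0, 1]")
        object.__setattr__(self, "scores", scores)

    @property
    def width(self) -> int:
        return int(self.scores.shape[0])

    @property
    def max_score(self) -> float:
        return float(self.scores.max(axis=1).sum())

    @property
    def min_score(self) -> float:
        return float(self.scores.min(axis=1).sum())

    @property
    def score_threshold(self) -> float:
        """Cut-off on the raw window-score scale."""
        if self.threshold_mode == "absolute":
            return self.threshold_fraction * self.max_score
        lo, hi = self.min_score, self.max_score
        return lo + self.threshold_fraction * (hi - lo)

    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.scores.argmax(axis=1))

    def score_window(self, window: str) -> float:
        """Score one window; any base outside A/C/G/T scores -inf."""
        window = _normalize_seq(window)
        if len(window) != self.width:
            raise ValidationError(f"window length {len(window)} != PWM width {self.width}")
        total = 0.0
        for pos, base in enumerate(window):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return float("-inf")
            total += self.scores[pos, idx]
        return total

    @classmethod
    def from_counts(
        cls,
        counts: np.ndarray,
        pseudocount: float = 1.0,
        threshold_fraction: float = 0.70,
        threshold_mode: str = "absolute",
    ) -> "Pwm":
        """Log2-odds matrix from base counts against a uniform background."""
        counts = np.asarray(counts, dtype=float)
        if np.any(counts < 0):
            raise ValidationError("counts must be non-negative")
        freq = (counts + pseudocount) / (counts + pseudocount).sum(axis=1, keepdims=True)
        return cls(
            scores=np.log2(freq / 0.25),
            threshold_fraction=threshold_fraction,
            threshold_mode=threshold_mode,
        )


@dataclass(frozen=True)
class PwmSite:
    """A PWM match; ``position`` is the leftmost base on the forward strand."""

    seq_id: str
    position: int
    strand: str
    score: float
    assigned_gene: str | None = None


def _encode(residues: str) -> np.ndarray:
    codes = np.full(len(residues), 4, dtype=np.int8)
    arr = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def _window_scores(codes: np.ndarray, pwm: Pwm) -> np.ndarray:
    """Score every forward window; windows touching an N get -inf."""
    w, L = pwm.width, codes.shape[0]
    n_win = L - w + 1
    if n_win <= 0:
        return np.empty(0)
    # 5th column swallows N with -inf
    table = np.concatenate([pwm.scores, np.full((w, 1), -np.inf)], axis=1)
    total = np.zeros(n_win)
    for j in range(w):
        total += table[j, codes[j : j + n_win]]
    return total


def scan_pwm(genome: GenomeSequence, pwm: Pwm) -> list[PwmSite]:
    """All windows on both strands scoring at or above the threshold.

    Minus-strand windows are scored on the reverse complement; their
    reported position is the leftmost base of the match on the forward
    strand.  Sites are sorted by position then strand.
    """
    if genome.length < pwm.width:
        return []
    threshold = pwm.score_threshold
    sites: list[PwmSite] = []
    fwd = _encode(genome.residues)
    fwd_scores = _window_scores(fwd, pwm)
    for pos in np.flatnonzero(fwd_scores >= threshold):
        sites.append(PwmSite(genome.seq_id, int(pos), "+", float(fwd_scores[pos])))
    rev = _encode(reverse_complement(genome.residues))
    rev_scores = _window_scores(rev, pwm)
    for rpos in np.flatnonzero(rev_scores >= threshold):
        pos = genome.length - int(rpos) - pwm.width
        sites.append(PwmSite(genome.seq_id, pos, "-", float(rev_scores[rpos])))
    sites.sort(key=lambda s: (s.position, s.strand))
    return sites


def assign_sites_to_genes(
    sites: Sequence[PwmSite],
    annotations: Sequence[GeneAnnotation],
    upstream_window: int = 250,
    site_width: int | None = None,
) -> tuple[list[PwmSite], dict[str, bool]]:
    """Assign each site to the closest gene whose upstream promoter window
    contains it.

    A gene's window is the ``upstream_window`` nt immediately upstream of
    its ATG (strand-aware, ATG excluded).  Distance is measured from the
    site base nearest the ATG; ties go to the lexicographically smaller
    gene_id.  Returns the updated sites plus per-gene has-site flags.
    """
    width = site_width if site_width is not None else 1
    has_site = {g.gene_id: False for g in annotations}
    assigned: list[PwmSite] = []
    genes = sorted(annotations, key=lambda g: g.gene_id)
    for site in sites:
        w = width
        best: tuple[int, str] | None = None
        for gene in genes:
            if gene.seq_id != site.seq_id:
                continue
            if gene.strand == "+":
                # window [ATG - upstream, ATG); nearest site base is its right end
                near = site.position + w - 1
                if gene.start - upstream_window <= near < gene.start:
                    dist = gene.start - near
                else:
                    continue
            else:
                atg = gene.end - 1
                near = site.position
                if atg < near <= atg + upstream_window:
                    dist = near - atg
                else:
                    continue
            if best is None or (dist, gene.gene_id) < best:
                best = (dist, gene.gene_id)
        if best is not None:
            assigned.append(replace(site, assigned_gene=best[1]))
            has_site[best[1]] = True
        else:
            assigned.append(site)
    return assigned, has_site


def site_set_enrichment(
    gene_set: Iterable[str],
    all_genes: Iterable[str],
    has_site: Mapping[str, bool],
    description: str = "TF box presence",
) -> EnrichmentResult:
    """Enrichment of TF-box-bearing genes in a gene set over all genes."""
    gene_set = sorted(set(gene_set))
    universe = sorted(set(all_genes))
    if not gene_set:
        raise ValidationError("gene_set is empty")
    missing = set(gene_set) - set(universe)
    if missing:
        raise ValidationError(f"gene_set members outside universe: {sorted(missing)[:3]}")
    k = sum(bool(has_site.get(g, False)) for g in gene_set)
    n = len(gene_set)
    p0 = sum(bool(has_site.get(g, False)) for g in universe) / len(universe)
    return EnrichmentResult(
        k=k, n=n, p0=p0,
        p_value=binomial_upper_tail(k, n, p0),
        description=description,
    )


# ---------------------------------------------------------------------------
# PWM file format: TSV with header A C G T, one row per position


def read_pwm(
    path: str | Path,
    kind: str = "scores",
    pseudocount: float = 1.0,
    threshold_fraction: float = 0.70,
    threshold_mode: str = "absolute",
) -> Pwm:
    df = pd.read_csv(path, sep="\t")
    cols = [c.upper() for c in df.columns]
    if cols[:4] != list(_BASES) and sorted(cols) != sorted(_BASES):
        raise ValidationError(f"{path}: PWM must have columns A, C, G, T")
    matrix = df[[c for c in df.columns]].to_numpy(dtype=float)
    order = [cols.index(b) for b in _BASES]
    matrix = matrix[:, order]
    if kind == "counts":
        return Pwm.from_counts(matrix, pseudocount=pseudocount,
                               threshold_fraction=threshold_fraction,
                               threshold_mode=threshold_mode)
    if kind != "scores":
        raise ValidationError("PWM kind must be 'counts' or 'scores'")
    return Pwm(scores=matrix, threshold_fraction=threshold_fraction,
               threshold_mode=threshold_mode)


def write_pwm(pwm: Pwm, path: str | Path) -> None:
    pd.DataFrame(pwm.scores, columns=list(_BASES)).to_csv(path, sep="\t", index=False)


def sites_to_bed6(sites: Sequence[PwmSite], width: int, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            name = s.assigned_gene or "."
            fh.write(f"{s.seq_id}\t{s.position}\t{s.position + width}\t{name}\t{s.score:.4f}\t{s.strand}\n")
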
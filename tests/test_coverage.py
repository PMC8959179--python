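"""Strand-aware region coverage and the ratio/floor candidate caller."""

import math
from fractions import Fraction

import numpy as np
import pytest

from mapscall.coverage import (
    CandidateCall,
    MapsCallerConfig,
    OrientationProtocol,
    RegionCoverage,
    call_candidates,
    classify_pair_orientation,
    compute_region_coverages,
    coverage_from_alignments,
    nearest_rank_quantile,
    region_coverage,
)
from mapscall.genome_io import (
    CoverageTrack,
    GenomeSequence,
    Orientation,
    ValidationError,
)
from mapscall.regions import Region, RegionKind


def _region(gid, start, end, strand="+", kind=RegionKind.BODY):
    return Region(gid, kind, "chr", start, end, strand)


def _tracks(plus, minus, total):
    return {
        Orientation.PLUS_SET: CoverageTrack("chr", np.asarray(plus, float),
                                            Orientation.PLUS_SET, total),
        Orientation.MINUS_SET: CoverageTrack("chr", np.asarray(minus, float),
                                             Orientation.MINUS_SET, total),
    }


class TestFlagClassifier:
    @pytest.mark.parametrize("flag", [99, 147])
    def test_forward_pairs(self, flag):
        assert classify_pair_orientation(flag) is Orientation.PLUS_SET

    @pytest.mark.parametrize("flag", [83, 163])
    def test_reverse_pairs(self, flag):
        assert classify_pair_orientation(flag) is Orientation.MINUS_SET

    @pytest.mark.parametrize("flag", [0, 4, 16, 77, 97, 145, 355, 1123, 2048])
    def test_everything_else_excluded(self, flag):
        assert classify_pair_orientation(flag) is Orientation.EXCLUDED

    def test_negative_flag_rejected(self):
        with pytest.raises(ValidationError):
            classify_pair_orientation(-1)


class TestRegionCoverage:
    def test_sum_and_rpm(self):
        values = np.zeros(30)
        values[10:13] = 5.0
        tracks = _tracks(values, np.zeros(30), 2e6)
        rc = region_coverage(_region("g", 10, 13), tracks)
        assert rc.raw_sum == 15.0 and rc.rpm == pytest.approx(7.5)

    def test_all_zero_track(self):
        rc = region_coverage(_region("g", 0, 10), _tracks(np.zeros(30), np.zeros(30), 1e6))
        assert rc.raw_sum == 0.0 and rc.rpm == 0.0

    def test_minus_region_reads_minus_track_only(self):
        plus = np.full(30, 100.0)
        minus = np.zeros(30)
        minus[5:10] = 2.0
        rc = region_coverage(_region("g", 5, 10, strand="-"), _tracks(plus, minus, 1e6))
        assert rc.raw_sum == 10.0

    def test_flipped_protocol(self):
        plus = np.full(20, 3.0)
        minus = np.zeros(20)
        protocol = OrientationProtocol(plus_strand=Orientation.MINUS_SET,
                                       minus_strand=Orientation.PLUS_SET)
        rc = region_coverage(_region("g", 0, 10, strand="-"), _tracks(plus, minus, 1e6),
                             protocol)
        assert rc.raw_sum == 30.0

    def test_region_outside_track_rejected(self):
        with pytest.raises(ValidationError):
            region_coverage(_region("g", 25, 40), _tracks(np.zeros(30), np.zeros(30), 1e6))


def _cov(gid, rpm, kind=RegionKind.BODY, start=0, end=10):
    region = _region(gid, start, end, kind=kind)
    return RegionCoverage(region=region, raw_sum=rpm, rpm=rpm)


class TestCaller:
    def test_fourfold_boundary_is_inclusive(self):
        cfg = MapsCallerConfig(pseudocount_rpm=0.0)
        ms = [_cov("a", 400.0), _cov("b", 390.0, kind=RegionKind.UTR5)]
        control = [_cov("a", 100.0), _cov("b", 100.0, kind=RegionKind.UTR5)]
        calls, _ = call_candidates(ms, control, cfg)
        by_gene = {c.gene_id: c for c in calls}
        assert by_gene["a"].log2_ratio == pytest.approx(2.0)
        assert by_gene["a"].passed_ratio
        assert by_gene["b"].log2_ratio == pytest.approx(math.log2(3.9))
        assert not by_gene["b"].passed_ratio

    def test_quantile_floor_is_strict_nearest_rank(self):
        cfg = MapsCallerConfig(pseudocount_rpm=0.0)
        ms = [_cov(g, v) for g, v in zip("abcd", (10.0, 20.0, 30.0, 40.0))]
        control = [_cov(g, 1.0) for g in "abcd"]
        calls, _ = call_candidates(ms, control, cfg)
        floor_flags = {c.gene_id: c.passed_floor for c in calls}
        assert floor_flags == {"a": False, "b": True, "c": True, "d": True}

    def test_pseudocount_keeps_zero_control_finite(self):
        cfg = MapsCallerConfig(pseudocount_rpm=1.0)
        calls, _ = call_candidates([_cov("a", 30.0)], [_cov("a", 0.0)], cfg)
        assert calls[0].log2_ratio == pytest.approx(math.log2(31.0))
        assert calls[0].passed_ratio

    def test_gene_candidacy_is_or_of_regions(self):
        cfg = MapsCallerConfig(pseudocount_rpm=0.0)
        ms = [
            _cov("a", 400.0, kind=RegionKind.UTR5),
            _cov("a", 10.0, kind=RegionKind.BODY),
            _cov("a", 10.0, kind=RegionKind.UTR3),
            _cov("b", 10.0, kind=RegionKind.UTR5),
            _cov("b", 11.0, kind=RegionKind.BODY),
            _cov("b", 12.0, kind=RegionKind.UTR3),
        ]
        control = [
            _cov("a", 10.0, kind=RegionKind.UTR5),
            _cov("a", 10.0, kind=RegionKind.BODY),
            _cov("a", 10.0, kind=RegionKind.UTR3),
            _cov("b", 10.0, kind=RegionKind.UTR5),
            _cov("b", 10.0, kind=RegionKind.BODY),
            _cov("b", 10.0, kind=RegionKind.UTR3),
        ]
        calls, genes = call_candidates(ms, control, cfg)
        region_flags = [c.is_candidate_region for c in calls if c.gene_id == "a"]
        assert genes == {"a"} and any(region_flags) and not all(region_flags)

    def test_mismatched_region_sets_rejected(self):
        with pytest.raises(ValidationError):
            call_candidates([_cov("a", 1.0)], [_cov("b", 1.0)])

    def test_depth_rescaling_invariance_without_pseudocount(self):
        """RPM cancels library depth: scaling raw counts changes nothing."""
        rng = np.random.default_rng(7)
        plus = rng.poisson(5.0, 500).astype(float)
        minus = rng.poisson(5.0, 500).astype(float)
        regions = [_region(f"g{i}", i * 50, i * 50 + 40) for i in range(10)]
        cfg = MapsCallerConfig(pseudocount_rpm=0.0)

        def calls_at(scale):
            ms = [region_coverage(r, _tracks(plus * scale, minus * scale, 1e5 * scale))
                  for r in regions]
            ctrl = [region_coverage(r, _tracks(plus, minus, 1e5)) for r in regions]
            calls, _ = call_candidates(ms, ctrl, cfg)
            return [(c.passed_ratio, c.passed_floor) for c in calls]

        assert calls_at(1.0) == calls_at(7.0) == calls_at(0.3)

    def test_raising_ms_coverage_never_unsets_flags_at_frozen_floor(self):
        cfg = MapsCallerConfig(pseudocount_rpm=1.0)
        ms = [_cov(g, v) for g, v in zip("abcde", (5.0, 40.0, 60.0, 80.0, 100.0))]
        control = [_cov(g, 10.0) for g in "abcde"]
        base_calls, _ = call_candidates(ms, control, cfg)
        floor = nearest_rank_quantile([c.ms_rpm for c in base_calls], cfg.coverage_quantile)
        for bump in (1.0, 10.0, 1000.0):
            bumped = [_cov("c", 60.0 + bump)] + [c for c in ms if c.region.gene_id != "c"]
            calls, _ = call_candidates(bumped, control, cfg)
            target = next(c for c in calls if c.gene_id == "c")
            base = next(c for c in base_calls if c.gene_id == "c")
            assert target.passed_ratio >= base.passed_ratio
            assert (target.ms_rpm > floor) >= (base.ms_rpm > floor)


def _oracle_calls(ms_raw, ctrl_raw, ms_total, ctrl_total, pc=Fraction(1)):
    """Exact-rational reference for the ratio/floor caller (4-fold, Q1)."""
    ms_rpm = [Fraction(int(v)) * 10**6 / ms_total for v in ms_raw]
    ctrl_rpm = [Fraction(int(v)) * 10**6 / ctrl_total for v in ctrl_raw]
    ranked = sorted(ms_rpm)
    rank = math.ceil(Fraction(1, 4) * len(ranked))
    floor = ranked[max(rank, 1) - 1]
    out = []
    for m, c in zip(ms_rpm, ctrl_rpm):
        passed_ratio = (m + pc) >= 4 * (c + pc)
        out.append((passed_ratio, m > floor))
    return out


def test_caller_matches_exact_arithmetic_reference():
    """Float caller decisions equal an exact-rational recomputation."""
    rng = np.random.default_rng(99)
    for _ in range(50):
        n = int(rng.integers(2, 21))
        ms_raw = rng.integers(0, 5000, n)
        ctrl_raw = rng.integers(0, 5000, n)
        ms_total, ctrl_total = int(rng.integers(10**4, 10**6)), int(rng.integers(10**4, 10**6))
        regions = [_region(f"g{i:02d}", i * 10, i * 10 + 5) for i in range(n)]
        ms = [RegionCoverage(r, float(v), float(v) * 1e6 / ms_total)
              for r, v in zip(regions, ms_raw)]
        ctrl = [RegionCoverage(r, float(v), float(v) * 1e6 / ctrl_total)
                for r, v in zip(regions, ctrl_raw)]
        calls, _ = call_candidates(ms, ctrl, MapsCallerConfig(pseudocount_rpm=1.0))
        got = [(c.passed_ratio, c.passed_floor) for c in calls]
        expected = _oracle_calls(ms_raw, ctrl_raw, ms_total, ctrl_total)
        assert got == expected


def test_coverage_from_alignments_tiny_sam(tmp_path):
    """Paired SAM records build stranded tracks; other flags are ignored."""
    sam = tmp_path / "tiny.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr\tLN:50\n"
        "r2b\t163\tchr\t5\t60\t5M\t=\t21\t21\tAAAAA\t*\n"
        "r1a\t99\tchr\t11\t60\t5M\t=\t31\t25\tAAAAA\t*\n"
        "r2a\t83\tchr\t21\t60\t5M\t=\t5\t-21\tAAAAA\t*\n"
        "r1b\t147\tchr\t31\t60\t5M\t=\t11\t-25\tAAAAA\t*\n"
        "r3\t77\t*\t0\t0\t*\t*\t0\t0\tAAAAA\t*\n"
    )
    genome = GenomeSequence("chr", "A" * 50)
    tracks = coverage_from_alignments(sam, genome)
    plus = tracks[Orientation.PLUS_SET]
    minus = tracks[Orientation.MINUS_SET]
    assert plus.library_total == 2 and minus.library_total == 2
    assert plus.values.sum() == 10 and minus.values.sum() == 10
    assert list(np.flatnonzero(plus.values)) == list(range(10, 15)) + list(range(30, 35))
    assert list(np.flatnonzero(minus.values)) == list(range(4, 9)) + list(range(20, 25))
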
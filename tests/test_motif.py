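"""Seed-motif presence/enrichment, the exact binomial tail, and PWM scanning."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from mapscall.genome_io import GeneAnnotation, GenomeSequence, ValidationError
from mapscall.motif import (
    MotifQuery,
    Pwm,
    assign_sites_to_genes,
    binomial_upper_tail,
    count_motif_occurrences,
    loop_complement_motif,
    motif_enrichment,
    read_pwm,
    sample_background_utrs,
    scan_pwm,
    site_set_enrichment,
    utr_has_motif,
    write_pwm,
)
from mapscall.regions import RegionKind, RegionRules, build_region_set

GGGG = MotifQuery()


class TestMotifPresence:
    @pytest.mark.parametrize(
        "seq, expected",
        [("AAGGGGTT", True), ("AGGGT", False), ("GGGGGG", True), ("auggggua", True)],
    )
    def test_presence(self, seq, expected):
        assert utr_has_motif(seq, GGGG) is expected

    def test_overlapping_occurrences_counted(self):
        assert count_motif_occurrences("GGGGGG", GGGG) == 3
        assert count_motif_occurrences("GGGGAAGGGG", GGGG) == 2

    def test_loop_complement(self):
        assert loop_complement_motif("AACCCCAA", (2, 6)).motif == "GGGG"
        assert loop_complement_motif("AUGC", (0, 4)).motif == "GCAT"
        with pytest.raises(ValidationError):
            loop_complement_motif("ACGT", (2, 2))

    def test_empty_motif_rejected(self):
        with pytest.raises(ValidationError):
            MotifQuery(motif="")


def _binomial_tail_oracle(k, n, p0: Fraction) -> Fraction:
    """Direct summation with exact rationals."""
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0**i * (1 - p0) ** (n - i)
    return total


class TestBinomialTail:
    def test_zero_successes_gives_one(self):
        assert binomial_upper_tail(0, 50, 0.3) == 1.0

    def test_all_successes_power(self):
        assert binomial_upper_tail(3, 3, 0.5) == pytest.approx(0.125)

    @pytest.mark.parametrize(
        "k, n, p0",
        [
            (10, 20, Fraction(1, 4)),
            (3, 17, Fraction(1, 3)),
            (60, 200, Fraction(3, 10)),
            (199, 200, Fraction(9, 10)),
            (1, 200, Fraction(1, 100)),
        ],
    )
    def test_matches_exact_rational_summation(self, k, n, p0):
        expected = _binomial_tail_oracle(k, n, p0)
        got = binomial_upper_tail(k, n, float(p0))
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            binomial_upper_tail(5, 3, 0.5)
        with pytest.raises(ValidationError):
            binomial_upper_tail(1, 3, 1.5)


class TestMotifEnrichment:
    def test_planted_enrichment(self):
        fg = ["AAGGGGAA"] * 10
        bg = ["AAGGGGAA"] + ["AACCTTAA"] * 9  # background fraction 0.1
        res = motif_enrichment(fg, bg, GGGG)
        assert (res.k, res.n, res.p0) == (10, 10, 0.1)
        assert res.p_value == pytest.approx(0.1**10)

    def test_no_motif_gives_p_one(self):
        res = motif_enrichment(["AAAA"] * 5, ["GGGG", "AAAA"], GGGG)
        assert res.k == 0 and res.p_value == 1.0 and res.fraction == 0.0

    def test_matched_fractions_not_significant(self):
        fg = ["AAGGGGAA"] * 30 + ["AACCTTAA"] * 70
        bg = ["AAGGGGAA"] * 30 + ["AACCTTAA"] * 70
        assert motif_enrichment(fg, bg, GGGG).p_value > 0.05

    def test_empty_collections_rejected(self):
        with pytest.raises(ValidationError):
            motif_enrichment([], ["ACGT"], GGGG)


class TestBackgroundSampling:
    def _region_set(self, random_genome):
        genes = [
            GeneAnnotation(f"g{i}", "chr", 400 + i * 500, 700 + i * 500,
                           "+" if i % 2 else "-")
            for i in range(5)
        ]
        return build_region_set(genes, {}, RegionRules(), random_genome), random_genome

    def test_deterministic_given_seed(self, random_genome):
        rs, genome = self._region_set(random_genome)
        a = sample_background_utrs(rs, genome, 3, seed=42)
        b = sample_background_utrs(rs, genome, 3, seed=42)
        assert a == b

    def test_full_complement_when_n_equals_gene_count(self, random_genome):
        rs, genome = self._region_set(random_genome)
        sample = sample_background_utrs(rs, genome, 5, seed=1)
        from mapscall.regions import region_sequence

        all_utrs = {region_sequence(r, genome) for r in rs if r.kind is RegionKind.UTR5}
        assert set(sample) == all_utrs

    def test_oversampling_without_replacement_rejected(self, random_genome):
        rs, genome = self._region_set(random_genome)
        with pytest.raises(ValidationError):
            sample_background_utrs(rs, genome, 6, seed=1)
        assert len(sample_background_utrs(rs, genome, 6, seed=1, replace_=True)) == 6


def _toy_pwm():
    scores = np.array([[2.0, 0.0, 0.0, 0.0], [0.0, 2.0, 0.0, 0.0]])  # consensus AC
    return Pwm(scores=scores, threshold_fraction=0.70)


class TestPwmScan:
    def test_forward_hand_example(self):
        sites = scan_pwm(GenomeSequence("chr", "AACT"), _toy_pwm())
        fwd = [s for s in sites if s.strand == "+"]
        assert [(s.position, s.score) for s in fwd] == [(1, 4.0)]

    def test_reverse_hand_example(self):
        # revcomp of AGTT is AACT, AC at rc-offset 1 -> forward leftmost 1
        sites = scan_pwm(GenomeSequence("chr", "AGTT"), _toy_pwm())
        rev = [s for s in sites if s.strand == "-"]
        assert [(s.position, s.score) for s in rev] == [(1, 4.0)]

    def test_all_n_genome_has_no_sites(self):
        assert scan_pwm(GenomeSequence("chr", "N" * 100), _toy_pwm()) == []

    def test_raising_threshold_never_adds_sites(self, random_genome):
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(6, 4))
        previous = None
        for frac in (0.5, 0.7, 0.9, 1.0):
            pwm = Pwm.from_counts(counts, threshold_fraction=frac)
            n_sites = len(scan_pwm(random_genome, pwm))
            if previous is not None:
                assert n_sites <= previous
            previous = n_sites

    @pytest.mark.parametrize("mode", ["absolute", "minmax"])
    def test_matches_bruteforce_enumeration(self, random_genome, mode):
        """Vectorized scan equals per-window enumeration on both strands."""
        rng = np.random.default_rng(17)
        counts = rng.integers(0, 40, size=(7, 4))
        pwm = Pwm.from_counts(counts, threshold_fraction=0.8, threshold_mode=mode)
        comp = str.maketrans("ACGT", "TGCA")
        index = {b: i for i, b in enumerate("ACGT")}
        expected = []
        threshold = pwm.score_threshold
        for pos in range(random_genome.length - pwm.width + 1):
            window = random_genome.residues[pos : pos + pwm.width]
            fwd = sum(pwm.scores[j, index[b]] for j, b in enumerate(window))
            rev_window = window.translate(comp)[::-1]
            rev = sum(pwm.scores[j, index[b]] for j, b in enumerate(rev_window))
            if fwd >= threshold:
                expected.append((pos, "+", pytest.approx(fwd)))
            if rev >= threshold:
                expected.append((pos, "-", pytest.approx(rev)))
        got = [(s.position, s.strand, s.score) for s in scan_pwm(random_genome, pwm)]
        assert got == expected

    def test_strand_mirror_symmetry(self, random_genome):
        """Scanning the reverse-complemented genome mirrors the site list."""
        from mapscall.genome_io import reverse_complement

        rng = np.random.default_rng(23)
        pwm = Pwm.from_counts(rng.integers(0, 30, size=(6, 4)), threshold_fraction=0.8)
        L = random_genome.length
        mirrored = GenomeSequence("chr", reverse_complement(random_genome.residues))
        flip = {"+": "-", "-": "+"}
        got = {(s.position, s.strand, round(s.score, 9))
               for s in scan_pwm(mirrored, pwm)}
        expected = {(L - s.position - pwm.width, flip[s.strand], round(s.score, 9))
                    for s in scan_pwm(random_genome, pwm)}
        assert got == expected


class TestSiteAssignment:
    GENES = [
        GeneAnnotation("geneA", "chr", 1000, 2000, "+"),
        GeneAnnotation("geneB", "chr", 3000, 4000, "-"),
    ]

    def _site(self, pos):
        from mapscall.motif import PwmSite

        return PwmSite("chr", pos, "+", 5.0)

    def test_site_in_window_assigned(self):
        assigned, has_site = assign_sites_to_genes([self._site(980)], self.GENES)
        assert assigned[0].assigned_gene == "geneA" and has_site["geneA"]

    def test_site_outside_window_unassigned(self):
        assigned, has_site = assign_sites_to_genes([self._site(700)], self.GENES)
        assert assigned[0].assigned_gene is None and not has_site["geneA"]

    def test_minus_strand_window_is_downstream_in_genome_coordinates(self):
        assigned, has_site = assign_sites_to_genes([self._site(4100)], self.GENES)
        assert assigned[0].assigned_gene == "geneB"

    def test_equidistant_tie_broken_lexicographically(self):
        genes = [
            GeneAnnotation("geneZ", "chr", 1000, 2000, "+"),
            GeneAnnotation("geneY", "chr", 500, 940, "-"),
        ]
        # ATGs at 1000 (+, window [750,1000)) and 939 (-, window (939,1189])
        assigned, _ = assign_sites_to_genes([self._site(969)], genes)
        # distances: geneZ 1000-969=31; geneY 969-939=30 -> geneY closer
        assert assigned[0].assigned_gene == "geneY"
        assigned, _ = assign_sites_to_genes([self._site(970)], genes)
        # distances: 30 vs 31 -> geneZ
        assert assigned[0].assigned_gene == "geneZ"
        genes_tied = [
            GeneAnnotation("b_gene", "chr", 1000, 2000, "+"),
            GeneAnnotation("a_gene", "chr", 500, 941, "-"),
        ]
        # ATGs at 1000 and 940; site 970 is 30 from both
        assigned, _ = assign_sites_to_genes([self._site(970)], genes_tied)
        assert assigned[0].assigned_gene == "a_gene"

    def test_site_width_moves_nearest_base(self):
        site = self._site(700)
        assigned, _ = assign_sites_to_genes([site], self.GENES, site_width=60)
        # nearest base 759 lies in [750, 1000) -> assigned
        assert assigned[0].assigned_gene == "geneA"


class TestSiteSetEnrichment:
    def test_all_members_with_sites(self):
        universe = [f"g{i}" for i in range(50)]
        has_site = {g: i < 10 for i, g in enumerate(universe)}
        res = site_set_enrichment(universe[:10], universe, has_site)
        assert (res.k, res.n, res.p0) == (10, 10, 0.2)
        assert res.p_value == pytest.approx(0.2**10)

    def test_whole_universe_is_null(self):
        universe = [f"g{i}" for i in range(200)]
        has_site = {g: i % 5 == 0 for i, g in enumerate(universe)}
        assert site_set_enrichment(universe, universe, has_site).p_value > 0.4

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            site_set_enrichment([], ["g1"], {})


class TestPwmIO:
    def test_round_trip_scores(self, tmp_path):
        pwm = _toy_pwm()
        path = tmp_path / "pwm.tsv"
        write_pwm(pwm, path)
        loaded = read_pwm(path, kind="scores")
        np.testing.assert_allclose(loaded.scores, pwm.scores)

    def test_counts_become_log_odds(self, tmp_path):
        path = tmp_path / "counts.tsv"
        pd.DataFrame({"A": [97], "C": [1], "G": [1], "T": [1]}).to_csv(
            path, sep="\t", index=False)
        pwm = read_pwm(path, kind="counts", pseudocount=1.0)
        assert pwm.consensus() == "A"
        assert pwm.scores[0, 0] == pytest.approx(math.log2((98 / 104) / 0.25))

    def test_bad_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"A": [1], "C": [1]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValidationError):
            read_pwm(path)
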
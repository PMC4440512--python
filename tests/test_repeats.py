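import itertools
import math

import numpy as np
import pytest

from alumeth.digestion import Fragment
from alumeth.formats import RepeatAnnotation
from alumeth.repeats import (AluClass, RepeatIndex, classify_subfamily,
                             composition, enrichment_test,
                             loci_fragment_overlap, sweep_variance)


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability is <= the observed table's (relative tolerance 1e-7 for
    floating-point ties).
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (math.comb(r1, x) * math.comb(r2, c1 - x)
                / math.comb(n, c1))

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1)
               if prob(x) <= p_obs * (1 + 1e-7))


class TestClassify:
    @pytest.mark.parametrize("name,family,expected", [
        ("AluYa5", "Alu", AluClass.ALU_Y),
        ("AluY", "Alu", AluClass.ALU_Y),
        ("AluSx1", "Alu", AluClass.ALU_S),
        ("AluJb", "Alu", AluClass.ALU_J),
        ("FLAM_A", "Alu", AluClass.ALU_OTHER),
        ("FRAM", "Alu", AluClass.ALU_OTHER),
        ("L1PA3", "L1", AluClass.NON_ALU),
        ("AluYa5", "L1", AluClass.NON_ALU),
    ])
    def test_name_prefix_rule(self, name, family, expected):
        assert classify_subfamily(name, family) is expected

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            classify_subfamily("", "Alu")


class TestComposition:
    @pytest.fixture()
    def repeats(self):
        return [
            RepeatAnnotation("c", 100, 400, "+", "AluYa5", "Alu"),
            RepeatAnnotation("c", 600, 900, "+", "AluYb8", "Alu"),
            RepeatAnnotation("c", 1100, 1400, "-", "AluYk11", "Alu"),
            RepeatAnnotation("c", 1600, 1900, "+", "AluSx", "Alu"),
            RepeatAnnotation("c", 2100, 2400, "+", "L1PA2", "L1"),
        ]

    def test_counts_by_construction(self, repeats):
        inside = [Fragment("c", s, s + 50) for s in (150, 650, 1150, 1650)]
        outside = [Fragment("c", s, s + 50) for s in
                   (0, 450, 950, 1450, 1950, 2150)]  # last is L1, not Alu
        summary = composition(inside + outside, repeats)
        assert summary.n_items == 10
        assert summary.fraction_alu == pytest.approx(0.4)
        assert summary.subfamily_fractions[AluClass.ALU_Y] == pytest.approx(0.75)
        assert summary.subfamily_fractions[AluClass.ALU_S] == pytest.approx(0.25)

    def test_no_repeats_loaded(self):
        summary = composition([("c", 5, "+", "CpG")], [])
        assert summary.fraction_alu == 0.0

    def test_empty_items_flagged_undefined(self, repeats):
        summary = composition([], repeats)
        assert summary.n_items == 0
        assert summary.fraction_alu is None

    def test_largest_overlap_wins_ties_leftmost(self):
        repeats = [RepeatAnnotation("c", 0, 100, "+", "AluY", "Alu"),
                   RepeatAnnotation("c", 100, 200, "+", "AluSx", "Alu")]
        # fragment overlaps AluY by 60 bp and AluSx by 40 bp
        s = composition([Fragment("c", 40, 140)], repeats)
        assert s.subfamily_counts[AluClass.ALU_Y] == 1
        # exact tie: leftmost annotation (AluY) wins
        s = composition([Fragment("c", 50, 150)], repeats)
        assert s.subfamily_counts[AluClass.ALU_Y] == 1

    def test_order_invariance(self, repeats):
        frags = [Fragment("c", s, s + 80) for s in range(0, 2400, 90)]
        a = composition(frags, repeats)
        b = composition(frags[::-1], repeats[::-1])
        assert a.n_alu == b.n_alu
        assert a.subfamily_counts == b.subfamily_counts

    def test_point_loci_containment(self, repeats):
        loci = [("c", 150, "+", "CpG"), ("c", 50, "+", "CpG")]
        summary = composition(loci, repeats)
        assert summary.n_alu == 1


class TestEnrichment:
    def test_diagonal_table(self):
        assert enrichment_test([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_balanced_table(self):
        assert enrichment_test([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_margins(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            a, b, c, d = rng.integers(0, 9, size=4)
            if a + b + c + d == 0:
                continue
            assert enrichment_test([[a, b], [c, d]]) == pytest.approx(
                fisher_enumeration_oracle(a, b, c, d), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            enrichment_test([[0, 0], [0, 0]])


def _summary(frac_alu, frac_y):
    from alumeth.repeats import CompositionSummary
    n = 1000
    n_alu = round(n * frac_alu)
    return CompositionSummary(
        n_items=n, n_alu=n_alu,
        subfamily_counts={AluClass.ALU_Y: round(n_alu * frac_y),
                          AluClass.ALU_S: n_alu - round(n_alu * frac_y),
                          AluClass.ALU_J: 0, AluClass.ALU_OTHER: 0})


class TestSweepVariance:
    def test_constant_input_zero_variance(self):
        sv = sweep_variance([_summary(0.3, 0.4)] * 4)
        assert sv.variance == 0.0
        assert sv.range == 0.0

    def test_direct_formula(self):
        sv = sweep_variance([_summary(0.2, 0.5), _summary(0.4, 0.5)])
        assert sv.range == pytest.approx(0.2)
        assert sv.variance == pytest.approx(0.02)

    def test_variance_ratio_direction(self):
        windows = [_summary(0.30, 0.5), _summary(0.31, 0.5)]
        samples = [_summary(0.1, 0.5), _summary(0.6, 0.5),
                   _summary(0.35, 0.5)]
        sv = sweep_variance(windows, other=samples)
        assert sv.variance_ratio > 1

    def test_requires_two_summaries(self):
        with pytest.raises(ValueError):
            sweep_variance([_summary(0.3, 0.4)])


class TestLociFragmentOverlap:
    def test_toy_partition(self):
        frac, inside, outside = loci_fragment_overlap(
            [("c", 5, "+", "CpG"), ("c", 50, "+", "CpG")],
            [Fragment("c", 0, 10)])
        assert frac == 0.5
        assert len(inside) == 1 and len(outside) == 1

    def test_all_inside(self):
        loci = [("c", i, "+", "CpG") for i in range(5)]
        frac, inside, outside = loci_fragment_overlap(loci, [Fragment("c", 0, 10)])
        assert frac == 1.0 and not outside

    def test_empty_fragments(self):
        loci = [("c", 1, "+", "CpG")]
        frac, inside, outside = loci_fragment_overlap(loci, [])
        assert frac == 0.0 and outside == loci

    def test_partition_sizes_sum(self):
        rng = np.random.default_rng(0)
        loci = [("c", int(p), "+", "CpG") for p in rng.integers(0, 1000, 200)]
        frags = [Fragment("c", int(s), int(s) + 30)
                 for s in rng.integers(0, 1000, 20)]
        frac, inside, outside = loci_fragment_overlap(loci, frags)
        assert len(inside) + len(outside) == len(loci)
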
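import numpy as np
import pytest

from alumeth.digestion import SizeWindow, digest, size_select
from alumeth.repeats import AluClass, RepeatIndex, classify_subfamily
from alumeth.sets import call_context
from alumeth.synthetic import (GenomeDesign, MethylomeDesign,
                               generate_genome, generate_methylomes,
                               generate_read_intervals, stage_rng)


SMALL = dict(n_chroms=1, chrom_length=40_000, alu_fragment_share=None)


class TestGenerateGenome:
    def test_deterministic_under_seed(self):
        a = generate_genome(GenomeDesign(seed=5, **SMALL, n_alu_insertions=6))
        b = generate_genome(GenomeDesign(seed=5, **SMALL, n_alu_insertions=6))
        assert a[0].sequences == b[0].sequences
        assert a[1] == b[1]

    def test_different_seeds_differ(self):
        a = generate_genome(GenomeDesign(seed=5, **SMALL, n_alu_insertions=6))
        b = generate_genome(GenomeDesign(seed=6, **SMALL, n_alu_insertions=6))
        assert a[0].sequences != b[0].sequences

    def test_zero_insertions_empty_annotation(self):
        genome, repeats, genes, _ = generate_genome(
            GenomeDesign(seed=1, **SMALL, n_alu_insertions=0))
        assert repeats == []
        assert len(genes) > 0

    def test_degenerate_mix_all_y(self):
        design = GenomeDesign(seed=2, n_chroms=2, chrom_length=150_000,
                              alu_fragment_share=None, n_alu_insertions=50,
                              subfamily_mix={"Y": 1.0, "S": 0.0, "J": 0.0})
        _, repeats, _, _ = generate_genome(design)
        assert len(repeats) == 50
        assert all(classify_subfamily(r.rep_name, r.rep_family)
                   is AluClass.ALU_Y for r in repeats)

    def test_annotations_within_genome(self, planted_genome):
        genome, repeats, _, _ = planted_genome
        for r in repeats:
            assert 0 <= r.start < r.end <= genome.length(r.chrom)
            assert r.end - r.start == 300

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            GenomeDesign(subfamily_mix={"Y": 0.9, "S": 0.3, "J": 0.2})
        with pytest.raises(ValueError, match="TSD"):
            GenomeDesign(tsd_length=30)

    def test_element_bodies_host_selected_fragments(self, planted_genome):
        genome, repeats, _, truth = planted_genome
        selected = size_select(digest(genome), SizeWindow(40, 300))
        planted = {r.key: int(r.value)
                   for r in truth.of_kind("alu-interior-fragments")}
        for rep in repeats[:20]:
            inside = [f for f in selected
                      if f.chrom == rep.chrom and f.start >= rep.start
                      and f.end <= rep.end]
            assert len(inside) == planted[f"{rep.chrom}:{rep.start}-{rep.end}"]


@pytest.fixture(scope="module")
def generated(plain_genome):
    design = MethylomeDesign(seed=3, n_baseline_loci=300,
                             n_unique_loci=40, n_entropy_loci=20,
                             n_predictive_loci=20)
    samples, truth = generate_methylomes(plain_genome, design)
    return design, samples, truth


class TestGenerateMethylomes:
    def test_layout(self, generated):
        design, samples, _ = generated
        assert len(samples) == 9 + 14
        assert set(design.clinical_labels().values()) == {"benefit",
                                                          "no_benefit"}

    def test_contexts_match_genome(self, plain_genome, generated):
        _, samples, _ = generated
        sample = next(iter(samples.values()))
        for rec in sample.records[:100]:
            assert call_context(plain_genome, rec.chrom, rec.pos,
                                rec.strand) == rec.context

    def test_unique_loci_covered_only_in_their_group(self, generated):
        design, samples, truth = generated
        groups = design.cell_line_samples()
        for rec in truth.of_kind("unique-locus"):
            chrom, pos, strand, ctx = rec.key.split("|")
            key = (chrom, int(pos), strand, ctx)
            for group, sids in groups.items():
                for sid in sids:
                    by_key = {(r.chrom, r.pos, r.strand, r.context): r
                              for r in samples[sid]}
                    covered = by_key[key].covered
                    assert covered == (group == rec.value)

    def test_zero_coverage_design(self, plain_genome):
        design = MethylomeDesign(seed=1, n_baseline_loci=50, n_unique_loci=0,
                                 n_entropy_loci=0, n_predictive_loci=0,
                                 coverage_lambda=0.0)
        samples, _ = generate_methylomes(plain_genome, design)
        assert all(not r.covered for s in samples.values() for r in s)

    def test_planted_level_recovered_in_mean(self, plain_genome):
        # binomial sampling around a planted level: the mean observed
        # level over many loci stays within a few standard errors
        design = MethylomeDesign(seed=7, n_baseline_loci=0, n_unique_loci=500,
                                 n_entropy_loci=0, n_predictive_loci=0,
                                 coverage_lambda=50.0, unique_level=0.9)
        samples, truth = generate_methylomes(plain_genome, design)
        levels = []
        for s in samples.values():
            levels += [r.level for r in s if r.covered]
        assert np.mean(levels) == pytest.approx(0.9, abs=0.03)

    def test_design_larger_than_genome_rejected(self, plain_genome):
        design = MethylomeDesign(seed=1, n_baseline_loci=10 ** 6)
        with pytest.raises(ValueError, match="cytosines"):
            generate_methylomes(plain_genome, design)


@pytest.fixture(scope="module")
def frags_index(planted_genome):
    genome, repeats, _, _ = planted_genome
    fragments = size_select(digest(genome), SizeWindow(40, 300))
    return fragments, RepeatIndex(repeats)


class TestGenerateReadIntervals:
    def test_null_multipliers_equal_proportions(self, frags_index):
        fragments, index = frags_index
        reads, _ = generate_read_intervals(
            fragments, index, {"a": 20_000, "b": 20_000},
            {"a": 1.0, "b": 1.0}, seed=4, frac_nonunique=0.0,
            frac_no_site=0.0)

        def aluy_frac(rs):
            return np.mean([index.best_alu(r.chrom, r.start, r.end)
                            is not None for r in rs])
        assert aluy_frac(reads["a"]) == pytest.approx(aluy_frac(reads["b"]),
                                                      abs=0.02)

    def test_zero_multiplier_removes_aluy(self, frags_index):
        fragments, index = frags_index
        reads, _ = generate_read_intervals(fragments, index, {"a": 5_000},
                                           {"a": 0.0}, seed=4)
        for r in reads["a"]:
            hit = index.best_alu(r.chrom, r.start, r.end)
            assert hit is None or hit[1] is not AluClass.ALU_Y

    def test_empty_fragments_rejected(self, frags_index):
        _, index = frags_index
        with pytest.raises(ValueError):
            generate_read_intervals([], index, {"a": 10}, {"a": 1.0})

    def test_flag_fractions(self, frags_index):
        fragments, index = frags_index
        reads, _ = generate_read_intervals(
            fragments, index, {"a": 20_000}, {"a": 1.0}, seed=1,
            frac_nonunique=0.1, frac_no_site=0.0)
        frac_bad = np.mean([not r.unique_flag for r in reads["a"]])
        assert frac_bad == pytest.approx(0.1, abs=0.01)


def test_stage_rng_streams_differ():
    a = stage_rng(1, "genome").integers(0, 10 ** 9)
    b = stage_rng(1, "methylome").integers(0, 10 ** 9)
    c = stage_rng(1, "genome").integers(0, 10 ** 9)
    assert a == c
    assert a != b
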
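import pytest

from alumeth.formats import CytosineRecord, GenomeSequence, MethylomeSample
from alumeth.sets import (LocusSet, build_set_E, call_context, common_set,
                          presence, shared_high_noncpg, unique_group_sets)


def sample(sid, loci):
    """loci: list of (chrom, pos, strand, context, n_meth, n_unmeth)."""
    return MethylomeSample(sid, [
        CytosineRecord(c, p, s, ctx, m, u) for c, p, s, ctx, m, u in loci])


class TestCallContext:
    @pytest.mark.parametrize("seq,pos,strand,expected", [
        ("ACGTT", 1, "+", "CpG"),
        ("ACAGT", 1, "+", "CHG"),
        ("ACTTT", 1, "+", "CHH"),
        ("TTCGA", 3, "-", "CpG"),    # G at 3; revcomp downstream = C,G -> CpG
        ("TCTGG", 3, "-", "CHG"),    # revcomp reads C,A,G
        ("AAAGG", 3, "-", "CHH"),
    ])
    def test_context_rule(self, seq, pos, strand, expected):
        genome = GenomeSequence({"c": seq})
        assert call_context(genome, "c", pos, strand) == expected

    def test_boundary_undefined(self):
        genome = GenomeSequence({"c": "AAAAC"})
        assert call_context(genome, "c", 4, "+") is None

    def test_n_in_window_undefined(self):
        genome = GenomeSequence({"c": "ACNGT"})
        assert call_context(genome, "c", 1, "+") is None

    def test_not_a_cytosine_rejected(self):
        genome = GenomeSequence({"c": "AAGTT"})
        with pytest.raises(ValueError):
            call_context(genome, "c", 0, "+")


class TestPresence:
    def test_depth_threshold(self):
        s = sample("s", [("c", 4, "+", "CpG", 1, 0),
                         ("c", 9, "+", "CpG", 2, 2)])
        assert len(presence(s, 1)) == 2
        assert presence(s, 5) == set()

    def test_monotone_in_depth(self):
        s = sample("s", [("c", i, "+", "CpG", i, i) for i in range(1, 10)])
        sizes = [len(presence(s, d)) for d in range(1, 20)]
        assert sizes == sorted(sizes, reverse=True)


class TestUniqueGroupSets:
    def make_groups(self):
        # locus a: parental only; locus b: parental + oxpt; locus c: sn38 only
        par = [sample("p1", [("c", 1, "+", "CpG", 3, 1),
                             ("c", 2, "+", "CpG", 3, 1)]),
               sample("p2", [])]
        oxpt = [sample("o1", [("c", 2, "+", "CpG", 1, 1)]), sample("o2", [])]
        sn38 = [sample("n1", [("c", 3, "+", "CpG", 2, 0)]), sample("n2", [])]
        return {"parental": par, "oxpt": oxpt, "sn38": sn38}

    def test_exclusivity_rule(self):
        sets = unique_group_sets(self.make_groups())
        assert ("c", 1, "+", "CpG") in sets["parental"]
        assert ("c", 2, "+", "CpG") not in sets["parental"]
        assert ("c", 2, "+", "CpG") not in sets["oxpt"]
        assert ("c", 3, "+", "CpG") in sets["sn38"]

    def test_pairwise_disjoint(self):
        sets = unique_group_sets(self.make_groups())
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                assert not (sets[a].loci & sets[b].loci)

    def test_duplicate_sample_ids_rejected(self):
        groups = self.make_groups()
        groups["oxpt"][0].sample_id = "p1"
        with pytest.raises(ValueError, match="two groups"):
            unique_group_sets(groups)

    def test_quorum(self):
        groups = self.make_groups()
        sets = unique_group_sets(groups, presence_quorum=2)
        assert len(sets["parental"]) == 0  # only one parental sample covers


class TestCommonAndE:
    def test_single_sample_identity(self):
        s = sample("s", [("c", 1, "+", "CpG", 1, 0)])
        assert common_set([s]).loci == presence(s)

    def test_empty_sample_absorbs(self):
        s1 = sample("s1", [("c", 1, "+", "CpG", 1, 0)])
        s2 = sample("s2", [])
        assert len(common_set([s1, s2])) == 0

    def test_intersection_bound(self):
        s1 = sample("s1", [("c", i, "+", "CpG", 1, 0) for i in range(10)])
        s2 = sample("s2", [("c", i, "+", "CpG", 1, 0) for i in range(5, 20)])
        assert len(common_set([s1, s2])) <= min(len(presence(s1)),
                                                len(presence(s2)))

    def test_set_e_algebra(self):
        def ls(label, keys):
            return LocusSet(label, frozenset(keys))
        a, b, c, d = [("c", i, "+", "CpG") for i in range(4)]
        E = build_set_E(ls("C", {a, b, c}), ls("P", {a}), ls("O", {d}),
                        ls("S", {c}))
        assert E.loci == {a, c}
        assert E.label == "E"

    def test_set_e_disjoint_and_superset_cases(self):
        def ls(label, keys):
            return LocusSet(label, frozenset(keys))
        a, b = ("c", 0, "+", "CpG"), ("c", 1, "+", "CpG")
        assert len(build_set_E(ls("C", {a}), ls("P", {b}), ls("O", set()),
                               ls("S", set()))) == 0
        E = build_set_E(ls("C", {a, b}), ls("P", {a}), ls("O", {b}),
                        ls("S", set()))
        assert E.loci == {a, b}


class TestSharedHighNonCpG:
    def test_inclusive_threshold_and_context_split(self):
        s1 = sample("s1", [("c", 1, "+", "CHG", 5, 5),   # level 0.5 exactly
                           ("c", 2, "+", "CHH", 9, 1),
                           ("c", 3, "+", "CpG", 10, 0)])
        s2 = sample("s2", [("c", 1, "+", "CHG", 6, 4),
                           ("c", 2, "+", "CHH", 49, 51),  # 0.49 -> dropped
                           ("c", 3, "+", "CpG", 10, 0)])
        result = shared_high_noncpg([s1, s2], min_level=0.5)
        assert ("c", 1, "+", "CHG") in result["CHG"]
        assert len(result["CHH"]) == 0
        assert all(k[3] != "CpG" for ctx in result.values() for k in ctx)
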
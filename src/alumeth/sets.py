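"""Presence calling and locus set algebra over methylome samples.

The experimental design behind this module: three colorectal cancer cell
lines, each as a parental line plus an oxaliplatin (OxPt)-resistant and an
SN38-resistant derivative, and a cohort of clinical samples.  From their
RRBS cytosine calls we build labelled locus sets:

* P / O / S — loci unique to the parental, OxPt-resistant and
  SN38-resistant groups respectively (present in the group, absent from
  all samples of both other groups; pairwise disjoint by construction);
* A — loci common to all nine cell-line samples;
* C — loci common to all clinical samples;
* E — C intersected with P ∪ O ∪ S, the drug-phenotype loci that are
  also observable in every clinical sample.

Loci are keyed by (chrom, pos, strand, context); a CpG and its
reverse-strand partner are distinct loci, matching stranded cytosine
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .formats import GenomeSequence, MethylomeSample

LocusKey = tuple  # (chrom, pos, strand, context)


@dataclass
class LocusSet:
    label: str
    loci: frozenset = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    def __contains__(self, key) -> bool:
        return key in self.loci


def call_context(genome: GenomeSequence, chrom: str, pos: int,
                 strand: str) -> Optional[str]:
    """Cytosine context (CpG/CHG/CHH, H = A, T or C) at a genomic position.

    On the minus strand the reference base is G and the two downstream
    bases are read towards decreasing coordinates on the reverse
    complement.  Returns None when the window runs off the chromosome or
    touches an N; raises if the stranded base is not a cytosine.
    """
    seq = genome[chrom]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    if strand == "+":
        base = seq[pos]
        if base != "C":
            raise ValueError(f"{chrom}:{pos}:+ is {base}, not C")
        if pos + 2 >= len(seq):
            return None
        b1, b2 = seq[pos + 1], seq[pos + 2]
    elif strand == "-":
        base = seq[pos]
        if base != "G":
            raise ValueError(f"{chrom}:{pos}:- is {comp[base]}, not C")
        if pos - 2 < 0:
            return None
        b1, b2 = comp[seq[pos - 1]], comp[seq[pos - 2]]
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if "N" in (b1, b2):
        return None
    if b1 == "G":
        return "CpG"
    if b2 == "G":
        return "CHG"
    return "CHH"


def presence(sample: MethylomeSample, min_depth: int = 1) -> set:
    """Locus keys covered by at least ``min_depth`` reads in the sample."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return {(r.chrom, r.pos, r.strand, r.context)
            for r in sample if r.total >= min_depth}


def unique_group_sets(groups: Mapping[str, Sequence[MethylomeSample]],
                      min_depth: int = 1, presence_quorum: int = 1,
                      ) -> dict[str, LocusSet]:
    """Group-unique locus sets (P/O/S-style).

    A locus belongs to group g's set iff it is present at ``min_depth`` in
    at least ``presence_quorum`` samples of g and below ``min_depth`` in
    every sample of every other group.  The resulting sets are pairwise
    disjoint by construction.
    """
    seen_ids: set[str] = set()
    for samples in groups.values():
        if not samples:
            raise ValueError("empty sample group")
        for s in samples:
            if s.sample_id in seen_ids:
                raise ValueError(f"sample id {s.sample_id!r} in two groups")
            seen_ids.add(s.sample_id)

    presence_sets = {name: [presence(s, min_depth) for s in samples]
                     for name, samples in groups.items()}
    out: dict[str, LocusSet] = {}
    for name, plist in presence_sets.items():
        counts: dict = {}
        for p in plist:
            for key in p:
                counts[key] = counts.get(key, 0) + 1
        candidates = {k for k, c in counts.items() if c >= presence_quorum}
        for other, other_plist in presence_sets.items():
            if other == name:
                continue
            for p in other_plist:
                candidates -= p
        out[name] = LocusSet(label=name, loci=frozenset(candidates))
    return out


def common_set(samples: Sequence[MethylomeSample], min_depth: int = 1,
               label: str = "common") -> LocusSet:
    """Intersection of presence over all samples (sets A and C)."""
    if not samples:
        raise ValueError("need at least one sample")
    loci = presence(samples[0], min_depth)
    for s in samples[1:]:
        loci &= presence(s, min_depth)
    return LocusSet(label=label, loci=frozenset(loci))


def build_set_E(C: LocusSet, P: LocusSet, O: LocusSet,
                S: LocusSet) -> LocusSet:
    """E = C ∩ (P ∪ O ∪ S)."""
    return LocusSet(label="E",
                    loci=frozenset(C.loci & (P.loci | O.loci | S.loci)))


def shared_high_noncpg(samples: Sequence[MethylomeSample],
                       min_level: float = 0.5,
                       min_depth: int = 1) -> dict[str, LocusSet]:
    """Non-CpG loci methylated at >= ``min_level`` in every sample.

    The threshold is inclusive ("at least 50% or higher").  Returns the
    CHG and CHH sets separately; CpG loci are never returned.
    """
    if not samples:
        raise ValueError("need at least one sample")
    levels: list[dict] = []
    for s in samples:
        lv = {}
        for r in s:
            if r.context == "CpG" or r.total < min_depth:
                continue
            if r.level is not None:
                lv[(r.chrom, r.pos, r.strand, r.context)] = r.level
        levels.append(lv)
    candidates = set(levels[0])
    for lv in levels[1:]:
        candidates &= set(lv)
    kept = {k for k in candidates if all(lv[k] >= min_level for lv in levels)}
    return {
        "CHG": LocusSet("CHG", frozenset(k for k in kept if k[3] == "CHG")),
        "CHH": LocusSet("CHH", frozenset(k for k in kept if k[3] == "CHH")),
    }


def write_locus_set(locus_set: LocusSet, path) -> None:
    with open(path, "w") as handle:
        handle.write("chrom\tpos0\tstrand\tcontext\tset_label\n")
        for chrom, pos, strand, context in sorted(locus_set.loci):
            handle.write(f"{chrom}\t{pos}\t{strand}\t{context}\t"
                         f"{locus_set.label}\n")


def read_locus_set(path) -> LocusSet:
    loci = set()
    label = "custom"
    with open(path) as handle:
        header = handle.readline()
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            chrom, pos, strand, context, label = line.split("\t")[:5]
            loci.add((chrom, int(pos), strand, context))
    return LocusSet(label=label, loci=frozenset(loci))
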
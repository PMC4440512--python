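"""Genomic-component annotation of cytosine loci.

Each locus gets exactly one component label, resolved by a fixed priority:
exon > intron > TSS > promoter > repeat > intergenic.  The TSS window is
the transcription start point +/- ``tss_halfwidth``; the promoter is the
stretch upstream of the TSS window on the coding strand.  A locus that
overlaps only a repeat annotation is labelled "repeat"; one matching
nothing is "intergenic".

Per-gene locus counting is many-to-many: a locus inside two overlapping
genes counts for both.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from intervaltree import IntervalTree

from .formats import RepeatAnnotation
from .repeats import RepeatIndex

COMPONENTS = ("exon", "intron", "TSS", "promoter", "repeat", "intergenic")


@dataclass
class GeneModel:
    """A gene with exon structure; introns and promoter are derived."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        prev_end = None
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s},{e}) outside gene {self.name}")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"overlapping exons in gene {self.name}")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start point (0-based position)."""
        return self.start if self.strand == "+" else self.end - 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1:
                out.append((e1, s2))
        return out

    def tss_window(self, tss_halfwidth: int = 200) -> tuple[int, int]:
        return (max(0, self.tss - tss_halfwidth), self.tss + tss_halfwidth + 1)

    def promoter(self, tss_halfwidth: int = 200,
                 promoter_up: int = 2000) -> tuple[int, int]:
        """Upstream-of-TSS-window stretch on the coding strand."""
        if self.strand == "+":
            return (max(0, self.tss - promoter_up),
                    max(0, self.tss - tss_halfwidth))
        return (self.tss + tss_halfwidth + 1,
                self.tss + promoter_up + 1)


def read_bed12_genes(path) -> list[GeneModel]:
    """Read gene models from BED12 (blocks become exons)."""
    genes = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5] if len(f) > 5 else "+"
            exons = []
            if len(f) >= 12:
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                starts = [int(x) for x in f[11].rstrip(",").split(",")]
                exons = [(start + s, start + s + sz)
                         for s, sz in zip(starts, sizes)]
            else:
                exons = [(start, end)]
            genes.append(GeneModel(name=name, chrom=chrom, start=start,
                                   end=end, strand=strand, exons=exons))
    return genes


def write_bed12_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as handle:
        for g in genes:
            sizes = ",".join(str(e - s) for s, e in g.exons) + ","
            starts = ",".join(str(s - g.start) for s, e in g.exons) + ","
            handle.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.name}\t0\t{g.strand}\t"
                f"{g.start}\t{g.end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


class GeneIndex:
    """Interval indexes over exons, introns, TSS and promoter windows."""

    def __init__(self, genes: Sequence[GeneModel], tss_halfwidth: int = 200,
                 promoter_up: int = 2000):
        self.genes = list(genes)
        self._exon: dict[str, IntervalTree] = {}
        self._intron: dict[str, IntervalTree] = {}
        self._tss: dict[str, IntervalTree] = {}
        self._promoter: dict[str, IntervalTree] = {}
        self._span: dict[str, IntervalTree] = {}
        for g in self.genes:
            for s, e in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            for s, e in g.introns():
                self._intron.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            s, e = g.tss_window(tss_halfwidth)
            self._tss.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            s, e = g.promoter(tss_halfwidth, promoter_up)
            if s < e:
                self._promoter.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self._span.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)

    def _hit(self, trees: dict[str, IntervalTree], chrom: str,
             pos: int) -> bool:
        tree = trees.get(chrom)
        return tree is not None and tree.overlaps_point(pos)

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        """Genes whose span or promoter contains the position."""
        hits = []
        for trees in (self._span, self._promoter):
            tree = trees.get(chrom)
            if tree is not None:
                hits.extend(iv.data for iv in tree.at(pos))
        seen, out = set(), []
        for g in hits:
            if id(g) not in seen:
                seen.add(id(g))
                out.append(g)
        return out


def assign_component(locus: tuple, gene_index: GeneIndex,
                     repeat_index: Optional[RepeatIndex] = None) -> str:
    """Single component label for a locus, by fixed priority.

    Priority: exon > intron > TSS > promoter > repeat > intergenic.
    ``locus`` is any tuple starting (chrom, pos).
    """
    chrom, pos = locus[0], locus[1]
    if gene_index._hit(gene_index._exon, chrom, pos):
        return "exon"
    if gene_index._hit(gene_index._intron, chrom, pos):
        return "intron"
    if gene_index._hit(gene_index._tss, chrom, pos):
        return "TSS"
    if gene_index._hit(gene_index._promoter, chrom, pos):
        return "promoter"
    if repeat_index is not None and repeat_index.overlapping(chrom, pos, pos + 1):
        return "repeat"
    return "intergenic"


def component_distribution(loci: Sequence[tuple], gene_index: GeneIndex,
                           repeat_index: Optional[RepeatIndex] = None,
                           dmc_subset: Optional[Iterable[tuple]] = None,
                           ) -> dict[str, dict[str, Counter]]:
    """Component counts per context for all loci and for a DMC subset.

    Returns ``{"all": {context: Counter}, "dmc": {context: Counter}}``;
    within each context the counts partition the loci of that context.
    """
    if not loci:
        raise ValueError("empty locus list")
    dmc = set(dmc_subset) if dmc_subset is not None else set()
    out = {"all": {}, "dmc": {}}
    for locus in loci:
        context = locus[3] if len(locus) > 3 else "CpG"
        label = assign_component(locus, gene_index, repeat_index)
        out["all"].setdefault(context, Counter())[label] += 1
        if locus in dmc:
            out["dmc"].setdefault(context, Counter())[label] += 1
    return out


def loci_per_gene(loci: Iterable[tuple],
                  gene_index: GeneIndex) -> list[tuple[str, int]]:
    """Per-gene locus counts, sorted by count desc then gene name.

    Attribution is many-to-many (span or promoter containment); genes
    with zero loci are omitted.
    """
    counts: Counter = Counter()
    for locus in loci:
        for g in gene_index.genes_at(locus[0], locus[1]):
            counts[g.name] += 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
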
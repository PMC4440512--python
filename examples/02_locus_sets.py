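"""Locus set algebra: P/O/S group-unique sets, common sets A and C, set E.

Generates methylomes for a 3-cell-line drug-resistance panel (parental,
OxPt-resistant, SN38-resistant) plus 14 clinical samples, then builds the
labelled locus sets: a locus is unique to a group when it is covered in
that group and in no sample of the other two groups; E keeps the
group-unique loci that every clinical sample also covers.
"""

from alumeth import (RepeatIndex, build_set_E, common_set, composition,
                     enrichment_test, unique_group_sets)
from alumeth.synthetic import (GenomeDesign, MethylomeDesign,
                               generate_genome, generate_methylomes)

genome, repeats, _genes, _ = generate_genome(GenomeDesign(seed=2))
design = MethylomeDesign(seed=2)
samples, truth = generate_methylomes(genome, design)

groups = {g: [samples[s] for s in sids]
          for g, sids in design.cell_line_samples().items()}
sets = unique_group_sets(groups, min_depth=1)
P, O, S = sets["parental"], sets["oxpt"], sets["sn38"]
print(f"group-unique loci: |P|={len(P)} |O|={len(O)} |S|={len(S)}")
print(f"planted per group: {design.n_unique_loci}")

cell = [s for grp in groups.values() for s in grp]
A = common_set(cell, label="A")
clinical = [samples[s] for s in design.clinical_samples()]
C = common_set(clinical, label="C")
E = build_set_E(C, P, O, S)
print(f"|A| (all nine cell lines) = {len(A)}, |C| (clinical) = {len(C)}, "
      f"|E| = C ∩ (P∪O∪S) = {len(E)}")

planted_e = len(truth.of_kind("unique-clinical-shared"))
print(f"planted clinically shared unique loci: {planted_e}")

index = RepeatIndex(repeats)
e_comp = composition(sorted(E.loci), index)
print(f"Alu fraction of set E loci: {e_comp.fraction_alu:.3f}")
print("(loci are planted uniformly over the genome, so this tracks the "
      "genomic Alu footprint; enrichment beyond it is the headline test)")
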
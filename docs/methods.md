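# Methods

## The analysis in one paragraph

Three colorectal cancer cell lines, each as a parental line with an
oxaliplatin (OxPt)-resistant and an SN38-resistant derivative, plus a
clinical cohort split into treatment benefit / no-benefit groups, are
profiled by RRBS. The pipeline identifies the cytosine loci unique to each
phenotype group (sets P, O, S), the loci those share with every clinical
sample (set E), and asks whether these sets are enriched in Alu elements
and the Alu Y subfamily beyond what RRBS chemistry alone would sample — the
control being an in-silico MspI digest of the same reference genome with
the same gel selection. Orthogonal evidence comes from read-level Alu Y
counts (paired t-test on log₂ counts), from flanking-sequence motifs and
target site duplications (the signature of fresh retrotransposition), and
from entropy-based differential methylation with clustering and outcome
prediction on the clinical arm.

## Models and procedures

### In-silico digestion and size selection

MspI cuts C^CGG and ignores CpG methylation. Cut positions are
`occurrence_start + 1` for every exact CCGG occurrence (occurrences
containing N never match; overlapping occurrences of a general site each
cut). Fragments are the intervals between consecutive cuts on a
chromosome; terminal stretches carry only one MspI end and are excluded by
default because RRBS library molecules need MspI ends on both sides
(`include_terminal=True` restores them). Fragment size is the genomic
insert length; adaptor bases are ignored. Size selection is inclusive on
both bounds. The window sweep emits the base window, windows slid by
±k·step (both bounds, clipped at 1; default step 50 bp, one slide each
way — the granularity of the extension, since no slide step is canonical),
and two windows extended 50 bp down / up.

### Alu classification and composition

`rep_family == "Alu"` plus name-prefix AluY*/AluS*/AluJ* defines the three
subfamilies; FLAM/FRAM-like family members are tracked as AluOther and
never folded into Y/S/J. A fragment is Alu-assigned if it overlaps an Alu
annotation by ≥1 bp (configurable minimum; point loci use containment);
among multiple hits the largest overlap wins, ties to the leftmost
annotation. The any-overlap default is the most inclusive reading of
"sequences from Alu repeats"; the knob exists because the field has no
canonical rule. Enrichment is the two-sided Fisher exact test under the
probability-mass criterion (all tables with the observed margins whose
hypergeometric probability is ≤ the observed one, with 1e-7 relative
slack for floating-point ties), delegated to `scipy.stats.fisher_exact`
and cross-checked in the tests against a full enumeration oracle for all
margins ≤ 12.

### Locus sets

Loci are keyed `(chrom, pos0, strand, context)`; a CpG and its
reverse-strand partner are distinct, as in stranded Bismark reports.
Presence means total read depth ≥ `min_depth` (default 1 — no coverage
threshold is imposed silently). "Unique to group g" means present in ≥
`presence_quorum` samples of g (default 1, the weakest exclusivity
reading, which maximises set sizes) and below `min_depth` in **every**
sample of both other groups; P, O, S are therefore disjoint by
construction. A and C are presence intersections over all cell-line /
clinical samples; E = C ∩ (P∪O∪S). The shared high-methylation non-CpG
filter keeps CHG/CHH loci at level ≥ 0.5 (inclusive) in every sample.

### Methylation entropy and DMCs

For levels v over N ≥ 2 covered samples, H(v) = −Σ pᵢ log₂ pᵢ with
pᵢ = vᵢ/Σv (zero terms contribute 0; log base 2, bits). The statistic is
`min(H(m), H(1−m))`: the demethylation arm catches sample-specific
hypomethylation; an arm with zero sum counts as maximal (log₂ N), so
all-zero or all-one profiles are non-differential. This is a plain-entropy
reimplementation of the QDMR idea, not a port — QDMR's fitted one-step
threshold adjustment is deliberately out of scope, because the plain form
is exactly testable. DMCs are loci with entropy at or below an absolute
cutoff or the lower q-quantile (default q = 0.05) of entropies over fully
covered loci. Clustering uses 1 − Pearson correlation over co-covered loci
(pairwise deletion; a pair sharing < 10 loci is an error naming the pair),
average linkage, columns pre-sorted by sample name so exact ties merge
deterministically; dendrograms export to Newick.

### Read-level Alu Y counts

Reads must be uniquely mapped with the MspI site at the 5' end. Totals are
equalised by linear scaling to the arithmetic mean total (the test
statistic is invariant to the common target); scaled counts stay real,
never re-rounded. A read counts toward the subfamily of its
largest-overlap annotation. The paired test is Student's t on
dᵢ = log₂(resistantᵢ) − log₂(parentalᵢ), sample sd, df = n−1, two-sided;
zero counts are an error, zero sd with non-zero mean reports p = 0 with a
degenerate-variance flag.

### Motifs and TSDs

Flanks are the `flank` bp (default 20) outside each element; minus-strand
elements have both flanks reverse-complemented and swapped so "left" is
always upstream in element orientation (the endonuclease site is
strand-relative). Logo statistics: per-column counts over A/C/G/T with N
excluded per column (not per sequence), probabilities over non-N
observations, information content R = 2 − H with no small-sample
correction by default (the correction is a flag; the uncorrected form is
exactly testable: conserved ⇒ 2 bits, uniform ⇒ 0). TSD detection returns
the longest exact sequence of length 4–25 that ends the left flank and
begins the right flank.

### Outcome prediction

Feature score s = (μ₀−μ₁)/(σ₀+σ₁) with each sample sd floored at
max(0.2·|μ|, 0.2), ranked by |s|. With the floors in place a constant
feature scores 0 rather than raising a division error. KNN uses Euclidean
distance on the selected features, missing cells deleted pairwise with
renormalisation by √(L/L_used); distance ties break by sample name, vote
ties by the nearest neighbour's class. LOOCV re-selects features inside
every fold by default (leakage-free); the alternative — selecting once on
the full cohort before validating — is available via
`fold_internal_selection=False` since both protocols are defensible
readings of "select key features from all patients, then leave-one-out".
Defaults k = 3, 50 features. Accuracy is tested with the Fisher exact test
on the predicted-vs-actual 2×2 table.

### Annotation priority

One label per locus: exon > intron > TSS > promoter > repeat > intergenic.
The published priority phrase omits TSS and places repeats last; here TSS
outranks promoter (more specific) and repeat outranks only intergenic —
an interpretive decision, documented as such. TSS window = point ± 200 bp,
promoter = 2000 bp upstream of the TSS window on the coding strand; both
configurable, since no widths are canonical. Per-gene locus counts are
many-to-many (span ∪ promoter containment), sorted by count then name.

## Synthetic data: what it emulates and what it does not

`generate_genome` builds i.i.d. background sequence at GC 0.41 (stripped
of accidental CCGG so spacing follows the planted model exactly), plants
CCGG sites at geometric gaps (mean 400 bp), and splices in Alu-like
cassettes: A-rich pad (20 bp, 65% A) + TSD + 300 bp body + identical TSD +
pad, reverse-complemented on half the insertions. TSDs are exact
duplicates (8 bp, seeded TTAAAA + random bases) so motif/TSD recovery has
a sharp truth. Each body carries its own interior CCGG sites yielding one
or two selected fragments fully inside the element, and a 320 bp site-free
exclusion zone around every insertion keeps boundary fragments above the
selection window — so the fraction of selected fragments overlapping Alu
is controlled by construction. When a target share f is designed (default
0.30), the generator digests its own background, counts selected
background fragments B, and plants round(f·B/(1−f)) element-interior
fragments across ⌈·/2⌉ insertions, apportioning subfamilies Y/S/J by
largest remainder (default mix 0.5/0.3/0.2). Gene models tile the
chromosomes with simple 3-exon genes.

`generate_methylomes` emits the 3×3 cell-line panel plus 14 clinical
samples (7 benefit / 7 no-benefit): baseline loci with strong per-line
means (U(0.05, 0.95)) and small variant jitter (sd 0.03) — the somatic
memory that drives lineage clustering; group-unique loci covered only in
their group (depth ≥ 1 enforced so recovery is exact), half of them also
covered in every clinical sample, which is precisely the planted set E;
sample-specific loci (one sample at 0.9, the rest at 0.05) as low-entropy
truth; and clinical predictive loci separated by 0.4 between outcome
groups. Depth is Poisson(λ = 30) truncated at 1 where presence is planted
(λ = 0 produces fully uncovered records as the degenerate case); observed
counts are binomial around the planted level. Read generation samples
size-selected fragments with Alu Y-overlapping fragments up-weighted by a
per-sample multiplier, with small flagged fractions of non-unique and
missing-5'-site reads for the filter to remove. Every generator draws
from a stream derived from the master seed and the stage name, so stages
reproduce independently.

Not emulated: sequence evolution within Alu subfamilies (synthetic bodies
are random sequence with labelled annotations, so classification is by
annotation, never by sequence similarity), bisulfite conversion errors,
mapping bias and multi-mapping (read "mapping" is fragment identity),
chromosomal aberrations, and the correlation structure of real CpG
islands. Passing recovery tests therefore demonstrates the correctness of
the pipeline's logic and statistics under the designed conditions — not
robustness to the noise sources of real RRBS data.

## Experiment sizes in the validation suite

Chosen so each recovery quantity has tight sampling error: the composition
genome is 2 × 250 kb with ~100 insertions and ~700 selected fragments
(share recovery to ±0.01, subfamily mix to ±0.02); DMC recovery plants 100
sample-specific loci among 2000 baseline loci — just under the 5% calling
quantile, so the called set is dominated by planted loci and precision is
informative (with planted fraction far below the quantile, precision would
be bounded by construction, not by the statistic); clustering and DMC runs
use 20 independent seeds, the read-excess power estimate 100 seeds at
10 000 reads per sample, and the label-permutation null 100 permutations.

## Numerical choices

Entropy: 0·log 0 ≡ 0; arm ties resolve to "hyper-specific". Quantile
thresholds use pandas' linear interpolation; the DMC rule is ≤ threshold
so an absolute threshold of 0 still returns exactly-one-sample loci.
Fisher: scipy's probability-mass two-sided definition, verified to 1e-12
against enumeration. t-tests: sample sd (ddof 1). KNN distances and vote
ties as above; all tie-breaks are deterministic, so the whole pipeline is
reproducible bit-for-bit under a fixed seed (checked via output checksums).

## Full-scale reproduction notes

The original cohort's headline numbers — set sizes 505,147 / 337,242 /
359,770 (CpG loci in P/O/S) and 48,944 (E); Alu fractions 48.8 / 60.1 /
53.3% in P/O/S, 53.4% in E with 46.3% Alu Y; the simulation's ~28% Alu
with 39.5% Alu Y on the human reference; overlap fractions 54.7 / 42.4 /
42.1 / 87.7% for P/O/S/A vs. simulation; paired t-test p-values 0.0039
(SN38) and 2.13×10⁻¹² (OxPt); and LOOCV accuracies 35.7 / 35.7 / 64.3%
(CpG/CHH/CHG) — derive from the deposited RRBS dataset (GEO accession
GSE56269) aligned to hg19. Reproducing them requires that data, the hg19
FASTA and its RepeatMasker rmsk table; the code paths are the same ones
exercised here (`read_fasta` + `digest` + `size_select` + `composition`
for the simulation maxima; the set algebra, read counting and prediction
modules for the rest). They are not recomputed at validation scale.

## Known limitations

- Subfamily classification trusts annotation names; no sequence-level
  verification.
- The entropy statistic is not numerically identical to QDMR's adjusted
  score, so absolute DMC counts are not comparable with QDMR output (the
  quantile rule sidesteps this for within-dataset calls).
- `unique_group_sets` holds all presence sets in memory; genome-scale
  inputs (~10⁷ loci × 23 samples) need the chromosome-partitioned path via
  the CLI rather than one in-memory call.
- The paired t-test assumes log₂ counts are approximately normal; with
  n = 3 pairs the test is fragile to a single outlying pair, which is why
  the power criterion is Monte-Carlo-estimated rather than asserted from
  the closed form.
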
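"""End-to-end orchestration of the analysis stages.

``run_all`` executes the three experiments on one dataset — locus set
algebra plus in-silico digestion comparison, read-level Alu Y validation,
and clinical entropy/prediction — and writes every stage product under a
single output directory with a JSON manifest of parameters, seeds and
per-file checksums.  The default configuration runs on synthetic data
generated in place, which makes the pipeline reproducible end to end
from a single seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alu_reads import filter_reads, normalize_totals, paired_log2_test, subfamily_counts
from .annotate import GeneIndex, loci_per_gene, write_bed12_genes
from .digestion import SizeWindow, digest, size_select, window_sweep, write_fragments_bed
from .entropy import call_dmcs, cluster_samples, matrix_from_samples
from .formats import write_cytosine_report, write_fasta, write_repeat_table
from .motif import build_matrix, detect_tsd, extract_flanks, rank_position, write_matrix_tsv
from .predict import loocv
from .repeats import RepeatIndex, composition, enrichment_test, loci_fragment_overlap, AluClass
from .sets import build_set_E, common_set, unique_group_sets, write_locus_set
from .synthetic import (GenomeDesign, MethylomeDesign, generate_genome,
                        generate_methylomes, generate_read_intervals)

log = logging.getLogger("alumeth")


@dataclass
class PipelineConfig:
    out_dir: str = "alumeth_out"
    seed: int = 0
    min_depth: int = 1
    window_min: int = 40
    window_max: int = 300
    dmc_quantile: float = 0.05
    knn_k: int = 3
    knn_features: int = 50
    n_reads_per_sample: int = 10_000
    aluy_excess: float = 1.5
    genome: GenomeDesign = field(default_factory=GenomeDesign)
    methylome: MethylomeDesign = field(default_factory=MethylomeDesign)


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Run every stage on a synthetic dataset; returns the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(name)s %(levelname)s %(message)s")
    results: dict = {}

    log.info("[simulate] generating genome and methylomes")
    config.genome.seed = config.seed
    config.methylome.seed = config.seed
    genome, repeats, genes, genome_truth = generate_genome(config.genome)
    samples, meth_truth = generate_methylomes(genome, config.methylome)
    write_fasta(genome, out / "genome.fa")
    write_repeat_table(repeats, out / "repeats.tsv")
    write_bed12_genes(genes, out / "genes.bed")
    genome_truth.write_tsv(out / "truth_genome.tsv")
    meth_truth.write_tsv(out / "truth_methylome.tsv")
    for sid, sample in samples.items():
        write_cytosine_report(sample, out / f"{sid}.cov.tsv", genome=genome)

    log.info("[digest] in-silico MspI digestion and size selection")
    window = SizeWindow(config.window_min, config.window_max, "base")
    fragments = digest(genome)
    selected = size_select(fragments, window)
    write_fragments_bed(selected, out / "fragments.bed")
    index = RepeatIndex(repeats)
    results["n_fragments"] = len(fragments)
    results["n_selected_fragments"] = len(selected)

    log.info("[compose] fragment composition across the window sweep")
    sweep_summaries = []
    for w in window_sweep(window):
        summary = composition(size_select(fragments, w), index, label=w.label)
        sweep_summaries.append(summary)
    base_summary = sweep_summaries[0]
    results["fraction_alu"] = base_summary.fraction_alu
    results["fraction_aluy_of_alu"] = (
        base_summary.subfamily_fractions[AluClass.ALU_Y])

    log.info("[sets] presence calling and locus set algebra")
    groups = {g: [samples[sid] for sid in sids]
              for g, sids in config.methylome.cell_line_samples().items()}
    pos_sets = unique_group_sets(groups, min_depth=config.min_depth)
    P, O, S = pos_sets["parental"], pos_sets["oxpt"], pos_sets["sn38"]
    cell_samples = [s for grp in groups.values() for s in grp]
    A = common_set(cell_samples, config.min_depth, label="A")
    clinical = [samples[sid] for sid in config.methylome.clinical_samples()]
    C = common_set(clinical, config.min_depth, label="C")
    E = build_set_E(C, P, O, S)
    for ls in (P, O, S, A, C, E):
        write_locus_set(ls, out / f"set_{ls.label}.tsv")
        results[f"n_set_{ls.label}"] = len(ls)

    log.info("[overlap] locus sets versus the simulation")
    for ls in (P, O, S, A):
        frac, _inside, outside = loci_fragment_overlap(ls.loci, selected)
        results[f"overlap_{ls.label}_with_simulation"] = frac

    log.info("[enrich] Alu Y enrichment against the simulation")
    e_comp = composition(sorted(E.loci), index, label="E")
    sim_y = base_summary.subfamily_counts[AluClass.ALU_Y]
    table = [[e_comp.subfamily_counts[AluClass.ALU_Y],
              max(1, e_comp.n_alu - e_comp.subfamily_counts[AluClass.ALU_Y])],
             [sim_y, max(1, base_summary.n_alu - sim_y)]]
    results["aluy_enrichment_p"] = enrichment_test(table)

    log.info("[entropy] DMC calling and unsupervised clustering")
    matrix = matrix_from_samples(cell_samples, min_depth=config.min_depth)
    dmcs = call_dmcs(matrix, quantile=config.dmc_quantile)
    results["n_dmcs"] = len(dmcs)
    dmc_matrix = matrix.loc[[loc for loc in matrix.index if loc in dmcs]]
    dendrogram = cluster_samples(matrix)
    (out / "dendrogram.nwk").write_text(dendrogram.to_newick() + "\n")

    log.info("[alu-reads] read-level Alu Y excess and paired t-test")
    sample_ids = list(samples)
    cell_ids = [s.sample_id for s in cell_samples]
    multipliers = {sid: (config.aluy_excess if ("oxpt" in sid or "sn38" in sid)
                         else 1.0) for sid in cell_ids}
    reads, _ = generate_read_intervals(
        selected, index, {sid: config.n_reads_per_sample for sid in cell_ids},
        multipliers, seed=config.seed)
    filtered = {sid: filter_reads(r) for sid, r in reads.items()}
    factors = normalize_totals({sid: len(r) for sid, r in filtered.items()})
    counts = subfamily_counts(filtered, index, factors)
    for drug in ("oxpt", "sn38"):
        pairs = [(counts[f"{ln}_{drug}"].counts[AluClass.ALU_Y],
                  counts[f"{ln}_parental"].counts[AluClass.ALU_Y])
                 for ln in config.methylome.lines]
        res = paired_log2_test(pairs)
        results[f"aluy_reads_{drug}_vs_parental_p"] = res.p

    log.info("[motif] flanking motifs and TSD detection")
    flanks, skipped = extract_flanks(repeats, genome, flank=20)
    left_matrix = build_matrix([fp.left for fp in flanks])
    write_matrix_tsv(left_matrix, out / "left_flank_matrix.tsv")
    results["first_flank_base_ranking"] = "".join(rank_position(left_matrix, 0))
    tsd_calls = [detect_tsd(fp.left, fp.right, element_id=fp.element_id)
                 for fp in flanks]
    results["tsd_detected_fraction"] = (
        sum(c is not None for c in tsd_calls) / len(tsd_calls)
        if tsd_calls else 0.0)

    log.info("[annotate] loci per gene")
    gene_index = GeneIndex(genes)
    gene_counts = loci_per_gene(sorted(E.loci), gene_index)
    pd.DataFrame(gene_counts, columns=["gene", "n_loci"]).to_csv(
        out / "loci_per_gene.tsv", sep="\t", index=False)

    log.info("[predict] clinical outcome LOOCV")
    clin_matrix = matrix_from_samples(clinical, min_depth=config.min_depth)
    labels = pd.Series(config.methylome.clinical_labels())
    full = clin_matrix.dropna()
    report = loocv(full, labels, k=config.knn_k,
                   n_features=config.knn_features)
    results["loocv_accuracy"] = report.accuracy
    results["loocv_fisher_p"] = report.fisher_p

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("genome", "methylome")
        },
        "results": results,
        "checksums": {},
    }
    for path in sorted(out.iterdir()):
        if path.name != "manifest.json" and path.is_file():
            manifest["checksums"][path.name] = _checksum(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    log.info("[done] wrote %s", out / "manifest.json")
    return manifest
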
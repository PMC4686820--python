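"""Per-mutation signature assignment and gene-level AID target discovery.

Computes p_ms for every mutation from the fitted factorization, hard-
assigns at p_ms > 0.75, extracts each AID signature's hotspot motifs
(third-quintile rule), and tests every gene carrying assigned mutations
for enrichment over the context-aware background rate (binomial test,
Benjamini-Hochberg q < 0.1).
"""

import tempfile
from pathlib import Path

import pandas as pd

from aidsig import (annotate_context, assignment_table, build_matrix,
                    compute_nmd, empirical_spectra, fit_restarts,
                    gene_enrichment, hotspot_motifs, match_signatures,
                    partition, read_genes, read_mutations, truth_evaluate,
                    tss_enrichment)
from aidsig.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=31, n_contigs=2, contig_length=3_000_000,
                       n_genes=150, gene_length_min=4_000,
                       gene_length_max=12_000, n_target_genes=5,
                       n_samples=6, mean_mutations_younger=1500,
                       mean_mutations_older=1800, n_older=3,
                       n_ighv_mutated=4)
out = Path(tempfile.mkdtemp(prefix="aidsig_ex3_"))
paths = simulate_cohort(cfg, out)
truth = pd.read_csv(paths.truth, sep="\t")

muts = read_mutations(paths.mutations)
muts = annotate_context(muts, paths.fasta)
muts = partition(compute_nmd(muts))
samples = sorted(muts["sample"].unique())
matrix = build_matrix(muts, samples)
model, _ = fit_restarts(matrix.counts, K0=12, n_restarts=8, seed0=2,
                        column_labels=matrix.column_labels)
names, _ = match_signatures(model.W, empirical_spectra(truth))
model.rename(names)

table = assignment_table(muts, model, matrix)
rep = truth_evaluate(table, truth)
print(f"hard-assigned at p_ms > 0.75: {rep['n_assigned']}/{rep['n_total']} "
      f"mutations, {100 * rep['accuracy']:.1f}% match their generating "
      "process")

label = "assigned_0.75"
motifs = hotspot_motifs(table, label, ["c-AID", "nc-AID"], W=model.W,
                        signature_names=model.signature_names)
for sig, m in motifs.items():
    print(f"{sig} hotspot motifs (above third quintile): {m.labels}")

genes = read_genes(paths.genes_bed)
enr = gene_enrichment("c-AID", motifs["c-AID"], table, label, genes,
                      paths.fasta)
bg = enr.attrs["background"]
print(f"\nc-AID background rate: {bg.per_mb:.0f} hotspot mutations per Mb "
      f"of hotspot context ({bg.x_total}/{bg.n_total} sites, "
      f"{len(bg.universe)} genes in universe)")
print("\ntop genes by q-value (x = hotspot mutations, n = hotspot sites):")
print(enr.head(8)[["gene_id", "x", "n", "p", "q", "significant"]]
      .to_string(index=False))

targets = set(pd.read_csv(paths.truth_genes, sep="\t")
              .query("is_target")["gene_id"])
hits = set(enr.loc[enr["significant"], "gene_id"])
print(f"\ntrue targets recovered at q<0.1: {len(hits & targets)}/"
      f"{len(targets)}")

contig_lengths = {f"chr{i+1}": cfg.contig_length
                  for i in range(cfg.n_contigs)}
tss = tss_enrichment(table, label, genes, cfg.genome_length,
                     names, contig_lengths=contig_lengths)
print("\nmutation density within 2 kb of TSS vs genome-wide:")
print(tss.round(2).to_string())
print("\nThe clustered c-AID signature concentrates near transcription "
      "start sites; the dispersed signatures sit at the genome-wide rate.")
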
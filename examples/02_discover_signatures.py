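"""Unsupervised signature discovery with NMD-stratified ARD-NMF.

Counts each sample's mutations into clustered and non-clustered columns of
a 96 x 2M matrix, runs the Bayesian NMF with exponential priors from many
random restarts, and reports how many signatures survive automatic
relevance determination and how well they match the generating spectra.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from aidsig import (annotate_context, build_matrix, compute_nmd,
                    empirical_spectra, fit_restarts, match_signatures,
                    partition, read_mutations)
from aidsig.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=21, n_contigs=2, contig_length=3_000_000,
                       n_genes=150, gene_length_min=4_000,
                       gene_length_max=12_000, n_target_genes=5,
                       n_samples=6, mean_mutations_younger=1200,
                       mean_mutations_older=1500, n_older=3,
                       n_ighv_mutated=4)
out = Path(tempfile.mkdtemp(prefix="aidsig_ex2_"))
paths = simulate_cohort(cfg, out)

muts = read_mutations(paths.mutations)
muts = annotate_context(muts, paths.fasta)
muts = partition(compute_nmd(muts))
samples = sorted(muts["sample"].unique())
matrix = build_matrix(muts, samples)
print(f"count matrix X: {matrix.counts.shape[0]} channels x "
      f"{matrix.counts.shape[1]} sample-stratum columns "
      f"({matrix.counts.sum()} mutations)")

model, restarts = fit_restarts(matrix.counts, K0=12, n_restarts=10,
                               seed0=1, column_labels=matrix.column_labels)
print("\nK across restarts:", dict(restarts["K"].value_counts().sort_index()))
print(f"selected model: K={model.K}, log posterior "
      f"{model.log_posterior:.1f} ({model.n_iter} iterations)")

truth = pd.read_csv(paths.truth, sep="\t")
ref = empirical_spectra(truth)
names, cosines = match_signatures(model.W, ref)
model.rename(names)
print("\ncosine similarity to the generating spectra:")
for name, cos in zip(names, cosines):
    print(f"  {name:>7s}: {cos:.4f}")

print("\ntop channels of each recovered signature:")
W = pd.DataFrame(model.W, index=matrix.channel_labels, columns=names)
for name in names:
    top = W[name].nlargest(3)
    desc = ", ".join(f"{c} ({v:.2f})" for c, v in top.items())
    print(f"  {name:>7s}: {desc}")
print("\nEach column of W sums to 1 and is the signature's mutability "
      "over the 96 contexts; H carries the mutation counts it explains "
      "per clustered/non-clustered column.")
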
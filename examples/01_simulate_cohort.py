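"""Simulate a small synthetic CLL-like cohort and inspect its structure.

Builds a 6-sample cohort on a 2 x 3 Mb genome with the three generative
processes (ageing C>T at CpG, clustered c-AID C>T/G at WRCY near TSS,
dispersed nc-AID A>C at WA), then shows the per-process mutation counts
and the inter-mutation distance structure that motivates the
clustered/non-clustered stratification.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from aidsig import compute_nmd, partition, read_mutations
from aidsig.simulate import SimulationConfig, simulate_cohort

cfg = SimulationConfig(seed=11, n_contigs=2, contig_length=3_000_000,
                       n_genes=150, gene_length_min=4_000,
                       gene_length_max=12_000, n_target_genes=5,
                       n_samples=6, mean_mutations_younger=1200,
                       mean_mutations_older=1500, n_older=3,
                       n_ighv_mutated=4)
out = Path(tempfile.mkdtemp(prefix="aidsig_ex1_"))
paths = simulate_cohort(cfg, out)
print(f"cohort written to {out}")

truth = pd.read_csv(paths.truth, sep="\t")
print("\nmutations per generative process:")
print(truth["process"].value_counts().to_string())

muts = read_mutations(paths.mutations)
muts = partition(compute_nmd(muts))
frac = (muts["stratum"] == "clustered").mean()
print(f"\nclustered fraction (NMD <= 1,000 nt): {100 * frac:.1f}%")

nmd = muts["nmd"].dropna()
for lo, hi in [(0, 1e3), (1e3, 1e4), (1e4, 1e5), (1e5, 1e7)]:
    n = ((nmd > lo) & (nmd <= hi)).sum()
    print(f"  NMD in ({lo:>8.0f}, {hi:>8.0f}] nt: {n:5d} mutations")
print("\nThe low-NMD mass is the clustered c-AID activity; the rest is "
      "the dispersed background. This toy genome is ~100x denser in "
      "mutations than a real one, so the two modes sit close together; "
      "at the default full-scale density (800 Mb genome) the background "
      "mode moves out to ~100 kb and a clean valley opens near the "
      "1,000 nt partition threshold.")
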
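# aidsig

Unsupervised discovery of mutational signatures in whole-genome somatic
SNVs, with the inter-mutation distance as an extra feature. Built for the
question that motivates it in chronic lymphocytic leukaemia: separating
the clustered canonical-AID process (C>T/G at WRCY motifs near
transcription start sites) from the dispersed non-canonical-AID (A>C at
WA motifs) and ageing (C>T at CpG) processes, then using per-mutation
assignments to find AID target genes and to order the processes in time
from mutation clonality.

Intended users: cancer-genomics analysts with a somatic SNV table
(MAF-like TSV or VCF), a reference FASTA, a gene BED and, optionally,
per-mutation cancer-cell-fraction estimates and per-sample metadata.

## Method in brief

1. **NMD stratification.** Each mutation's nearest-mutation distance
   (NMD) — the minimum distance to any other mutation of the same
   patient on the same chromosome — splits mutations into clustered
   (NMD &le; 1,000 nt) and non-clustered strata.
2. **Stratified counts.** SNVs are encoded into the 96 pyrimidine-
   collapsed trinucleotide channels; each sample contributes a clustered
   and a non-clustered column, giving X (96 x 2M).
3. **ARD Bayesian NMF.** X &asymp; W'H' under a Poisson likelihood with
   per-component exponential priors whose scales &lambda;<sub>k</sub>
   carry an inverse-gamma hyperprior; automatic relevance determination
   prunes unneeded components, so the number of signatures K is inferred.
   Many restarts; modal K, then maximum posterior. The scaling transform
   W = W'U&#8315;&sup1;, H = UH' (U = diag column 1-norms of W') yields
   unit-sum spectra and mutation-count activities.
4. **Assignment.** p<sub>ms</sub> = [w<sub>k</sub>h<sub>k</sub> /
   &Sigma;<sub>k</sub>w<sub>k</sub>h<sub>k</sub>]<sub>ij</sub>; hard
   labels at p<sub>ms</sub> &gt; 0.75 (0.5 for the clonality ratios).
5. **Downstream.** Hotspot motifs per AID signature (third-quintile
   rule), context-aware background rates, per-gene binomial enrichment
   with BH q &lt; 0.1, TSS &plusmn; 2 kb proximity, expression-quartile
   densities, and clonal/subclonal timing statistics from CCF-based
   clonality (filtered &lt; 0.1; clonal iff Pr(CCF &ge; 0.95) &ge; 0.5).

A full synthetic-cohort simulator (three generative processes with
clustering, expression-linked targeting, clonality structure and complete
ground truth) ships as first-class code and is the test bed for the whole
pipeline. See `docs/methods.md` for the model details and design choices.

## Worked example

`examples/` contains one short script per capability. Discovery on a
small simulated cohort (`python examples/02_discover_signatures.py`):

```
count matrix X: 96 channels x 12 sample-stratum columns (8161 mutations)

K across restarts: {3: 10}
selected model: K=3, log posterior 2862.8 (540 iterations)

cosine similarity to the generating spectra:
   nc-AID: 0.9981
    c-AID: 0.9999
   ageing: 0.9999

top channels of each recovered signature:
   nc-AID: T[T>G]A (0.16), A[T>G]A (0.15), T[T>G]T (0.15)
    c-AID: A[C>T]T (0.24), A[C>T]C (0.17), G[C>T]T (0.15)
   ageing: T[C>T]G (0.29), A[C>T]G (0.29), G[C>T]G (0.20)
```

All ten restarts prune down to K=3; the recovered spectra match the
generating processes (ageing mass on N[C>T]G, i.e. CpG; nc-AID on
strand-collapsed A>C at WA, i.e. N[T>G]W; c-AID on R[C>T/G]Y, the WRCY
core). `examples/03_assign_and_enrich.py` continues to per-mutation
assignment (99.7% of hard-assigned mutations carry their generating
process), hotspot motifs, gene enrichment (5/5 planted target genes at
q &lt; 0.1) and TSS proximity (c-AID ~10x on that toy genome, dispersed
signatures ~1x); `examples/04_clonality_timing.py` reproduces the timing
ordering (clonal fractions nc-AID &gt; c-AID &gt; ageing).

The same stages are available as a thin CLI:

```sh
aidsig all --simulate --out-dir run1 --seed 1      # synthetic end-to-end
aidsig decompose --config my_cohort.yaml           # single stage, own data
```

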
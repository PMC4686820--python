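"""Signature-specific hotspot motifs and gene-level enrichment tests.

From the mutations hard-assigned to a signature at p_ms > 0.75, the
channels whose assigned-mutation tallies strictly exceed the third
quintile (60th percentile) of the non-zero tallies form that signature's
hotspot motif set.  Channel sets of different signatures are made disjoint
(a shared channel is kept by the signature with the larger normalized
spectrum weight).  The background rate r of a signature is the per-site
density of its hotspot-motif mutations over the hotspot-motif positions of
all genes carrying at least one assigned mutation; each gene is then
tested with an upper-tail binomial test of its observed hotspot-motif
mutation count x against Binomial(n, r), n being the gene's available
hotspot-motif positions, with Benjamini-Hochberg correction (significance
q < 0.1).

TSS proximity (mutation density within +/-2 kb of transcription start
sites versus genome-wide) and expression-quartile density profiles are
computed per signature from the same assignments.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pyfaidx
from scipy import stats

from .channels import (channel_context_index, context_index_codes,
                       seq_to_codes, CHANNEL_LABELS)

log = logging.getLogger(__name__)

Q_CUTOFF = 0.1
TSS_WINDOW = 2000


@dataclass
class HotspotMotifSet:
    signature: str
    channels: set[int]
    quintile_cut: float

    @property
    def labels(self) -> list[str]:
        return [CHANNEL_LABELS[c] for c in sorted(self.channels)]


def hotspot_motifs(assignments: pd.DataFrame, label_col: str,
                   signatures: list[str],
                   W: np.ndarray | None = None,
                   signature_names: list[str] | None = None
                   ) -> dict[str, HotspotMotifSet]:
    """Extract hotspot mutation motifs (channels) per signature.

    Tally assigned mutations per channel; keep channels strictly above the
    60th percentile of non-zero tallies.  When ``W`` (normalized spectra)
    and ``signature_names`` are given, channels claimed by several
    signatures go to the one with the larger W entry; otherwise to the one
    with the larger tally.
    """
    sets: dict[str, HotspotMotifSet] = {}
    tallies: dict[str, pd.Series] = {}
    for sig in signatures:
        sub = assignments[(assignments[label_col] == sig)
                          & (assignments["channel"] >= 0)]
        tally = sub["channel"].value_counts()
        tallies[sig] = tally
        if tally.empty:
            log.warning("signature %s has no assigned mutations; empty "
                        "motif set", sig)
            sets[sig] = HotspotMotifSet(sig, set(), float("nan"))
            continue
        cut = float(np.percentile(tally.to_numpy(), 60))
        chans = set(int(c) for c, v in tally.items() if v > cut)
        sets[sig] = HotspotMotifSet(sig, chans, cut)

    # enforce disjointness
    for i, a in enumerate(signatures):
        for b in signatures[i + 1:]:
            shared = sets[a].channels & sets[b].channels
            for ch in shared:
                if W is not None and signature_names is not None and \
                        a in signature_names and b in signature_names:
                    wa = W[ch, signature_names.index(a)]
                    wb = W[ch, signature_names.index(b)]
                else:
                    wa = tallies[a].get(ch, 0)
                    wb = tallies[b].get(ch, 0)
                loser = b if wa >= wb else a
                sets[loser].channels.discard(ch)
    return sets


def map_mutations_to_genes(muts: pd.DataFrame,
                           genes: pd.DataFrame) -> pd.DataFrame:
    """Pairs (mutation row index, gene_id) for every mutation falling in a
    gene footprint; overlapping genes each claim the mutation."""
    rows = []
    muts = muts.reset_index(drop=True)
    for chrom, midx in muts.groupby("chrom", sort=False).groups.items():
        midx = np.asarray(midx)
        pos = muts["pos"].to_numpy()[midx]
        order = np.argsort(pos)
        sp, si = pos[order], midx[order]
        g = genes[genes["chrom"] == chrom]
        lo = np.searchsorted(sp, g["start"].to_numpy(), side="left")
        hi = np.searchsorted(sp, g["end"].to_numpy(), side="right")
        for gid, l, h in zip(g["gene_id"], lo, hi):
            if h > l:
                rows.append(pd.DataFrame({"mut_index": si[l:h], "gene_id": gid}))
    if not rows:
        return pd.DataFrame(columns=["mut_index", "gene_id"])
    return pd.concat(rows, ignore_index=True)


def hotspot_context_counts(genes: pd.DataFrame, genome,
                           channels: set[int]) -> pd.Series:
    """Available hotspot-motif positions n per gene footprint.

    A position counts (once) when its strand-collapsed trinucleotide
    context matches the context part of any hotspot channel; the collapsed
    encoding makes the count identical on either strand.
    """
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(os.fspath(genome), as_raw=True,
                               sequence_always_upper=True)
    ctx = {channel_context_index(c) for c in channels}
    ctx_arr = np.zeros(32, dtype=bool)
    for c in ctx:
        ctx_arr[c] = True
    out = {}
    for row in genes.itertuples():
        L = len(genome[row.chrom])
        a = max(int(row.start) - 2, 0)          # 0-based, one flank left
        bnd = min(int(row.end) + 1, L)          # one flank right
        seq = genome[row.chrom][a:bnd]
        codes = seq_to_codes(seq)
        if codes.size < 3:
            out[row.gene_id] = 0
            continue
        center = codes[1:-1]
        f5, f3 = codes[:-2], codes[2:]
        valid = (center >= 0) & (f5 >= 0) & (f3 >= 0)
        idx = context_index_codes(f5[valid], center[valid], f3[valid])
        out[row.gene_id] = int(ctx_arr[idx].sum())
    return pd.Series(out, name="n", dtype=np.int64)


def gene_binomial_test(x: int, n: int, r: float) -> float:
    """Upper-tail binomial p-value P(X >= x) for X ~ Binomial(n, r)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < r < 1:
        raise ValueError("background rate must lie in (0, 1)")
    if x <= 0:
        return 1.0
    return float(stats.binom.sf(x - 1, n, r))


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class BackgroundRate:
    signature: str
    per_site: float
    per_mb: float
    x_total: int
    n_total: int
    universe: list[str]


def background_rate(signature: str, motifs: HotspotMotifSet,
                    assignments: pd.DataFrame, label_col: str,
                    genes: pd.DataFrame, genome,
                    gene_map: pd.DataFrame | None = None,
                    context_counts: pd.Series | None = None
                    ) -> BackgroundRate:
    """Context-aware background rate over the signature's gene universe.

    Universe = genes with >= 1 assigned mutation of the signature.
    r = (assigned mutations at hotspot motifs across the universe)
        / (hotspot-motif positions across the universe footprints).
    """
    if gene_map is None:
        gene_map = map_mutations_to_genes(assignments, genes)
    assigned = assignments[label_col] == signature
    sig_map = gene_map[assigned.to_numpy()[gene_map["mut_index"]]]
    universe = sorted(sig_map["gene_id"].unique())
    if not universe:
        raise ValueError(f"no genes with assigned {signature} mutations")
    ugenes = genes[genes["gene_id"].isin(universe)]
    if context_counts is None:
        context_counts = hotspot_context_counts(ugenes, genome, motifs.channels)
    else:
        context_counts = context_counts.reindex(universe)
    n_total = int(context_counts.loc[universe].sum())
    if n_total == 0:
        raise ValueError("zero available hotspot-motif positions in universe")
    hot = assignments["channel"].isin(list(motifs.channels)).to_numpy()
    x_total = int((hot[sig_map["mut_index"]]).sum())
    r = x_total / n_total
    return BackgroundRate(signature, r, 1e6 * r, x_total, n_total, universe)


def gene_enrichment(signature: str, motifs: HotspotMotifSet,
                    assignments: pd.DataFrame, label_col: str,
                    genes: pd.DataFrame, genome,
                    q_cutoff: float = Q_CUTOFF) -> pd.DataFrame:
    """Per-gene binomial enrichment of a signature at its hotspot motifs.

    Returns a DataFrame (gene_id, x, n, r, p, q, significant) over the
    signature's gene universe, sorted by q then p.
    """
    gene_map = map_mutations_to_genes(assignments, genes)
    bg = background_rate(signature, motifs, assignments, label_col,
                         genes, genome, gene_map=gene_map)
    ugenes = genes[genes["gene_id"].isin(bg.universe)]
    n_per_gene = hotspot_context_counts(ugenes, genome, motifs.channels)

    assigned = (assignments[label_col] == signature).to_numpy()
    hot = assignments["channel"].isin(list(motifs.channels)).to_numpy()
    mask = assigned[gene_map["mut_index"]] & hot[gene_map["mut_index"]]
    x_per_gene = gene_map[mask].groupby("gene_id").size()

    recs = []
    for gid in bg.universe:
        n = int(n_per_gene.get(gid, 0))
        x = int(x_per_gene.get(gid, 0))
        p = gene_binomial_test(x, n, bg.per_site) if n >= 1 else 1.0
        recs.append((gid, x, n, p))
    out = pd.DataFrame(recs, columns=["gene_id", "x", "n", "p"])
    out["r"] = bg.per_site
    out["q"] = fdr_bh(out["p"].to_numpy())
    out["significant"] = out["q"] < q_cutoff
    out.attrs["background"] = bg
    return out.sort_values(["q", "p"], ignore_index=True)


def _merged_window_length(genes: pd.DataFrame, window: int,
                          contig_lengths: dict[str, int] | None = None
                          ) -> tuple[dict[str, np.ndarray], int]:
    """Union of TSS +/- window intervals per chromosome; returns per-chrom
    merged (start, end) arrays (1-based inclusive) and the total length."""
    merged: dict[str, np.ndarray] = {}
    total = 0
    for chrom, g in genes.groupby("chrom", sort=False):
        tss = g["tss"].to_numpy(dtype=np.int64)
        lo = np.maximum(tss - window, 1)
        hi = tss + window
        if contig_lengths and chrom in contig_lengths:
            hi = np.minimum(hi, contig_lengths[chrom])
        order = np.argsort(lo)
        lo, hi = lo[order], hi[order]
        out = []
        cur_lo, cur_hi = lo[0], hi[0]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= cur_hi + 1:
                cur_hi = max(cur_hi, b)
            else:
                out.append((cur_lo, cur_hi))
                cur_lo, cur_hi = a, b
        out.append((cur_lo, cur_hi))
        arr = np.asarray(out, dtype=np.int64)
        merged[chrom] = arr
        total += int((arr[:, 1] - arr[:, 0] + 1).sum())
    return merged, total


def tss_enrichment(assignments: pd.DataFrame, label_col: str,
                   genes: pd.DataFrame, genome_size: int,
                   signatures: list[str], window: int = TSS_WINDOW,
                   contig_lengths: dict[str, int] | None = None) -> pd.Series:
    """Per-signature ratio of mutation density near TSS to genome-wide.

    ratio = (assigned mutations in the union of TSS +/- window intervals
    per bp of that union) / (all assigned mutations of the signature per
    genome bp).  Overlapping windows are merged before length computation.
    """
    merged, wlen = _merged_window_length(genes, window, contig_lengths)
    out = {}
    for sig in signatures:
        sub = assignments[assignments[label_col] == sig]
        total = len(sub)
        if total == 0:
            out[sig] = np.nan
            continue
        inside = 0
        for chrom, g in sub.groupby("chrom", sort=False):
            if chrom not in merged:
                continue
            iv = merged[chrom]
            pos = g["pos"].to_numpy(dtype=np.int64)
            j = np.searchsorted(iv[:, 0], pos, side="right") - 1
            ok = (j >= 0) & (pos <= iv[np.clip(j, 0, None), 1])
            inside += int(ok.sum())
        out[sig] = (inside / wlen) / (total / genome_size)
    return pd.Series(out, name="tss_enrichment")


def expression_quartile_density(assignments: pd.DataFrame, label_col: str,
                                genes: pd.DataFrame,
                                signatures: list[str]) -> pd.DataFrame:
    """Signature x expression-quartile table of normalized mutation density.

    Genes with expression are split into quartiles Q1..Q4 (increasing
    expression); the per-quartile mutation density (mutations per Mb of
    quartile footprint) is normalized within each signature to sum to 1.
    """
    g = genes.dropna(subset=["expression"]).copy()
    if g.empty:
        raise ValueError("no genes with expression values")
    g["quartile"] = pd.qcut(g["expression"].rank(method="first"), 4,
                            labels=["Q1", "Q2", "Q3", "Q4"])
    footprint = g.groupby("quartile", observed=True).apply(
        lambda d: float((d["end"] - d["start"] + 1).sum()), include_groups=False)
    if (footprint <= 0).any():
        raise ValueError("empty expression-quartile footprint")
    gene_map = map_mutations_to_genes(assignments, g)
    quart_of_gene = g.set_index("gene_id")["quartile"]
    rows = {}
    for sig in signatures:
        assigned = (assignments[label_col] == sig).to_numpy()
        sub = gene_map[assigned[gene_map["mut_index"]]]
        counts = quart_of_gene.loc[sub["gene_id"]].value_counts()
        dens = np.array([counts.get(q, 0) / (footprint[q] / 1e6)
                         for q in ["Q1", "Q2", "Q3", "Q4"]], dtype=float)
        tot = dens.sum()
        rows[sig] = dens / tot if tot > 0 else dens
    return pd.DataFrame(rows, index=["Q1", "Q2", "Q3", "Q4"]).T
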
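"""Hotspot motifs, background rates, binomial/BH machinery, TSS/expression."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from aidsig import (fdr_bh, gene_binomial_test, hotspot_motifs,
                    tss_enrichment, expression_quartile_density)
from aidsig.enrichment import hotspot_context_counts, map_mutations_to_genes
from aidsig.channels import revcomp


def _assign_df(channels, labels, positions=None, chrom="chr1", sample="S1"):
    n = len(channels)
    return pd.DataFrame({
        "sample": sample, "chrom": chrom,
        "pos": positions if positions is not None else np.arange(1, n+1) * 7,
        "channel": channels, "label": labels})


def test_quintile_cut_on_toy_tallies():
    # tallies {c1:10, c2:8, c3:1, c4:1, c5:1}: 60th percentile of the
    # non-zero tallies (linear interpolation) is 3.8 -> keep {c1, c2}
    channels = [1] * 10 + [2] * 8 + [3, 4, 5]
    df = _assign_df(channels, ["sig"] * len(channels))
    out = hotspot_motifs(df, "label", ["sig"])
    assert out["sig"].channels == {1, 2}
    assert np.isclose(out["sig"].quintile_cut, 3.8)


def test_quintile_all_equal_tallies_selects_nothing():
    df = _assign_df([1, 2, 3, 4, 5], ["sig"] * 5)
    assert hotspot_motifs(df, "label", ["sig"])["sig"].channels == set()


def test_empty_signature_warns_and_is_empty():
    df = _assign_df([1], ["other_sig"])
    out = hotspot_motifs(df, "label", ["sig"])
    assert out["sig"].channels == set()


def test_disjointness_winner_takes_channel():
    # channel 7 qualifies for both; signature with larger W entry keeps it
    channels = [7] * 10 + [1] * 2 + [7] * 9 + [2] * 2
    labels = ["a"] * 12 + ["b"] * 11
    df = _assign_df(channels, labels)
    W = np.zeros((96, 2))
    W[7] = [0.2, 0.6]
    out = hotspot_motifs(df, "label", ["a", "b"], W=W,
                         signature_names=["a", "b"])
    assert 7 in out["b"].channels and 7 not in out["a"].channels
    assert not (out["a"].channels & out["b"].channels)


@pytest.mark.parametrize("x,n,r,expect", [
    (0, 10, 0.3, 1.0),
    (3, 3, 0.5, 0.125),
])
def test_binomial_tail_known_values(x, n, r, expect):
    assert gene_binomial_test(x, n, r) == pytest.approx(expect, rel=1e-12)


@pytest.mark.parametrize("x,n,r", [(5, 1000, 0.001), (2, 50, 0.01),
                                   (40, 10_000, 0.003)])
def test_binomial_tail_matches_exact_summation(x, n, r):
    rf = Fraction(r).limit_denominator(10**6)
    lower = sum(Fraction(comb(n, k)) * rf**k * (1 - rf)**(n - k)
                for k in range(x))
    expect = float(1 - lower)
    assert gene_binomial_test(x, n, float(rf)) == \
        pytest.approx(expect, rel=1e-10)


def test_binomial_tail_input_validation():
    with pytest.raises(ValueError):
        gene_binomial_test(1, 0, 0.5)
    with pytest.raises(ValueError):
        gene_binomial_test(1, 10, 0.0)


def test_bh_hand_computed_and_degenerate():
    assert fdr_bh([0.02])[0] == pytest.approx(0.02)
    q = fdr_bh([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert np.all(fdr_bh([1.0, 1.0, 1.0]) == 1.0)


def test_bh_matches_statsmodels_reference(rng):
    from statsmodels.stats.multitest import multipletests
    for _ in range(100):
        p = rng.uniform(0, 1, size=rng.integers(1, 60))
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(fdr_bh(p), q_ref, atol=1e-12)


@pytest.fixture()
def toy_genome(tmp_path):
    rng = np.random.default_rng(12)
    seq = "".join(rng.choice(list("ACGT"), size=6000))
    (tmp_path / "toy.fa").write_text(f">chr1\n{seq}\n")
    return tmp_path / "toy.fa", seq


def test_hotspot_context_counts_strand_symmetric(toy_genome, tmp_path):
    """Counting motif positions on the reverse-complemented genome with
    mirrored gene coordinates gives identical n per gene."""
    path, seq = toy_genome
    L = len(seq)
    (tmp_path / "rc.fa").write_text(f">chr1\n{revcomp(seq)}\n")
    genes = pd.DataFrame({"gene_id": ["G1", "G2"], "chrom": "chr1",
                          "start": [101, 2001], "end": [1100, 4000]})
    mirrored = genes.copy()
    mirrored["start"] = L - genes["end"] + 1
    mirrored["end"] = L - genes["start"] + 1
    channels = {10, 33, 70, 85}
    n_fwd = hotspot_context_counts(genes, path, channels)
    n_rc = hotspot_context_counts(mirrored, tmp_path / "rc.fa", channels)
    assert n_fwd.tolist() == n_rc.tolist()


def test_map_mutations_to_genes_overlaps():
    genes = pd.DataFrame({"gene_id": ["A", "B"], "chrom": "chr1",
                          "start": [100, 150], "end": [200, 250]})
    muts = pd.DataFrame({"sample": "S", "chrom": "chr1",
                         "pos": [120, 160, 240, 300]})
    pairs = map_mutations_to_genes(muts, genes)
    got = set(map(tuple, pairs.to_numpy()))
    assert got == {(0, "A"), (1, "A"), (1, "B"), (2, "B")}


def test_background_rate_single_gene_is_own_density(toy_genome):
    from aidsig.enrichment import background_rate, HotspotMotifSet
    path, seq = toy_genome
    genes = pd.DataFrame({"gene_id": ["G1"], "chrom": "chr1",
                          "start": [101], "end": [1100]})
    motifs = HotspotMotifSet("sig", {10, 33, 70}, 0.0)
    n = hotspot_context_counts(genes, path, motifs.channels)["G1"]
    df = _assign_df([10, 33, 5], ["sig"] * 3, positions=[150, 200, 250])
    bg = background_rate("sig", motifs, df, "label", genes, path)
    assert bg.x_total == 2 and bg.n_total == n
    assert bg.per_site == pytest.approx(2 / n)
    assert bg.per_mb == pytest.approx(2e6 / n)


def test_tss_enrichment_extreme_and_merging():
    genes = pd.DataFrame({"gene_id": ["G1", "G2"], "chrom": "chr1",
                          "start": [10_000, 12_000], "end": [11_000, 13_000],
                          "tss": [10_000, 12_000]})
    # windows [8000,12000] and [10000,14000] merge to 6001 bp = 1% of genome
    genome_size = 600_100
    inside = _assign_df([0] * 10, ["sig"] * 10,
                        positions=np.linspace(8000, 14000, 10).astype(int))
    ratio = tss_enrichment(inside, "label", genes, genome_size, ["sig"])
    assert ratio["sig"] == pytest.approx(genome_size / 6001, rel=1e-9)


def test_tss_enrichment_uniform_null(rng):
    genes = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(50)], "chrom": "chr1",
        "start": np.arange(50) * 80_000 + 10_000,
        "end": np.arange(50) * 80_000 + 20_000,
        "tss": np.arange(50) * 80_000 + 10_000})
    genome_size = 4_000_000
    pos = rng.integers(1, genome_size, size=50_000)
    df = _assign_df(np.zeros(len(pos), int), ["sig"] * len(pos),
                    positions=pos)
    ratio = tss_enrichment(df, "label", genes, genome_size, ["sig"])
    assert 0.8 <= ratio["sig"] <= 1.25


def test_expression_quartile_density_uniform_and_targeted(rng):
    genes = pd.DataFrame({
        "gene_id": [f"G{i}" for i in range(40)], "chrom": "chr1",
        "start": np.arange(40) * 20_000 + 1,
        "end": np.arange(40) * 20_000 + 10_000,
        "expression": np.arange(40) + 1.0})
    pos_all = rng.integers(1, 40 * 20_000, size=8000)
    uniform = _assign_df(np.zeros(8000, int), ["u"] * 8000, positions=pos_all)
    top_gene = genes.iloc[-1]                      # highest expression (Q4)
    targeted = _assign_df([0] * 50, ["t"] * 50,
                          positions=rng.integers(top_gene["start"],
                                                 top_gene["end"], 50))
    table = expression_quartile_density(
        pd.concat([uniform, targeted], ignore_index=True), "label", genes,
        ["u", "t"])
    assert np.allclose(table.loc["u"], 0.25, atol=0.05)
    assert table.loc["t"].idxmax() == "Q4"
    assert np.allclose(table.sum(axis=1), 1.0)


def test_expression_quartile_requires_expression():
    genes = pd.DataFrame({"gene_id": ["G1"], "chrom": "chr1", "start": [1],
                          "end": [10], "expression": [np.nan]})
    with pytest.raises(ValueError):
        expression_quartile_density(_assign_df([0], ["s"]), "label", genes,
                                    ["s"])
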
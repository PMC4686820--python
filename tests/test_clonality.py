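"""Clonality classification and signature-timing statistics."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aidsig import (ccf_distribution, classify_clonality, count_vs_group,
                    signature_clonality_association,
                    subclonal_clonal_ratio_by_group)
from aidsig.clonality import _ranksum, contingency_table


@pytest.mark.parametrize("ccf,pr,expect", [
    (0.98, 0.6, "clonal"),
    (0.05, 0.9, "filtered"),      # low CCF filtered regardless of posterior
    (0.50, 0.2, "subclonal"),
    (0.10, 0.5, "clonal"),        # boundary: CCF 0.1 kept, pr 0.5 clonal
    (0.099, 0.5, "filtered"),
    (0.9, 0.499, "subclonal"),
])
def test_classification_rule(ccf, pr, expect):
    assert classify_clonality(ccf, pr) == expect


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.floats(0, 1), st.floats(0, 1))
def test_classification_total_function(ccf, pr):
    assert classify_clonality(ccf, pr) in {"clonal", "subclonal", "filtered"}


def test_classification_fallback_without_posterior():
    out = classify_clonality(np.array([0.97, 0.5, 0.05]), None)
    assert list(out) == ["clonal", "subclonal", "filtered"]


def _assign(labels, clonality, sample="S1"):
    n = len(labels)
    return pd.DataFrame({"sample": sample, "chrom": "chr1",
                         "pos": np.arange(n) * 11 + 1, "channel": 0,
                         "label": labels, "clonality": clonality,
                         "ccf": 0.5})


def test_contingency_marginals_exclude_filtered():
    df = _assign(["a", "a", "b", "b", "b"],
                 ["clonal", "filtered", "subclonal", "clonal", "subclonal"])
    tab = contingency_table(df, "label", signatures=["a", "b"])
    assert tab.loc["clonal"].sum() == 2 and tab.loc["subclonal"].sum() == 2
    assert "filtered" not in tab.index


def test_chi_square_near_zero_for_identical_fractions():
    df = _assign(["a"] * 40 + ["b"] * 80,
                 (["clonal", "subclonal"] * 20) + (["clonal", "subclonal"] * 40))
    _, chi2, p, _ = signature_clonality_association(df, "label",
                                                    signatures=["a", "b"])
    assert chi2 == pytest.approx(0.0, abs=1e-9)


def test_fisher_matches_hypergeometric_oracle():
    # table (8,2 / 1,5): two-sided Fisher from exact enumeration
    a, b, c, d = 8, 2, 1, 5
    n, K, N = a + b + c + d, a + b, a + c
    def prob(x):
        return comb(K, x) * comb(n - K, N - x) / comb(n, N)
    p0 = prob(a)
    expect = sum(prob(x) for x in range(max(0, K + N - n), min(K, N) + 1)
                 if prob(x) <= p0 + 1e-12)
    df = _assign(["a"] * 10 + ["b"] * 6,
                 ["clonal"] * 8 + ["subclonal"] * 2
                 + ["clonal"] * 1 + ["subclonal"] * 5)
    _, _, _, fisher = signature_clonality_association(df, "label",
                                                      signatures=["a", "b"])
    got = fisher.set_index("signature").loc["a", "p"]
    assert got == pytest.approx(expect, rel=1e-9)


def test_ccf_distribution_fractions_sum_to_one(rng):
    n = 500
    df = pd.DataFrame({"sample": "S1", "chrom": "chr1",
                       "pos": np.arange(n), "label": "sig",
                       "ccf": rng.uniform(0.1001, 1.0, n)})
    out = ccf_distribution(df, "label")
    assert len(out) == 20
    assert out["fraction"].sum() == pytest.approx(1.0)
    assert out["count"].sum() == n


def test_ccf_distribution_single_bin():
    df = pd.DataFrame({"sample": "S1", "chrom": "chr1", "pos": [1, 2],
                       "label": "sig", "ccf": [0.12, 0.13]})
    out = ccf_distribution(df, "label")
    assert out.loc[0, "fraction"] == 1.0 and out["count"].sum() == 2


def _ratio_df(spec):
    """spec: {sample: (n_clonal, n_subclonal)} for one signature."""
    rows = []
    for s, (ncl, nsub) in spec.items():
        for i in range(ncl):
            rows.append((s, "clonal"))
        for i in range(nsub):
            rows.append((s, "subclonal"))
    df = pd.DataFrame(rows, columns=["sample", "clonality"])
    df["label"] = "c-AID"
    df["chrom"] = "chr1"
    df["pos"] = np.arange(len(df))
    return df


def test_ratio_min_mut_filter_and_infinite_ratio():
    df = _ratio_df({"S1": (3, 3), "S2": (2, 2), "S3": (0, 6), "S4": (5, 0)})
    meta = pd.DataFrame({"sample": ["S1", "S2", "S3", "S4"],
                         "ighv": ["mutated", "mutated", "unmutated",
                                  "unmutated"]})
    per_sample, p = subclonal_clonal_ratio_by_group(df, "label", meta, "c-AID")
    per = per_sample.set_index("sample")
    assert "S2" not in per.index                     # 4 mutations < min_mut 5
    assert per.loc["S1", "ratio"] == 1.0
    assert np.isinf(per.loc["S3", "ratio"])
    assert per.loc["S4", "ratio"] == 0.0
    assert np.isfinite(p)


def test_ratio_skips_comparison_with_empty_group():
    df = _ratio_df({"S1": (3, 3)})
    meta = pd.DataFrame({"sample": ["S1"], "ighv": ["mutated"]})
    _, p = subclonal_clonal_ratio_by_group(df, "label", meta, "c-AID")
    assert np.isnan(p)


def test_ranksum_matches_exact_permutation_enumeration():
    a, b = [1, 2, 3], [10, 20, 30]
    # exact two-sided p over all C(6,3) assignments of ranks
    ranks = range(6)
    obs = sum(sorted(range(6))[:3])                  # a holds the 3 smallest
    sums = [sum(c) for c in combinations(ranks, 3)]
    mean = np.mean(sums)
    extreme = sum(1 for s in sums if abs(s - mean) >= abs(obs - mean) - 1e-9)
    expect = extreme / len(sums)                     # = 2/20 = 0.1
    assert expect == pytest.approx(0.1)
    assert _ranksum(np.array(a, float), np.array(b, float)) == \
        pytest.approx(expect, rel=1e-12)


def test_count_vs_group_identical_and_errors():
    df = pd.DataFrame({"sample": ["S1"] * 3 + ["S2"] * 3,
                       "label": ["sig"] * 6, "chrom": "chr1",
                       "pos": range(6)})
    meta = pd.DataFrame({"sample": ["S1", "S2"], "grp": ["x", "y"]})
    out = count_vs_group(df, "label", meta, "grp", ["sig"])
    assert out.loc[0, "p"] == pytest.approx(1.0)
    bad = pd.DataFrame({"sample": ["S1", "S2"], "grp": ["x", "x"]})
    with pytest.raises(ValueError):
        count_vs_group(df, "label", bad, "grp", ["sig"])


def test_default_cohort_clonal_fraction_recovery(cohort):
    """Per-process clonal fractions recovered within +/-0.05 of the
    generating values 0.36 / 0.40 / 0.54."""
    truth = cohort.truth
    labels = classify_clonality(
        cohort.mutations["ccf"].to_numpy(),
        cohort.mutations["pr_ccf_ge_095"].to_numpy())
    frame = pd.DataFrame({"process": truth["process"], "clonality": labels})
    frame = frame[frame["clonality"] != "filtered"]
    frac = frame.groupby("process")["clonality"].apply(
        lambda s: (s == "clonal").mean())
    for proc, expect in cohort.config.clonal_fractions.items():
        assert abs(frac[proc] - expect) <= 0.05
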
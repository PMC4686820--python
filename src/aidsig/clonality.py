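"""Clonality classification and signature-timing statistics.

A mutation's cancer cell fraction (CCF) and the posterior probability that
its CCF is at least 0.95 (both produced upstream by purity/ploidy
inference such as ABSOLUTE and consumed here as plain columns) determine
its clonality: CCF < 0.1 is filtered out for low power; otherwise the
mutation is clonal when Pr(CCF >= 0.95) >= 0.5 and subclonal otherwise.
Clonal mutations predate the last selective sweep, so the per-signature
clonal/subclonal composition orders the mutational processes in time.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

CLONAL, SUBCLONAL, FILTERED = "clonal", "subclonal", "filtered"

OTHER = "other"

CCF_BINS = np.linspace(0.1, 1.0, 21)  # 20 equal bins over (0.1, 1.0]


def classify_clonality(ccf, pr_ccf_ge_095=None) -> np.ndarray | str:
    """Classify mutations as clonal / subclonal / filtered.

    Accepts scalars or arrays.  When the clonality posterior is absent
    (None/NaN) a hard fallback Pr = 1[ccf >= 0.95] is applied with a
    logged warning.
    """
    scalar = np.isscalar(ccf)
    ccf = np.atleast_1d(np.asarray(ccf, dtype=float))
    if pr_ccf_ge_095 is None:
        pr = np.full_like(ccf, np.nan)
    else:
        pr = np.atleast_1d(np.asarray(pr_ccf_ge_095, dtype=float))
    missing = np.isnan(pr)
    if missing.any():
        log.warning("clonality posterior missing for %d mutations; using "
                    "Pr = 1[CCF >= 0.95] fallback", int(missing.sum()))
        pr = np.where(missing, (ccf >= 0.95).astype(float), pr)
    out = np.where(ccf < 0.1, FILTERED,
                   np.where(pr >= 0.5, CLONAL, SUBCLONAL)).astype(object)
    out[np.isnan(ccf)] = FILTERED
    return out[0] if scalar else out


def contingency_table(assignments: pd.DataFrame, label_col: str,
                      clonality_col: str = "clonality",
                      signatures: list[str] | None = None) -> pd.DataFrame:
    """2 x S table (clonal/subclonal rows) over signatures plus "other".

    Unassigned mutations form the "other" column; filtered mutations enter
    no cell.  Empty signature columns are dropped with a warning.
    """
    df = assignments[assignments[clonality_col].isin([CLONAL, SUBCLONAL])]
    labels = df[label_col].where(df[label_col] != "unassigned", OTHER)
    sigs = signatures or [s for s in labels.unique() if s != OTHER]
    cols = list(sigs) + [OTHER]
    tab = pd.crosstab(df[clonality_col], labels).reindex(
        index=[CLONAL, SUBCLONAL], columns=cols, fill_value=0)
    empty = tab.columns[tab.sum(axis=0) == 0]
    if len(empty):
        log.warning("dropping empty clonality columns: %s", list(empty))
        tab = tab.drop(columns=empty)
    return tab


def signature_clonality_association(assignments: pd.DataFrame, label_col: str,
                                    clonality_col: str = "clonality",
                                    signatures: list[str] | None = None):
    """Chi-square test of independence on the 2 x S table plus per-signature
    2 x 2 Fisher exact tests (that signature versus all others).

    Returns (table, chi2_stat, chi2_p, fisher DataFrame).
    """
    tab = contingency_table(assignments, label_col, clonality_col, signatures)
    chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy())
    rows = []
    totals = tab.sum(axis=1)
    for sig in tab.columns:
        a, c = int(tab.loc[CLONAL, sig]), int(tab.loc[SUBCLONAL, sig])
        b, d = int(totals[CLONAL] - a), int(totals[SUBCLONAL] - c)
        odds, fp = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        frac = a / (a + c) if a + c else np.nan
        rows.append((sig, a, c, frac, odds, fp))
    fisher = pd.DataFrame(rows, columns=["signature", "clonal", "subclonal",
                                         "clonal_fraction", "odds_ratio", "p"])
    return tab, float(chi2), float(p), fisher


def ccf_distribution(assignments: pd.DataFrame, label_col: str,
                     bins: np.ndarray = CCF_BINS,
                     signatures: list[str] | None = None) -> pd.DataFrame:
    """Per-signature CCF histogram: counts and within-signature fractions.

    Filtered mutations (CCF < 0.1 or missing) are excluded; fractions sum
    to 1 per signature with any assigned mutation.
    """
    df = assignments.dropna(subset=["ccf"])
    df = df[df["ccf"] >= bins[0]]
    sigs = signatures or sorted(s for s in df[label_col].unique()
                                if s != "unassigned")
    rows = []
    for sig in sigs:
        ccf = df.loc[df[label_col] == sig, "ccf"].to_numpy()
        counts, _ = np.histogram(np.clip(ccf, bins[0] + 1e-12, bins[-1]), bins)
        frac = counts / counts.sum() if counts.sum() else counts.astype(float)
        for lo, hi, c, f in zip(bins[:-1], bins[1:], counts, frac):
            rows.append((sig, lo, hi, int(c), f))
    return pd.DataFrame(rows, columns=["signature", "bin_lo", "bin_hi",
                                       "count", "fraction"])


def subclonal_clonal_ratio_by_group(assignments: pd.DataFrame, label_col: str,
                                    meta: pd.DataFrame, signature: str,
                                    group_col: str = "ighv",
                                    min_mut: int = 5,
                                    clonality_col: str = "clonality"):
    """Per-sample subclonal:clonal ratio of a signature's mutations, compared
    across metadata groups with a two-sided rank-sum test.

    Samples with fewer than ``min_mut`` assigned (non-filtered) mutations
    are excluded; a zero clonal count yields an infinite ratio, which the
    rank-based test tolerates.  Returns (per-sample DataFrame, p-value or
    NaN when a group has no eligible samples).
    """
    df = assignments[(assignments[label_col] == signature)
                     & assignments[clonality_col].isin([CLONAL, SUBCLONAL])]
    rows = []
    for sample, g in df.groupby("sample"):
        n_cl = int((g[clonality_col] == CLONAL).sum())
        n_sub = int((g[clonality_col] == SUBCLONAL).sum())
        if n_cl + n_sub < min_mut:
            continue
        ratio = n_sub / n_cl if n_cl else np.inf
        rows.append((sample, n_cl, n_sub, ratio))
    per_sample = pd.DataFrame(rows, columns=["sample", "clonal", "subclonal",
                                             "ratio"])
    per_sample = per_sample.merge(meta[["sample", group_col]], on="sample")
    groups = [g["ratio"].to_numpy() for _, g in
              per_sample.groupby(group_col, sort=True)]
    if len(groups) != 2 or any(len(g) == 0 for g in groups):
        log.warning("group with zero eligible samples; comparison skipped")
        return per_sample, float("nan")
    p = _ranksum(groups[0], groups[1])
    return per_sample, p


def count_vs_group(assignments: pd.DataFrame, label_col: str,
                   meta: pd.DataFrame, group_col: str,
                   signatures: list[str]) -> pd.DataFrame:
    """Two-sided rank-sum comparison of per-sample signature mutation counts
    between the two groups of ``group_col``."""
    levels = sorted(meta[group_col].dropna().unique())
    if len(levels) != 2:
        raise ValueError(f"{group_col} must have exactly two groups")
    membership = meta.set_index("sample")[group_col]
    rows = []
    for sig in signatures:
        counts = (assignments[assignments[label_col] == sig]
                  .groupby("sample").size())
        counts = counts.reindex(meta["sample"], fill_value=0)
        a = counts[membership.loc[counts.index] == levels[0]].to_numpy(float)
        bvals = counts[membership.loc[counts.index] == levels[1]].to_numpy(float)
        if len(a) == 0 or len(bvals) == 0:
            raise ValueError(f"empty group for {group_col}")
        rows.append((sig, levels[0], float(np.median(a)),
                     levels[1], float(np.median(bvals)), _ranksum(a, bvals)))
    return pd.DataFrame(rows, columns=["signature", "group_a", "median_a",
                                       "group_b", "median_b", "p"])


def _ranksum(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U): exact enumeration for
    small tie-free samples, normal approximation with tie correction
    otherwise.  Infinite values are allowed (rank-based)."""
    finite = np.concatenate([a, b])
    has_ties = np.unique(finite).size < finite.size
    exact = (len(a) <= 20 and len(b) <= 20 and not has_ties
             and np.all(np.isfinite(finite)))
    method = "exact" if exact else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method).pvalue)
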
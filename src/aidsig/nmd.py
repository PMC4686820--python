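"""Nearest-mutation distance, clustered/non-clustered partition and the
stratified 96 x 2M count matrix.

The nearest-mutation distance (NMD) of a mutation is the minimum genomic
distance to any other mutation of the same sample on the same chromosome.
Mutations with NMD <= 1,000 nt form the "clustered" stratum; the rest
(including mutations alone on their chromosome, which have no neighbour)
are "non-clustered".  Each sample contributes two adjacent columns to the
count matrix, one per stratum, so a 30-sample cohort yields 96 x 60.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channels import CHANNEL_LABELS, N_CHANNELS

CLUSTERED = "clustered"
NON_CLUSTERED = "non_clustered"
STRATA = (CLUSTERED, NON_CLUSTERED)

DEFAULT_NMD_THRESHOLD = 1000


def compute_nmd(muts: pd.DataFrame) -> pd.DataFrame:
    """Set the ``nmd`` column: per (sample, chromosome), the distance to the
    nearest other mutation.  Lone mutations get NaN (the "unpaired" sentinel).
    """
    muts = muts.reset_index(drop=True).copy()
    nmd = np.full(len(muts), np.nan)
    for _, idx in muts.groupby(["sample", "chrom"], sort=False).groups.items():
        idx = np.asarray(idx)
        if idx.size < 2:
            continue
        pos = muts["pos"].to_numpy()[idx]
        order = np.argsort(pos, kind="stable")
        sp = pos[order].astype(np.int64)
        gaps = np.diff(sp)
        d = np.empty(sp.size)
        d[0] = gaps[0]
        d[-1] = gaps[-1]
        if sp.size > 2:
            d[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        nmd[idx[order]] = d
    muts["nmd"] = nmd
    return muts


def partition(muts: pd.DataFrame,
              threshold_nt: int = DEFAULT_NMD_THRESHOLD) -> pd.DataFrame:
    """Set ``stratum``: clustered iff nmd <= threshold_nt (inclusive
    boundary); unpaired mutations are non-clustered."""
    if threshold_nt <= 0:
        raise ValueError("NMD threshold must be positive")
    if "nmd" not in muts.columns:
        raise ValueError("compute_nmd must run before partition")
    muts = muts.copy()
    nmd = muts["nmd"].to_numpy(dtype=float)
    clustered = np.where(np.isnan(nmd), False, nmd <= threshold_nt)
    muts["stratum"] = np.where(clustered, CLUSTERED, NON_CLUSTERED)
    return muts


@dataclass
class StratifiedCountMatrix:
    """The 96 x 2M mutation count matrix X.

    ``column_meta`` holds (sample, stratum) per column, two adjacent
    columns per sample in fixed sample order (clustered first).
    """

    counts: np.ndarray
    column_meta: list[tuple[str, str]]
    channel_labels: list[str] = field(default_factory=lambda: list(CHANNEL_LABELS))

    @property
    def samples(self) -> list[str]:
        return [s for s, st in self.column_meta if st == CLUSTERED]

    @property
    def column_labels(self) -> list[str]:
        return [f"{s}__{'clustered' if st == CLUSTERED else 'nonclustered'}"
                for s, st in self.column_meta]

    def column_index(self) -> dict[tuple[str, str], int]:
        return {key: j for j, key in enumerate(self.column_meta)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.channel_labels,
                            columns=self.column_labels)


def build_matrix(muts: pd.DataFrame, samples: list[str]) -> StratifiedCountMatrix:
    """Count channel-annotated mutations into the stratified matrix.

    Records with channel < 0 (excluded during annotation) are ignored.
    Samples with no mutations yield two zero columns; a mutation whose
    sample is not in ``samples`` raises.
    """
    for col in ("channel", "stratum"):
        if col not in muts.columns:
            raise ValueError(f"mutations lack {col!r}; run the upstream stages")
    known = set(samples)
    unknown = set(muts["sample"].unique()) - known
    if unknown:
        raise ValueError(f"mutations from unlisted samples: {sorted(unknown)}")

    col_of = {(s, st): 2 * i + (0 if st == CLUSTERED else 1)
              for i, s in enumerate(samples) for st in STRATA}
    counts = np.zeros((N_CHANNELS, 2 * len(samples)), dtype=np.int64)
    usable = muts[muts["channel"] >= 0]
    j = np.fromiter((col_of[(s, st)] for s, st in
                     zip(usable["sample"], usable["stratum"])),
                    dtype=np.int64, count=len(usable))
    np.add.at(counts, (usable["channel"].to_numpy(dtype=np.int64), j), 1)
    meta = [(s, st) for s in samples for st in STRATA]
    return StratifiedCountMatrix(counts=counts, column_meta=meta)


def spectrum_compare(matrix: StratifiedCountMatrix) -> pd.DataFrame:
    """Per-channel mutation proportions within each stratum and their ratio.

    Returns a DataFrame indexed by channel label with columns
    clustered_prop, nonclustered_prop (each summing to 1) and
    clustered_enrichment (ratio, NaN-safe), sorted by channel index.
    Channels over-represented in the clustered stratum rank highest by
    clustered_enrichment.
    """
    strata_cols = {st: [j for j, (_, s) in enumerate(matrix.column_meta)
                        if s == st] for st in STRATA}
    totals = {st: matrix.counts[:, cols].sum(axis=1)
              for st, cols in strata_cols.items()}
    out = pd.DataFrame(index=matrix.channel_labels)
    for st, name in ((CLUSTERED, "clustered_prop"),
                     (NON_CLUSTERED, "nonclustered_prop")):
        tot = totals[st].sum()
        out[name] = totals[st] / tot if tot > 0 else np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        out["clustered_enrichment"] = (
            out["clustered_prop"] / out["nonclustered_prop"])
    return out
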
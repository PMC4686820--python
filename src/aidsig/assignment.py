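"""Per-mutation signature association probabilities and hard assignment.

For a mutation in trinucleotide channel i of sample-stratum column j, the
probability that signature k generated it is the signature's share of the
reconstructed intensity at that cell,

    p_ms = W[i,k] H[k,j] / sum_k' W[i,k'] H[k',j],

identical for all mutations sharing (i, j).  Hard assignment uses a strict
threshold on p_ms (0.75 for signature calling, 0.5 as the looser option
for the clonality ratio analyses); at any threshold >= 0.5 at most one
signature can qualify.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ardnmf import SignatureModel
from .nmd import StratifiedCountMatrix, CLUSTERED, STRATA

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

DEFAULT_THRESHOLD = 0.75


def compute_pms(muts: pd.DataFrame, model: SignatureModel,
                matrix: StratifiedCountMatrix) -> pd.DataFrame:
    """Attach p_ms columns (``p_<signature>``) to the mutation table.

    Mutations must carry channel and stratum; the model must be normalized
    and its H columns must follow ``matrix.column_meta``.  Mutations whose
    (channel, column) cell has zero reconstructed intensity are tallied and
    left with NaN probabilities (they can never be assigned).
    """
    if model.W.size == 0:
        raise ValueError("model is not normalized")
    names = model.signature_names
    col_of = matrix.column_index()
    muts = muts.reset_index(drop=True).copy()
    usable = muts["channel"].to_numpy() >= 0
    i = muts["channel"].to_numpy(dtype=np.int64)
    j = np.fromiter((col_of[(s, st)] for s, st in
                     zip(muts["sample"], muts["stratum"])),
                    dtype=np.int64, count=len(muts))
    # numerator per mutation and signature; rows with channel -1 masked out
    num = np.where(usable[:, None],
                   model.W[np.clip(i, 0, None), :] * model.H[:, j].T, np.nan)
    denom = num.sum(axis=1)
    zero = usable & ~(denom > 0)
    if zero.any():
        log.warning("%d mutations at cells with zero reconstructed "
                    "intensity left unassigned", int(zero.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        P = num / denom[:, None]
    P[zero | ~usable] = np.nan
    for k, name in enumerate(names):
        muts[f"p_{name}"] = P[:, k]
    muts.attrs["signatures"] = list(names)
    return muts


def assign(table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
           signatures: list[str] | None = None) -> pd.Series:
    """Hard labels: the signature whose p_ms strictly exceeds ``threshold``,
    else "unassigned".  Returns a Series aligned with the table."""
    if not 0 <= threshold < 1:
        raise ValueError("threshold must be in [0, 1)")
    sigs = signatures or table.attrs.get("signatures")
    if not sigs:
        sigs = [c[2:] for c in table.columns if c.startswith("p_")]
    P = table[[f"p_{s}" for s in sigs]].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        best = np.nanmax(P, axis=1, initial=-np.inf)
        arg = np.where(np.isfinite(best), np.argmax(np.nan_to_num(P, nan=-1.0),
                                                    axis=1), 0)
    labels = np.where(best > threshold, np.asarray(sigs, dtype=object)[arg],
                      UNASSIGNED)
    return pd.Series(labels, index=table.index, name=f"assigned_{threshold:g}")


def assignment_table(muts: pd.DataFrame, model: SignatureModel,
                     matrix: StratifiedCountMatrix,
                     thresholds: tuple[float, ...] = (0.5, 0.75)
                     ) -> pd.DataFrame:
    """p_ms plus hard labels at each threshold (columns assigned_<t>)."""
    table = compute_pms(muts, model, matrix)
    for t in thresholds:
        table[f"assigned_{t:g}"] = assign(table, threshold=t)
    return table


def signature_totals(table: pd.DataFrame,
                     signatures: list[str] | None = None) -> pd.Series:
    """Sum of p_ms over mutations per signature (soft mutation counts).

    Conservation check: matches the mutation totals attributed by H for
    cells that contain observed mutations.
    """
    sigs = signatures or table.attrs.get("signatures") or \
        [c[2:] for c in table.columns if c.startswith("p_")]
    return pd.Series({s: float(table[f"p_{s}"].sum(skipna=True)) for s in sigs})
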
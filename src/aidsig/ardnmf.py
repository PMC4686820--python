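"""Bayesian NMF with exponential priors and automatic relevance determination.

The stratified count matrix X (96 x 2M) is modelled with a Poisson
likelihood, X ~ Poisson(W'H'), equivalently a Kullback-Leibler divergence
objective.  Every entry of the k-th column of W' and the k-th row of H'
shares an exponential prior with scale lambda_k, and each lambda_k carries
an inverse-gamma(a, b) hyperprior.  MAP estimation uses multiplicative
majorisation-minimisation updates for W' and H' interleaved with the
closed-form lambda update; relevance weights of unneeded components shrink,
driving those components towards zero, so the effective number of
signatures K is read off after convergence by dropping components whose
fractional contribution falls below ``prune_frac``.

The negative log posterior (up to additive constants) is

    F = D_KL(X || W'H')
        + sum_k (||w'_k||_1 + ||h'_k||_1 + b) / lambda_k
        + (F_dim + N_dim + a + 1) * sum_k log lambda_k

which each block update never increases.  The scaling transform
W = W' U^-1, H = U H' (U = diag of column 1-norms of W') converts the raw
factors into unit-sum signature spectra W and mutation-count activities H
with W H = W' H' on the active components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ARDHyper:
    """Hyperparameters of the ARD exponential-prior model.

    a: inverse-gamma shape of the relevance hyperprior.
    b: inverse-gamma scale; None selects sqrt(mean(X) * (a - 1) / K0) so
       the prior scale matches the data magnitude.
    tol: relative objective-change convergence threshold.
    max_iter: iteration cap.
    prune_frac: components contributing less than this fraction of
       sum_k ||w'_k||_1 ||h'_k||_1 are pruned after convergence.
    """

    a: float = 10.0
    b: float | None = None
    tol: float = 1e-7
    max_iter: int = 10_000
    prune_frac: float = 1e-3


@dataclass
class SignatureModel:
    """Result of one ARD-NMF fit."""

    W_raw: np.ndarray            # 96 x K0, W'
    H_raw: np.ndarray            # K0 x 2M, H'
    relevance: np.ndarray        # lambda_k, K0
    active: np.ndarray           # boolean mask over K0 components
    K: int
    W: np.ndarray                # 96 x K, unit column sums
    H: np.ndarray                # K x 2M
    log_posterior: float
    seed: int
    n_iter: int
    converged: bool
    column_labels: list[str] = field(default_factory=list)
    signature_names: list[str] = field(default_factory=list)

    def rename(self, names: list[str]) -> "SignatureModel":
        if len(names) != self.K:
            raise ValueError("one name per active component required")
        self.signature_names = list(names)
        return self


def _kl_objective(X, WH):
    mask = X > 0
    obj = WH.sum() - X.sum()
    xm, whm = X[mask], WH[mask]
    return obj + float(np.sum(xm * np.log(xm / whm)))


def mm_update(X: np.ndarray, W: np.ndarray, H: np.ndarray,
              inv_lambda: np.ndarray | float = 0.0
              ) -> tuple[np.ndarray, np.ndarray]:
    """One multiplicative MM sweep (W then H) of the penalised KL objective.

    ``inv_lambda`` is the per-component exponential prior rate 1/lambda_k;
    with it set to 0 (the vanishing-prior limit) this is exactly the
    standard KL-NMF multiplicative update.
    """
    inv_lambda = np.broadcast_to(np.asarray(inv_lambda, dtype=float),
                                 (W.shape[1],))
    eps = np.finfo(float).tiny
    WH = W @ H
    R = np.where(X > 0, X / np.maximum(WH, eps), 0.0)
    W = W * (R @ H.T) / (H.sum(axis=1)[None, :] + inv_lambda[None, :] + eps)
    WH = W @ H
    R = np.where(X > 0, X / np.maximum(WH, eps), 0.0)
    H = H * (W.T @ R) / (W.sum(axis=0)[:, None] + inv_lambda[:, None] + eps)
    return W, H


def fit_once(X, K0: int = 20, hyper: ARDHyper | None = None,
             seed: int = 0, init_W: np.ndarray | None = None,
             init_H: np.ndarray | None = None,
             column_labels: list[str] | None = None,
             track_objective: bool = False) -> SignatureModel:
    """MAP ARD-NMF fit from one random initialisation.

    Deterministic given ``seed`` (or the explicit init).  Raises on an
    all-zero X and on NaN appearing in the updates (reporting the
    iteration index).
    """
    X = np.asarray(getattr(X, "counts", X), dtype=float)
    if X.ndim != 2 or K0 < 1:
        raise ValueError("X must be 2-D and K0 >= 1")
    if not np.any(X > 0):
        raise ValueError("count matrix is all zero")
    if np.any(X < 0):
        raise ValueError("count matrix has negative entries")
    hyper = hyper or ARDHyper()
    F, N = X.shape
    b = hyper.b if hyper.b is not None else \
        float(np.sqrt(X.mean() * (hyper.a - 1) / K0))

    rng = np.random.default_rng(seed)
    W = rng.uniform(size=(F, K0)) if init_W is None else np.array(init_W, float)
    H = rng.uniform(size=(K0, N)) if init_H is None else np.array(init_H, float)
    scale = np.sqrt(X.mean() / (W @ H).mean())
    if init_W is None:
        W *= scale
    if init_H is None:
        H *= scale

    denom = F + N + hyper.a + 1
    lam = (W.sum(axis=0) + H.sum(axis=1) + b) / denom

    obj_prev = np.inf
    converged = False
    trace: list[float] = []
    it = 0
    check_every = 10
    for it in range(1, hyper.max_iter + 1):
        W, H = mm_update(X, W, H, 1.0 / lam)
        lam = (W.sum(axis=0) + H.sum(axis=1) + b) / denom
        if np.any(~np.isfinite(W)) or np.any(~np.isfinite(H)):
            raise FloatingPointError(f"non-finite factor entries at iteration {it}")
        if track_objective or it % check_every == 0 or it == hyper.max_iter:
            obj = (_kl_objective(X, W @ H)
                   + float(np.sum((W.sum(axis=0) + H.sum(axis=1) + b) / lam))
                   + denom * float(np.sum(np.log(lam))))
            if track_objective:
                trace.append(obj)
            if it % check_every == 0 or it == hyper.max_iter:
                if np.isfinite(obj_prev) and \
                        abs(obj_prev - obj) <= hyper.tol * abs(obj_prev):
                    converged = True
                    obj_prev = obj
                    break
                obj_prev = obj

    contrib = W.sum(axis=0) * H.sum(axis=1)
    total = contrib.sum()
    active = contrib > hyper.prune_frac * total if total > 0 else contrib > 0
    if not active.any():
        active = contrib == contrib.max()
    model = SignatureModel(
        W_raw=W, H_raw=H, relevance=lam, active=active, K=int(active.sum()),
        W=np.empty(0), H=np.empty(0), log_posterior=-obj_prev, seed=seed,
        n_iter=it, converged=converged,
        column_labels=list(column_labels or []))
    if track_objective:
        model.objective_trace = np.asarray(trace)  # type: ignore[attr-defined]
    return normalize(model)


def normalize(model: SignatureModel) -> SignatureModel:
    """Scaling transform: W = W'U^-1 (unit column sums), H = U H', restricted
    to active components.  Raises if an active column of W' has zero norm."""
    act = model.active
    Wp = model.W_raw[:, act]
    Hp = model.H_raw[act, :]
    u = Wp.sum(axis=0)
    if np.any(u <= 0):
        raise ValueError("active component with zero-norm W' column")
    model.W = Wp / u
    model.H = u[:, None] * Hp
    model.K = int(act.sum())
    if not model.signature_names:
        model.signature_names = [f"S{k+1}" for k in range(model.K)]
    return model


def fit_restarts(X, K0: int = 20, hyper: ARDHyper | None = None,
                 n_restarts: int = 50, seed0: int = 0,
                 column_labels: list[str] | None = None
                 ) -> tuple[SignatureModel, pd.DataFrame]:
    """Multi-restart fit: seeds seed0 .. seed0+n_restarts-1.

    Selects the modal K across restarts (ties broken toward smaller K),
    then the maximum-posterior run among those.  Returns (model, log)
    where log records seed, K, log_posterior, n_iter, converged per restart.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    runs = [fit_once(X, K0=K0, hyper=hyper, seed=seed0 + r,
                     column_labels=column_labels)
            for r in range(n_restarts)]
    logdf = pd.DataFrame({
        "seed": [m.seed for m in runs],
        "K": [m.K for m in runs],
        "log_posterior": [m.log_posterior for m in runs],
        "n_iter": [m.n_iter for m in runs],
        "converged": [m.converged for m in runs],
    })
    counts = logdf["K"].value_counts()
    modal_k = int(min(counts[counts == counts.max()].index))
    best = max((m for m in runs if m.K == modal_k),
               key=lambda m: m.log_posterior)
    return best, logdf


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        return 0.0
    return float(u @ v / (nu * nv))


def match_signatures(W: np.ndarray, reference: pd.DataFrame,
                     min_cosine: float = 0.0) -> tuple[list[str], np.ndarray]:
    """Greedy best-match of fitted components to reference spectra.

    ``reference`` is a DataFrame of reference spectra (96 rows, one column
    per named signature).  Returns (names, cosines) per component;
    components left unmatched (or below ``min_cosine``) are named "other".
    Matching is by cosine similarity and is invariant to reference column
    order.
    """
    W = np.asarray(W, dtype=float)
    refs = reference.to_numpy(dtype=float)
    ref_names = list(reference.columns)
    K, R = W.shape[1], refs.shape[1]
    sim = np.array([[cosine_similarity(W[:, k], refs[:, r])
                     for r in range(R)] for k in range(K)])
    names = ["other"] * K
    cosines = np.zeros(K)
    work = sim.copy()
    for _ in range(min(K, R)):
        k, r = np.unravel_index(np.argmax(work), work.shape)
        if work[k, r] < min_cosine or work[k, r] <= -np.inf:
            break
        names[k] = ref_names[r]
        cosines[k] = sim[k, r]
        work[k, :] = -np.inf
        work[:, r] = -np.inf
    for k in range(K):
        if names[k] == "other":
            cosines[k] = float(sim[k].max()) if R else 0.0
    return names, cosines
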
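"""Survey-weighted least-squares non-negative matrix factorisation.

Factorises a non-negative individual x food-group intake matrix X as W @ H
with W, H >= 0, minimising the survey-weighted squared error

    F(W, H) = sum_i s_i * sum_j (x_ij - (WH)_ij)^2,

where s_i is the survey weight of individual i.  Each row of H is a
"consumption system" (CS): a non-negative combination of food groups; each
row of W holds the weight of every CS in one individual's diet.  The
minimisation uses multiplicative updates with an elementwise weight matrix
(least-squares NMF), which reduce to the classical Lee-Seung Frobenius
updates when all weights are equal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

_EPS = 1e-12  # denominator stabiliser in multiplicative updates


@dataclass
class FactorPair:
    """Result of one NMF fit.

    Attributes
    ----------
    W : (n, k) scores — weight of each CS in each individual's diet.
    H : (k, p) loadings — contribution of each food group to each CS.
    objective_trace : weighted residual sum of squares per iteration
        (index 0 is the objective at initialisation).
    """

    W: np.ndarray
    H: np.ndarray
    objective_trace: np.ndarray
    k: int
    converged: bool
    n_iter: int
    food_groups: list[str] | None = None
    individual_ids: list[str] | None = None


@dataclass
class RankDiagnostics:
    """Objective-vs-rank curve and the automated elbow suggestion.

    The suggested rank maximises the discrete second difference of the best
    objective over the scanned ranks; the full curve is kept so the analyst
    can overrule it on interpretability grounds.
    """

    k_values: list[int]
    best_objective: list[float]
    elbow_score: dict[int, float] = field(default_factory=dict)
    suggested_k: int = 0

    def to_dict(self) -> dict:
        return {
            "k_values": self.k_values,
            "best_objective": self.best_objective,
            "elbow_score": {str(k): v for k, v in self.elbow_score.items()},
            "suggested_k": self.suggested_k,
        }


def _as_matrix(X) -> np.ndarray:
    A = np.asarray(getattr(X, "values", X), dtype=float)
    if A.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if np.any(A < 0):
        raise ValueError("X must be non-negative")
    return A


def weighted_rss(X: np.ndarray, W: np.ndarray, H: np.ndarray, s: np.ndarray) -> float:
    """Survey-weighted residual sum of squares sum_i s_i ||x_i - (WH)_i||^2."""
    R = X - W @ H
    return float(np.einsum("i,ij,ij->", s, R, R))


def ls_nmf(
    X,
    weights=None,
    k: int = 2,
    *,
    seed: int | None = None,
    W0: np.ndarray | None = None,
    H0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorPair:
    """Weighted multiplicative-update NMF of a non-negative matrix.

    Parameters
    ----------
    X : (n, p) non-negative array or DataFrame (g/d intake).
    weights : per-individual survey weights (positive); None means equal.
    k : rank (number of consumption systems), 1 <= k <= min(n, p).
    seed : seeds the uniform initialisation in (0, mean(X)/k] when W0/H0
        are not supplied.
    tol : stop when the relative objective change drops below this.
    max_iter : iteration cap.

    With per-row weight matrix U (u_ij = s_i) the updates are

        H <- H * (W' (U*X)) / (W' (U*(WH)) + eps)
        W <- W * ((U*X) H') / ((U*(WH)) H' + eps)

    which keep the factors non-negative and never increase the objective.
    """
    A = _as_matrix(X)
    n, p = A.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"rank k={k} outside [1, {min(n, p)}]")
    if weights is None:
        s = np.ones(n)
    else:
        s = np.asarray(getattr(weights, "values", weights), dtype=float).ravel()
        if s.shape != (n,) or np.any(s <= 0):
            raise ValueError("weights must be positive, one per row of X")

    if W0 is None or H0 is None:
        rng = np.random.default_rng(seed)
        hi = max(A.mean() / k, _EPS)
        W = hi * (1.0 - rng.random((n, k))) if W0 is None else np.array(W0, dtype=float)
        H = hi * (1.0 - rng.random((k, p))) if H0 is None else np.array(H0, dtype=float)
    else:
        W = np.array(W0, dtype=float)
        H = np.array(H0, dtype=float)
    if W.shape != (n, k) or H.shape != (k, p):
        raise ValueError("W0/H0 shapes inconsistent with X and k")

    SX = A * s[:, None]
    trace = [weighted_rss(A, W, H, s)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        WH = W @ H
        H *= (W.T @ SX) / (W.T @ (WH * s[:, None]) + _EPS)
        WH = W @ H
        W *= (SX @ H.T) / ((WH * s[:, None]) @ H.T + _EPS)
        obj = weighted_rss(A, W, H, s)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            converged = True
            break

    fp = FactorPair(
        W=W,
        H=H,
        objective_trace=np.asarray(trace),
        k=k,
        converged=converged,
        n_iter=it,
    )
    cols = getattr(X, "columns", None)
    idx = getattr(X, "index", None)
    if cols is not None:
        fp.food_groups = list(cols)
    if idx is not None:
        fp.individual_ids = list(idx)
    return fp


def ls_nmf_restarts(
    X,
    weights=None,
    k: int = 2,
    *,
    n_restarts: int = 10,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> FactorPair:
    """Best of ``n_restarts`` seeded runs (lowest final objective)."""
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    ss = np.random.SeedSequence(seed)
    best: FactorPair | None = None
    for child in ss.spawn(n_restarts):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        fp = ls_nmf(X, weights, k, seed=run_seed, tol=tol, max_iter=max_iter)
        if best is None or fp.objective_trace[-1] < best.objective_trace[-1]:
            best = fp
    return best


def lee_seung_mu(X, k, W0, H0, n_iter):
    """Unweighted Lee-Seung Frobenius multiplicative updates (reference).

    Runs exactly ``n_iter`` iterations from the given initialisation with the
    same denominator stabiliser as :func:`ls_nmf`; used as the equal-weights
    oracle in tests.
    """
    A = _as_matrix(X)
    W = np.array(W0, dtype=float)
    H = np.array(H0, dtype=float)
    for _ in range(n_iter):
        H *= (W.T @ A) / (W.T @ W @ H + _EPS)
        W *= (A @ H.T) / (W @ (H @ H.T) + _EPS)
    return W, H


def select_rank(
    X,
    weights=None,
    k_range=range(2, 11),
    *,
    n_restarts: int = 3,
    seed: int | None = None,
    tol: float = 1e-5,
    max_iter: int = 500,
) -> RankDiagnostics:
    """Scan ranks and suggest one via the elbow of the objective curve.

    For each k the best weighted objective over ``n_restarts`` is recorded;
    the suggested rank maximises the discrete second difference of the log
    objective, log f(k-1) - 2 log f(k) + log f(k+1) — the point where the
    relative marginal improvement collapses (the log makes the elbow
    invariant to the overall scale of the data).  The analyst inspects the
    emitted curve before accepting the suggestion.
    """
    ks = sorted(int(k) for k in k_range)
    if len(ks) < 3:
        raise ValueError("k_range must contain at least 3 ranks for an elbow")
    ss = np.random.SeedSequence(seed)
    objs = []
    for k, child in zip(ks, ss.spawn(len(ks))):
        fp = ls_nmf_restarts(
            X,
            weights,
            k,
            n_restarts=n_restarts,
            seed=int(child.generate_state(1)[0] % (2**31)),
            tol=tol,
            max_iter=max_iter,
        )
        objs.append(float(fp.objective_trace[-1]))
    # enforce monotone best-objective curve (a restart miss at higher k
    # cannot beat the nested lower-rank optimum)
    objs = list(np.minimum.accumulate(objs))
    logs = np.log(np.maximum(objs, 1e-300))
    elbow = {
        ks[i]: float(logs[i - 1] - 2 * logs[i] + logs[i + 1])
        for i in range(1, len(ks) - 1)
    }
    suggested = max(elbow, key=lambda k: (elbow[k], -k))
    return RankDiagnostics(
        k_values=ks, best_objective=objs, elbow_score=elbow, suggested_k=suggested
    )


def normalize_factors(fp: FactorPair) -> FactorPair:
    """Rescale each CS so its loading row sums to 1, moving scale into W.

    Leaves the product W @ H unchanged; loading entries then read directly as
    the proportional contribution of each food group to the CS.
    """
    rs = fp.H.sum(axis=1)
    if np.any(rs <= 0):
        raise ValueError("degenerate factor: H row with non-positive sum")
    return FactorPair(
        W=fp.W * rs[None, :],
        H=fp.H / rs[:, None],
        objective_trace=fp.objective_trace,
        k=fp.k,
        converged=fp.converged,
        n_iter=fp.n_iter,
        food_groups=fp.food_groups,
        individual_ids=fp.individual_ids,
    )


def loading_contributions(fp: FactorPair, cutoff: float = 0.025):
    """Per-CS food-group contributions (%) with main-contributor flags.

    Requires row-normalised loadings.  A food group is a main contributor to
    a CS when its contribution is at least ``cutoff`` (default 2.5 %).
    Returns a long DataFrame (cs, food_group, contribution_pct, is_main)
    sorted by contribution within CS.
    """
    import pandas as pd

    if not np.allclose(fp.H.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("loadings must be row-normalised; call normalize_factors first")
    foods = fp.food_groups or [f"food_{j}" for j in range(fp.H.shape[1])]
    frames = []
    for r in range(fp.k):
        df = pd.DataFrame(
            {
                "cs": r + 1,
                "food_group": foods,
                "contribution_pct": fp.H[r] * 100.0,
            }
        )
        df["is_main"] = df["contribution_pct"] >= cutoff * 100.0
        frames.append(df.sort_values("contribution_pct", ascending=False))
    return pd.concat(frames, ignore_index=True)


def match_factors(H_est: np.ndarray, H_ref: np.ndarray):
    """Optimal one-to-one matching of estimated to reference CS loadings.

    Maximises total cosine similarity over permutations (NMF is identifiable
    only up to permutation and scale).  Returns ``(perm, cosines)`` where
    ``H_est[perm[r]]`` matches ``H_ref[r]`` with similarity ``cosines[r]``.
    """
    A = np.asarray(H_est, float)
    B = np.asarray(H_ref, float)
    if A.shape != B.shape:
        raise ValueError("loading matrices must have identical shape")
    An = A / np.maximum(np.linalg.norm(A, axis=1, keepdims=True), _EPS)
    Bn = B / np.maximum(np.linalg.norm(B, axis=1, keepdims=True), _EPS)
    C = Bn @ An.T                      # C[r, e] = cos(ref r, est e)
    rows, cols = linear_sum_assignment(-C)
    return cols, C[rows, cols]
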
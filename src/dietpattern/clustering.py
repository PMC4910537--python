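"""Dietary-pattern clustering of individuals on their CS scores.

Ward hierarchical agglomeration in CS-score space with survey weights
entering as observation masses in the merge cost, cluster-count selection by
the between-cluster : total inertia ratio, and pattern description via
V-tests and relative CS contributions.

The merge table follows the scipy 4-column convention
(child_a, child_b, height, mass of the merged cluster); with unit masses it
coincides with ``scipy.cluster.hierarchy.linkage(..., method="ward")``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

V_TEST_THRESHOLD = 1.96  # two-sided 5 % significance


@dataclass
class PatternAssignment:
    """Partition of individuals into dietary patterns plus diagnostics."""

    labels: np.ndarray                    # 1..C per individual
    linkage: np.ndarray                   # (n-1, 4) merge table
    inertia_ratio: dict[int, float]       # candidate C -> ratio
    chosen_c: int
    shares_pct: pd.Series                 # survey-weighted % per pattern
    individual_ids: list[str] | None = None


@dataclass
class PatternDescription:
    """V-tests and relative CS contributions per (pattern, CS)."""

    v_tests: pd.DataFrame                 # pattern x CS
    significant_positive: pd.DataFrame    # boolean pattern x CS (descriptors)
    relative_contribution: pd.DataFrame   # pattern x CS, rows sum to 1


# ---------------------------------------------------------------------------
# Weighted Ward agglomeration (nearest-neighbour chain)
# ---------------------------------------------------------------------------


def hca_ward(W, weights=None) -> np.ndarray:
    """Ward linkage of rows of W with survey weights as observation masses.

    The dissimilarity between clusters u, v with masses m_u, m_v and
    centroids c_u, c_v is the inertia increase of their merge,
    delta = m_u m_v / (m_u + m_v) * ||c_u - c_v||^2, maintained by the
    Lance-Williams recurrence; reported heights are sqrt(2 * delta), which
    reduces to scipy's Ward linkage for unit masses.  Ties break on the
    lowest cluster index, making the tree deterministic.
    """
    X = np.asarray(getattr(W, "values", W), dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 individuals to cluster")
    if not np.all(np.isfinite(X)):
        raise ValueError("scores must be finite")
    n = X.shape[0]
    if weights is None:
        m = np.ones(n)
    else:
        m = np.asarray(getattr(weights, "values", weights), dtype=float).ravel()
        if m.shape != (n,) or np.any(m <= 0):
            raise ValueError("weights must be positive, one per individual")

    # pairwise merge costs delta(i, j)
    sq = (X * X).sum(axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * X @ X.T, 0.0)
    mm = m[:, None] * m[None, :] / (m[:, None] + m[None, :])
    D = mm * d2
    np.fill_diagonal(D, np.inf)

    active = np.ones(n, dtype=bool)
    mass = m.copy().astype(float)
    cluster_id = np.arange(n)             # scipy-style ids per active slot
    Z = np.zeros((n - 1, 4))
    chain: list[int] = []
    next_id = n

    for t in range(n - 1):
        if not chain:
            chain.append(int(np.flatnonzero(active)[0]))
        while True:
            a = chain[-1]
            row = np.where(active, D[a], np.inf)
            row[a] = np.inf
            b = int(np.argmin(row))       # argmin breaks ties on lowest index
            if len(chain) >= 2 and b == chain[-2]:
                break
            chain.append(b)
        chain.pop()
        chain.pop()
        a, b = (a, b) if a < b else (b, a)

        delta = D[a, b]
        ma, mb = mass[a], mass[b]
        ida, idb = cluster_id[a], cluster_id[b]
        Z[t] = (min(ida, idb), max(ida, idb), np.sqrt(2.0 * delta), ma + mb)

        # Lance-Williams update of delta(new, w) into slot a
        act = active.copy()
        act[a] = act[b] = False
        idx = np.flatnonzero(act)
        if idx.size:
            mw = mass[idx]
            D[a, idx] = (
                (ma + mw) * D[a, idx] + (mb + mw) * D[b, idx] - mw * delta
            ) / (ma + mb + mw)
            D[idx, a] = D[a, idx]
        active[b] = False
        mass[a] = ma + mb
        cluster_id[a] = next_id
        next_id += 1
    return Z


def cut_tree(Z: np.ndarray, n_clusters: int) -> np.ndarray:
    """Labels 1..C from the merge table by undoing the last C-1 merges."""
    n = Z.shape[0] + 1
    if not 1 <= n_clusters <= n:
        raise ValueError("n_clusters out of range")
    parent = np.arange(n + Z.shape[0])

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n - n_clusters):
        new = n + t
        parent[find(int(Z[t, 0]))] = new
        parent[find(int(Z[t, 1]))] = new
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    # relabel by first appearance so labels are stable in individual order
    order = {}
    out = np.empty(n, dtype=int)
    for i, r in enumerate(labels):
        if r not in order:
            order[r] = len(order) + 1
        out[i] = order[r]
    return out


# ---------------------------------------------------------------------------
# Cluster-count selection by inertia ratio
# ---------------------------------------------------------------------------


def inertia_ratio(W, labels, weights=None) -> float:
    """Survey-weighted between-cluster inertia over total inertia."""
    X = np.asarray(getattr(W, "values", W), dtype=float)
    lab = np.asarray(labels)
    n = X.shape[0]
    m = np.ones(n) if weights is None else np.asarray(weights, dtype=float).ravel()
    mu = np.average(X, axis=0, weights=m)
    total = float(np.einsum("i,ij->", m, (X - mu) ** 2))
    if total == 0:
        return 1.0
    between = 0.0
    for c in np.unique(lab):
        sel = lab == c
        mc = m[sel].sum()
        cc = np.average(X[sel], axis=0, weights=m[sel])
        between += mc * float(((cc - mu) ** 2).sum())
    return between / total


def select_n_clusters(Z, W, weights=None, c_range=range(2, 13)):
    """Choose the cluster count from the inertia-ratio curve.

    ratio(C) is non-decreasing in C (nested partitions); the chosen C
    maximises the drop in marginal gain, gain(C) - gain(C+1) with
    gain(C) = ratio(C) - ratio(C-1) and ratio(1) = 0 — the elbow where an
    extra pattern stops paying for itself.  The full curve is returned for
    the interpretability judgement.
    """
    cs = sorted(int(c) for c in c_range)
    n = Z.shape[0] + 1
    if cs[0] < 2 or cs[-1] > n - 1:
        raise ValueError("c_range must lie within [2, n-1]")
    ratios: dict[int, float] = {}
    for c in [cs[0] - 1] + cs + [cs[-1] + 1]:
        if c < 1 or c > n:
            continue
        if c == 1:
            ratios[1] = 0.0
        else:
            ratios[c] = inertia_ratio(W, cut_tree(Z, c), weights)
    drops = {}
    for c in cs:
        if c - 1 in ratios and c + 1 in ratios:
            gain = ratios[c] - ratios[c - 1]
            gain_next = ratios[c + 1] - ratios[c]
            drops[c] = gain - gain_next
    chosen = max(drops, key=lambda c: (drops[c], -c)) if drops else cs[0]
    return chosen, {c: ratios[c] for c in cs if c in ratios}


# ---------------------------------------------------------------------------
# Pattern description
# ---------------------------------------------------------------------------


def v_test(scores, labels, weights=None) -> pd.DataFrame:
    """V-test of each pattern's mean CS weight against the population mean.

    v = (m_c - m) / sqrt( ((N - n_c) / (N - 1)) * s^2 / n_c )

    with survey-weighted cluster mean m_c, population mean m and variance
    s^2, and effective sizes n_c = sum of weights in the pattern, N = total.
    The finite-population factor reflects sampling the cluster without
    replacement.  The single-cluster partition gives v = 0 everywhere; a
    zero-variance CS gives v = 0 when m_c = m and +/-inf otherwise.
    """
    S = np.asarray(getattr(scores, "values", scores), dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    lab = np.asarray(labels)
    if lab.shape[0] != S.shape[0] or S.shape[0] < 2:
        raise ValueError("need >= 2 individuals with one label each")
    w = np.ones(S.shape[0]) if weights is None else np.asarray(weights, float).ravel()
    N = w.sum()
    m = np.average(S, axis=0, weights=w)
    s2 = np.average((S - m) ** 2, axis=0, weights=w)
    pats = np.unique(lab)
    out = np.zeros((len(pats), S.shape[1]))
    for r, c in enumerate(pats):
        sel = lab == c
        if not sel.any():
            raise ValueError(f"empty pattern {c}")
        nc = w[sel].sum()
        mc = np.average(S[sel], axis=0, weights=w[sel])
        denom2 = (N - nc) / (N - 1.0) * s2 / nc
        with np.errstate(divide="ignore", invalid="ignore"):
            v = (mc - m) / np.sqrt(denom2)
        equal = np.isclose(mc, m, atol=1e-12)
        v = np.where(equal, 0.0, v)
        with np.errstate(invalid="ignore"):
            v = np.where((denom2 <= 0) & ~equal, np.sign(mc - m) * np.inf, v)
        out[r] = v
    cols = getattr(scores, "columns", None)
    cols = list(cols) if cols is not None else [f"CS{j+1}" for j in range(S.shape[1])]
    return pd.DataFrame(out, index=pd.Index(pats, name="pattern"), columns=cols)


def describe_patterns(
    W, labels, weights=None, threshold: float = V_TEST_THRESHOLD
) -> PatternDescription:
    """V-tests, descriptor flags and relative contributions per pattern.

    The CS describing a pattern are those with significant AND positive
    V-tests.
    """
    vt = v_test(W, labels, weights)
    sig_pos = (vt >= threshold)
    rc = relative_contribution(W, labels)
    return PatternDescription(
        v_tests=vt, significant_positive=sig_pos, relative_contribution=rc
    )


def relative_contribution(W, labels) -> pd.DataFrame:
    """Share of each CS in a pattern's total CS weight; rows sum to 1.

    r_ck = sum_{i in c} W_ik / sum_{i in c} sum_k' W_ik'
    """
    S = np.asarray(getattr(W, "values", W), dtype=float)
    if np.any(S < 0):
        raise ValueError("scores must be non-negative")
    lab = np.asarray(labels)
    pats = np.unique(lab)
    rows = []
    for c in pats:
        tot = S[lab == c].sum()
        if tot <= 0:
            raise ValueError(f"pattern {c} has all-zero CS scores")
        rows.append(S[lab == c].sum(axis=0) / tot)
    cols = getattr(W, "columns", None)
    cols = list(cols) if cols is not None else [f"CS{j+1}" for j in range(S.shape[1])]
    return pd.DataFrame(rows, index=pd.Index(pats, name="pattern"), columns=cols)


def weighted_share(labels, weights=None) -> pd.Series:
    """Survey-weighted population share (%) of each pattern."""
    lab = np.asarray(labels)
    w = np.ones(lab.shape[0]) if weights is None else np.asarray(weights, float).ravel()
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    tot = w.sum()
    pats = np.unique(lab)
    return pd.Series(
        [w[lab == c].sum() / tot * 100.0 for c in pats],
        index=pd.Index(pats, name="pattern"),
        name="share_pct",
    )


def assign_patterns(
    W, weights=None, c_range=range(2, 13), n_clusters: int | None = None
) -> PatternAssignment:
    """Full clustering step: tree, cluster count, labels and shares."""
    Z = hca_ward(W, weights)
    if n_clusters is None:
        chosen, curve = select_n_clusters(Z, W, weights, c_range)
    else:
        chosen = int(n_clusters)
        _, curve = select_n_clusters(Z, W, weights, c_range)
    labels = cut_tree(Z, chosen)
    idx = getattr(W, "index", None)
    return PatternAssignment(
        labels=labels,
        linkage=Z,
        inertia_ratio=curve,
        chosen_c=chosen,
        shares_pct=weighted_share(labels, weights),
        individual_ids=list(idx) if idx is not None else None,
    )
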
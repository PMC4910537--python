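"""Socio-economic characterisation of dietary patterns.

Two tools: a household wealth index from a correspondence analysis of
categorical wealth items (first-axis score, cut into tertiles), and
sex-stratified one-vs-rest binomial logistic regressions giving the odds
ratio of pattern membership per covariate level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

_SEPARATION_COEF = 15.0  # |log-OR| beyond this flags likely separation
_Z95 = 1.959963984540054


def _weighted_logit(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """Pseudo-likelihood logistic fit with a design-based sandwich covariance.

    Point estimates solve the survey-weighted score equations (IRLS via
    GLM); the covariance is A^-1 B A^-1 with bread A = X' diag(w p(1-p)) X
    and meat B = X' diag(w^2 (y-p)^2) X, i.e. the weights enter the meat
    squared — sampling weights, not frequencies.
    """
    fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(maxiter=200)
    p = np.asarray(fit.fittedvalues)
    A = X.T @ (X * (w * p * (1 - p))[:, None])
    B = X.T @ (X * ((w * (y - p)) ** 2)[:, None])
    Ainv = np.linalg.pinv(A)
    se = np.sqrt(np.diag(Ainv @ B @ Ainv))
    params = np.asarray(fit.params)
    ci = np.column_stack([params - _Z95 * se, params + _Z95 * se])
    return params, ci, bool(fit.converged)


@dataclass
class WealthIndex:
    """First-axis CA score per individual plus its tertile (1..3)."""

    score: pd.Series
    tertile: pd.Series
    column_coords: pd.Series      # first-axis coordinates of item levels
    inertia_share: float          # share of total inertia on the first axis


def _disjunctive(items: pd.DataFrame) -> pd.DataFrame:
    """Indicator (complete disjunctive) table; single-level items dropped."""
    cols = {}
    for var in items.columns:
        s = items[var].astype(str)
        levels = sorted(s.unique())
        if len(levels) < 2:
            warnings.warn(f"wealth item {var!r} has a single level; dropped")
            continue
        for lev in levels:
            cols[f"{var}={lev}"] = (s == lev).astype(float)
    if len(cols) < 4:
        raise ValueError("need >= 2 wealth variables with >= 2 levels each")
    return pd.DataFrame(cols, index=items.index)


def wealth_index(
    items: pd.DataFrame, weights=None, orient_by: str | None = None
) -> WealthIndex:
    """Wealth index: first principal axis of a correspondence analysis.

    The indicator table of the categorical wealth items is treated as a
    correspondence table; the standardised residual matrix
    D_r^{-1/2} (P - r c') D_c^{-1/2} is decomposed by SVD and the first-axis
    row principal coordinate is the summary wealth score, cut into weighted
    tertiles (lower-closed intervals, ties to the lower tertile).

    The axis sign is arbitrary; it is oriented so the ``orient_by`` column of
    the disjunctive table (e.g. ``"n_cars=3"``) has a positive coordinate,
    defaulting to the level with the largest absolute coordinate.
    """
    Z = _disjunctive(items)
    N = Z.to_numpy()
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # row principal coordinates on the first axis
    score = U[:, 0] * sv[0] / np.sqrt(r)
    col_coord = Vt[0] * sv[0] / np.sqrt(c)

    if orient_by is not None:
        if orient_by not in Z.columns:
            raise KeyError(f"{orient_by!r} is not a level of the disjunctive table")
        sign = np.sign(col_coord[Z.columns.get_loc(orient_by)]) or 1.0
    else:
        sign = np.sign(col_coord[np.argmax(np.abs(col_coord))]) or 1.0
    score = score * sign
    col_coord = col_coord * sign

    w = np.ones(len(score)) if weights is None else np.asarray(weights, float).ravel()
    q1, q2 = _weighted_quantile(score, w, [1 / 3, 2 / 3])
    tertile = 1 + (score > q1).astype(int) + (score > q2).astype(int)

    return WealthIndex(
        score=pd.Series(score, index=items.index, name="wealth_score"),
        tertile=pd.Series(tertile, index=items.index, name="wealth_tertile"),
        column_coords=pd.Series(col_coord, index=Z.columns, name="axis1"),
        inertia_share=float(sv[0] ** 2 / max((sv**2).sum(), 1e-300)),
    )


def _weighted_quantile(x, w, qs):
    order = np.argsort(x, kind="stable")
    cw = np.cumsum(w[order])
    cw = cw / cw[-1]
    return [x[order][np.searchsorted(cw, q)] for q in qs]


def pattern_logit(
    labels,
    covariates: pd.DataFrame,
    weights=None,
    stratify_by: str | None = "sex",
) -> pd.DataFrame:
    """Sex-stratified one-vs-rest logistic regressions of pattern membership.

    For each stratum and pattern, membership (vs all other patterns) is
    regressed on the covariates (categoricals dummy-coded against their
    first level); survey weights enter as frequency weights with a robust
    (sandwich) covariance.  Returns a long table (stratum, pattern,
    variable, level, OR, CI_low, CI_high, flagged) with an OR = 1 row for
    every reference level; separation is flagged, never returned as a
    silent infinite estimate.
    """
    lab = pd.Series(np.asarray(labels), index=covariates.index)
    w_all = (
        pd.Series(1.0, index=covariates.index)
        if weights is None
        else pd.Series(np.asarray(weights, float), index=covariates.index)
    )
    strata = (
        [(None, covariates.index)]
        if stratify_by is None
        else [(s, covariates.index[covariates[stratify_by] == s])
              for s in sorted(covariates[stratify_by].astype(str).unique())]
    )
    model_covs = covariates.drop(columns=[stratify_by], errors="ignore")

    rows = []
    for stratum, idx in strata:
        cov = model_covs.loc[idx]
        num = cov.select_dtypes("number")
        cat = cov.select_dtypes(exclude="number").astype(str)
        design_parts = [num]
        ref_levels: dict[str, str] = {}
        for var in cat.columns:
            levels = sorted(cat[var].unique())
            ref_levels[var] = levels[0]
            dums = pd.get_dummies(cat[var], prefix=var, prefix_sep="=", dtype=float)
            design_parts.append(dums[[f"{var}={l}" for l in levels[1:]]])
        Xd = pd.concat(design_parts, axis=1)
        Xd.insert(0, "const", 1.0)
        wv = w_all.loc[idx].to_numpy()

        for c in np.unique(lab):
            y = (lab.loc[idx] == c).astype(float).to_numpy()
            flagged = False
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    params, ci, converged = _weighted_logit(
                        y, Xd.to_numpy(dtype=float), wv
                    )
                if not converged or np.any(np.abs(params) > _SEPARATION_COEF):
                    flagged = True
                    warnings.warn(
                        f"possible separation in pattern {c} stratum {stratum}"
                    )
            except Exception:
                params = np.full(Xd.shape[1], np.nan)
                ci = np.full((Xd.shape[1], 2), np.nan)
                flagged = True

            for var in cat.columns:
                rows.append(
                    dict(
                        stratum=stratum, pattern=c, variable=var,
                        level=ref_levels[var], OR=1.0,
                        CI_low=np.nan, CI_high=np.nan,
                        reference=True, flagged=False,
                    )
                )
            for j, name in enumerate(Xd.columns):
                if name == "const":
                    continue
                var, _, level = name.partition("=")
                rows.append(
                    dict(
                        stratum=stratum, pattern=c, variable=var,
                        level=level if level else "(per unit)",
                        OR=float(np.exp(params[j])),
                        CI_low=float(np.exp(ci[j][0])),
                        CI_high=float(np.exp(ci[j][1])),
                        reference=False, flagged=flagged,
                    )
                )
    return pd.DataFrame(rows)
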
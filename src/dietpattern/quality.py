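"""Nutrient intakes, diet-quality indices and adjusted pattern comparisons.

Three indices summarise overall diet quality:

* MAR (mean adequacy ratio): mean over 20 key nutrients of the percentage of
  the recommended daily allowance covered, each ratio truncated at 100 so a
  surplus of one nutrient cannot compensate a deficit of another.
* ED (energy density): energy per gram of non-beverage foods, kcal/g.
* DDS (dietary diversity score): number (0-5) of macro food groups (dairy,
  meat/fish, cereals, fruits, vegetables) consumed at >= 30 g over 3 sampled
  diary days (2 weekdays + 1 weekend day).

Pattern means of any per-individual quantity are compared with the overall
mean through survey-weighted, covariate-adjusted linear models.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .synthetic import MAR_NUTRIENTS, age_band

KJ_PER_KCAL = 4.184
DDS_MIN_GRAMS = 30.0


def nutrient_intakes(X: pd.DataFrame, composition: pd.DataFrame) -> pd.DataFrame:
    """Per-individual mean daily nutrient intake from g/d consumption.

    intake_n = sum_j consumption_j * composition_{j,n} / 100 (per-100 g
    convention).  Raises if a consumed food group has no composition row.
    """
    missing = [g for g in X.columns if g not in composition.index]
    if missing:
        raise KeyError(f"composition table missing food groups: {missing}")
    comp = composition.reindex(X.columns).select_dtypes("number")
    return pd.DataFrame(
        X.to_numpy() @ comp.to_numpy() / 100.0, index=X.index, columns=comp.columns
    )


def mar(
    intakes: pd.DataFrame, rda: pd.DataFrame, covariates: pd.DataFrame
) -> pd.Series:
    """Mean adequacy ratio in [0, 100].

    MAR_i = 100/20 * sum_n min(intake_in / RDA_n(sex_i, band_i), 1); the RDA
    table is keyed by (sex, age_band).
    """
    missing = [n for n in MAR_NUTRIENTS if n not in intakes.columns]
    if missing:
        raise KeyError(f"intake table missing MAR nutrients: {missing}")
    cov = covariates.loc[intakes.index]
    bands = cov["age_band"] if "age_band" in cov else pd.Series(
        age_band(cov["age"]), index=cov.index
    )
    key = pd.MultiIndex.from_arrays([cov["sex"], bands])
    rda_rows = rda.loc[key, list(MAR_NUTRIENTS)]
    if (rda_rows.to_numpy() <= 0).any():
        raise ValueError("RDA values must be positive")
    ratios = intakes[list(MAR_NUTRIENTS)].to_numpy() / rda_rows.to_numpy()
    return pd.Series(
        np.minimum(ratios, 1.0).mean(axis=1) * 100.0, index=intakes.index, name="mar"
    )


def energy_density(
    X: pd.DataFrame, composition: pd.DataFrame, unit: str = "kcal"
) -> pd.Series:
    """Energy density of the non-beverage diet (kcal/g, or kJ/g).

    ED_i = sum_{j not beverage} X_ij e_j / 100 / sum_{j not beverage} X_ij.
    Beverage consumption (water, soft drinks, alcohol, milk, coffee, tea ...)
    never changes the value.  Individuals consuming no non-beverage food get
    NaN, not 0.
    """
    if "is_beverage" not in composition.columns:
        raise KeyError("composition table lacks the is_beverage flag column")
    comp = composition.reindex(X.columns)
    if comp["is_beverage"].isna().any():
        missing = list(comp.index[comp["is_beverage"].isna()])
        raise KeyError(f"beverage flag missing for groups: {missing}")
    solid = ~comp["is_beverage"].astype(bool).to_numpy()
    grams = X.to_numpy()[:, solid].sum(axis=1)
    energy = X.to_numpy()[:, solid] @ comp["energy_kcal"].to_numpy()[solid] / 100.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ed = np.where(grams > 0, energy / np.maximum(grams, 1e-300), np.nan)
    if unit == "kJ":
        ed = ed * KJ_PER_KCAL
    elif unit != "kcal":
        raise ValueError("unit must be 'kcal' or 'kJ'")
    return pd.Series(ed, index=X.index, name=f"ed_{unit}_per_g")


def dds(
    diary: pd.DataFrame,
    dds_mapping: dict[str, tuple[str, ...]],
    seed: int | None = None,
    min_grams: float = DDS_MIN_GRAMS,
) -> tuple[pd.Series, dict]:
    """Dietary diversity score (0-5) on 3 seeded random diary days.

    For each individual, 2 weekdays and 1 weekend day are drawn without
    replacement; a macro group counts when its total intake over the 3 days
    is at least ``min_grams``.  Individuals lacking the required day types
    are reported, not silently scored.
    """
    rng = np.random.default_rng(seed)
    group_to_macro = {
        g: macro for macro, members in dds_mapping.items() for g in members
    }
    d = diary.copy()
    d["macro"] = d["food_group"].map(group_to_macro)

    scores: dict[str, int] = {}
    failures: list[str] = []
    for ind, sub in d.groupby("individual_id", sort=True):
        days = sub[["day_index", "day_type"]].drop_duplicates()
        weekdays = sorted(days.loc[days["day_type"] == "weekday", "day_index"])
        weekends = sorted(days.loc[days["day_type"] == "weekend", "day_index"])
        if len(weekdays) < 2 or len(weekends) < 1:
            failures.append(ind)
            continue
        chosen = list(rng.choice(weekdays, 2, replace=False)) + list(
            rng.choice(weekends, 1, replace=False)
        )
        sel = sub[sub["day_index"].isin(chosen) & sub["macro"].notna()]
        totals = sel.groupby("macro")["amount_g"].sum()
        scores[ind] = int((totals >= min_grams).sum())
    report = {"n_scored": len(scores), "insufficient_day_types": failures}
    return pd.Series(scores, name="dds", dtype=int), report


# ---------------------------------------------------------------------------
# Covariate-adjusted pattern-vs-overall comparisons
# ---------------------------------------------------------------------------


def _design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Dummy-code categoricals (first level as reference), keep numerics."""
    num = covariates.select_dtypes("number")
    cat = covariates.select_dtypes(exclude="number")
    parts = [num]
    if not cat.empty:
        parts.append(pd.get_dummies(cat, drop_first=True, dtype=float))
    return pd.concat(parts, axis=1)


def _check_full_rank(M: pd.DataFrame) -> None:
    A = M.to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        # name offending columns via QR diagonal
        _, R = np.linalg.qr(A)
        bad = [M.columns[j] for j in range(A.shape[1]) if abs(R[j, j]) < 1e-8]
        raise ValueError(f"collinear design columns: {bad}")


def compare_group_means(
    values: pd.Series,
    labels,
    covariates: pd.DataFrame | None = None,
    weights=None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Survey-weighted adjusted pattern means vs the overall mean.

    For each pattern c a weighted linear model of the value on a membership
    indicator plus covariates is fitted; the indicator coefficient is the
    adjusted pattern-vs-rest difference, converted to a pattern-vs-overall
    difference by the factor (1 - weighted share of c).  Flags are ``lower``
    / ``ns`` / ``higher`` at the two-sided ``alpha``; ``adjust`` may be
    ``"bonferroni"`` or ``"bh"`` (off by default).
    """
    y = pd.Series(values).astype(float)
    mask = y.notna()
    y = y[mask]
    lab = pd.Series(np.asarray(labels), index=pd.Series(values).index)[mask]
    n = len(y)
    if weights is None:
        w = np.ones(n)
    elif isinstance(weights, pd.Series):
        w = weights.loc[y.index].to_numpy(dtype=float)
    else:
        w = np.asarray(weights, float).ravel()[np.asarray(mask)]
    if covariates is not None:
        Xc = _design(covariates.loc[y.index])
    else:
        Xc = pd.DataFrame(index=y.index)

    overall = float(np.average(y, weights=w))
    tot_w = w.sum()
    rows = []
    for c in np.unique(lab):
        ind = (lab == c).astype(float)
        share = w[lab == c].sum() / tot_w
        M = pd.concat([pd.Series(ind, index=y.index, name="_pattern"), Xc], axis=1)
        M.insert(0, "const", 1.0)
        _check_full_rank(M)
        # sandwich covariance: survey weights are sampling weights, not
        # precision weights, so model-based WLS errors would be too small
        fit = sm.WLS(y.to_numpy(), M.to_numpy(dtype=float), weights=w).fit(
            cov_type="HC1"
        )
        coef = fit.params[1]
        pval = fit.pvalues[1]
        diff = coef * (1.0 - share)      # pattern mean minus overall mean
        rows.append(
            {
                "pattern": c,
                "adjusted_mean": overall + diff,
                "diff_vs_overall": diff,
                "p_value": pval,
                "share_pct": share * 100.0,
            }
        )
    out = pd.DataFrame(rows).set_index("pattern")
    pvals = out["p_value"].to_numpy()
    if adjust == "bonferroni":
        pvals = np.minimum(pvals * len(pvals), 1.0)
    elif adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        pvals = multipletests(pvals, method="fdr_bh")[1]
    elif adjust is not None:
        raise ValueError("adjust must be None, 'bonferroni' or 'bh'")
    out["p_adjusted"] = pvals
    sig = pvals < alpha  # NaN p-values (degenerate fits) count as ns
    out["flag"] = np.where(
        sig, np.where(out["diff_vs_overall"] > 0, "higher", "lower"), "ns"
    )
    return out
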
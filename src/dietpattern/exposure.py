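"""Dietary contaminant exposure from consumption and contamination data.

Per-individual daily exposure to each substance is the body-weight-normalised
sum over food groups of consumption times concentration:

    E_is = sum_j consumption_ij (g/d) * conc_sj (ug/g) / body_weight_i (kg)

in ug/kg bw/d.  Left-censored laboratory values are handled by substitution:
lower bound (LB, censored = 0), middle bound (MB, censored = LOD/2, the
default) or upper bound (UB, censored = LOD); the contamination table carries
one concentration column per bound.  Congeners sharing a ``tef_group`` are
aggregated into toxicity-equivalent exposure as a sum weighted by their
user-supplied TEF values.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CENSORING_MODES = ("LB", "MB", "UB")


def _conc_matrix(
    contamination: pd.DataFrame, food_groups, mode: str, assume_zero: bool
) -> pd.DataFrame:
    if mode not in CENSORING_MODES:
        raise ValueError(f"mode must be one of {CENSORING_MODES}")
    col = f"conc_{mode}"
    wide = contamination.pivot_table(
        index="substance", columns="food_group", values=col, aggfunc="first"
    )
    wide = wide.reindex(columns=food_groups)
    if wide.isna().any().any():
        if not assume_zero:
            missing = [
                (s, g)
                for s in wide.index
                for g in wide.columns
                if pd.isna(wide.loc[s, g])
            ]
            raise KeyError(
                "missing concentration for consumed food groups "
                f"(set assume_zero=True to treat as 0): {missing[:10]}"
            )
        wide = wide.fillna(0.0)
    return wide


def exposure_levels(
    X: pd.DataFrame,
    contamination: pd.DataFrame,
    body_weight_kg,
    mode: str = "MB",
    assume_zero: bool = False,
) -> pd.DataFrame:
    """Individual x substance exposure table (ug/kg bw/d).

    ``contamination`` is long format with columns substance, food_group,
    unit (ug_per_g or ug_per_kg), conc_LB/conc_MB/conc_UB and optional
    tef_group / tef columns for toxicity-equivalent aggregation.
    """
    bw = np.asarray(
        getattr(body_weight_kg, "values", body_weight_kg), dtype=float
    ).ravel()
    if bw.shape != (len(X),) or np.any(bw <= 0):
        raise ValueError("body weights must be positive, one per individual")
    contamination = contamination.copy()
    units = contamination["unit"].unique() if "unit" in contamination else ["ug_per_g"]
    for u in units:
        if u not in ("ug_per_g", "ug_per_kg"):
            raise ValueError(f"unsupported concentration unit: {u}")
    if "unit" in contamination:
        factor = np.where(contamination["unit"] == "ug_per_kg", 1e-3, 1.0)
        for col in ("conc_LB", "conc_MB", "conc_UB"):
            contamination[col] = contamination[col] * factor

    # restrict the missing-value check to groups actually consumed
    consumed = X.columns[(X > 0).any(axis=0)]
    conc = _conc_matrix(contamination, consumed, mode, assume_zero)
    conc_full = conc.reindex(columns=X.columns).fillna(0.0)

    E = X.to_numpy() @ conc_full.to_numpy().T / bw[:, None]
    out = pd.DataFrame(E, index=X.index, columns=conc_full.index)

    # toxicity-equivalent aggregation of congeners sharing a tef_group
    if "tef_group" in contamination.columns:
        tef_rows = contamination.dropna(subset=["tef_group"])
        if not tef_rows.empty:
            if "tef" not in tef_rows.columns or tef_rows["tef"].isna().any():
                raise ValueError("tef weights required for tef_group rows")
            tef_by_sub = tef_rows.groupby("substance").agg(
                tef=("tef", "first"), tef_group=("tef_group", "first")
            )
            for grp, members in tef_by_sub.groupby("tef_group"):
                subs = [s for s in members.index if s in out.columns]
                if subs:
                    out[str(grp)] = sum(
                        out[s] * members.loc[s, "tef"] for s in subs
                    )
                    out = out.drop(columns=subs)
    return out


def compare_exposures(
    exposures: pd.DataFrame,
    labels,
    covariates: pd.DataFrame | None = None,
    weights=None,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> pd.DataFrame:
    """Adjusted pattern-vs-overall comparison for every substance.

    Thin wrapper over :func:`dietpattern.quality.compare_group_means`;
    returns a long DataFrame (substance, pattern, adjusted_mean, p_value,
    flag).
    """
    from .quality import compare_group_means

    frames = []
    for sub in exposures.columns:
        res = compare_group_means(
            exposures[sub], labels, covariates, weights, alpha=alpha, adjust=adjust
        ).reset_index()
        res.insert(0, "substance", sub)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
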
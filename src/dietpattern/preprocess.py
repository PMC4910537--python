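"""From food diaries to the analysis-ready consumption matrix.

Aggregates diary records to food groups as mean daily intake (g/d), filters
rarely consumed groups, applies the extremely-low-energy exclusion and flags
(but never removes) likely energy under-reporters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RARE_GROUP_THRESHOLD = 0.10   # strict <10 % consumption rate excludes a group
LOW_TEI_FACTOR = 0.45         # default: exclude TEI < 0.45 x Schofield BMR
GOLDBERG_CUTOFF = 1.05        # TEI/BMR below this flags an under-reporter

_KCAL_PER_MJ = 239.005736


@dataclass
class ExclusionRule:
    """Low-energy exclusion: TEI below ``factor`` x Schofield BMR (kcal/d).

    The cut-off is deliberately configurable; any published low-energy
    criterion can be expressed by swapping the factor or supplying absolute
    thresholds via ``min_tei_kcal``.
    """

    factor: float = LOW_TEI_FACTOR
    min_tei_kcal: float | None = None

    def threshold(self, bmr_kcal: np.ndarray) -> np.ndarray:
        if self.min_tei_kcal is not None:
            return np.full_like(np.asarray(bmr_kcal, float), self.min_tei_kcal)
        return self.factor * np.asarray(bmr_kcal, float)


def schofield_bmr(sex, age, weight_kg) -> np.ndarray:
    """Basal metabolic rate (kcal/d) from the Schofield weight equations."""
    sex = np.asarray(sex)
    age = np.asarray(age, dtype=float)
    wt = np.asarray(weight_kg, dtype=float)
    male = np.char.upper(sex.astype(str)) == "M"
    mj = np.where(
        male,
        np.where(age < 30, 0.063 * wt + 2.896,
                 np.where(age < 60, 0.048 * wt + 3.653, 0.049 * wt + 2.459)),
        np.where(age < 30, 0.062 * wt + 2.036,
                 np.where(age < 60, 0.034 * wt + 3.538, 0.038 * wt + 2.755)),
    )
    return mj * _KCAL_PER_MJ


def aggregate_to_groups(
    records: pd.DataFrame,
    mapping: dict[str, str] | pd.Series | None = None,
    n_days: int = 7,
    roster: list[str] | None = None,
) -> pd.DataFrame:
    """Mean daily intake (g/d) per individual x food group.

    ``records`` needs columns individual_id, amount_g and either food_group
    directly or food_item plus a food_item -> group ``mapping``.  Each cell is
    the diary total divided by ``n_days``.  Individuals in ``roster`` with no
    records get zero rows; an unmapped food item raises a KeyError naming it.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rec = records.copy()
    if "food_group" not in rec.columns or mapping is not None:
        if mapping is None:
            raise ValueError("records lack food_group and no mapping given")
        mp = mapping if isinstance(mapping, pd.Series) else pd.Series(mapping)
        items = rec["food_item"]
        unmapped = sorted(set(items) - set(mp.index))
        if unmapped:
            raise KeyError(f"food items missing from mapping: {unmapped}")
        rec["food_group"] = items.map(mp).values
    if (rec["amount_g"] < 0).any():
        raise ValueError("negative diary amounts")
    mat = (
        rec.pivot_table(
            index="individual_id",
            columns="food_group",
            values="amount_g",
            aggfunc="sum",
            fill_value=0.0,
        )
        / n_days
    )
    if roster is not None:
        mat = mat.reindex(roster, fill_value=0.0)
    mat.columns.name = "food_group"
    return mat


def consumption_rates(X: pd.DataFrame) -> pd.Series:
    """Fraction of individuals with positive intake, per food group."""
    return (X > 0).mean(axis=0)


def filter_rare_groups(
    X: pd.DataFrame, threshold: float = RARE_GROUP_THRESHOLD
) -> tuple[pd.DataFrame, list[str]]:
    """Drop food groups whose consumption rate is strictly below ``threshold``.

    Column order of the retained groups is preserved; returns the filtered
    matrix and the excluded group names.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    rates = consumption_rates(X)
    keep = rates >= threshold
    if not keep.any():
        raise ValueError("rare-group filter excluded every food group")
    excluded = [c for c in X.columns if not keep[c]]
    return X.loc[:, keep], excluded


def total_energy_intake(X: pd.DataFrame, composition: pd.DataFrame) -> pd.Series:
    """TEI (kcal/d) from the consumption matrix and energy per 100 g."""
    energy = composition["energy_kcal"].reindex(X.columns)
    if energy.isna().any():
        missing = list(energy[energy.isna()].index)
        raise KeyError(f"composition missing energy for groups: {missing}")
    return (X @ energy) / 100.0


def exclude_low_energy(
    tei: pd.Series, covariates: pd.DataFrame, rule: ExclusionRule | None = None
):
    """Apply the extremely-low-energy exclusion.

    Returns (kept ids, excluded ids, report dict).  Consumption values are
    never modified; callers subset the matrix on the kept ids.
    """
    if tei.isna().any():
        raise ValueError("missing TEI values")
    if (tei < 0).any():
        raise ValueError("negative TEI values")
    rule = rule or ExclusionRule()
    cov = covariates.loc[tei.index]
    bmr = schofield_bmr(cov["sex"], cov["age"], cov["body_weight_kg"])
    thr = rule.threshold(bmr)
    excluded_mask = tei.to_numpy() < thr
    excluded = list(tei.index[excluded_mask])
    kept = list(tei.index[~excluded_mask])
    report = {
        "n_total": int(len(tei)),
        "n_excluded": int(len(excluded)),
        "fraction_excluded": float(len(excluded) / len(tei)),
        "rule": "min_tei_kcal" if rule.min_tei_kcal is not None else f"TEI < {rule.factor} x BMR",
    }
    return kept, excluded, report


def flag_under_reporters(
    tei: pd.Series, covariates: pd.DataFrame, cutoff: float = GOLDBERG_CUTOFF
) -> pd.Series:
    """Goldberg-type under-reporting flags (TEI/BMR below ``cutoff``).

    Flags only annotate; under-reporters stay in the analysis.
    """
    cov = covariates.loc[tei.index]
    bmr = schofield_bmr(cov["sex"], cov["age"], cov["body_weight_kg"])
    return pd.Series(tei.to_numpy() / bmr < cutoff, index=tei.index, name="under_reporter")


def derive_day_type(dates: pd.Series) -> pd.Series:
    """weekday (Mon-Fri) / weekend (Sat-Sun) from calendar dates."""
    dow = pd.to_datetime(dates).dt.dayofweek
    return pd.Series(np.where(dow >= 5, "weekend", "weekday"), index=dates.index)
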
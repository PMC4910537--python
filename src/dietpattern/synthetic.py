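"""Synthetic food-consumption survey generator.

Emulates a national dietary survey of the kind used for dietary-pattern
analysis: a sparse, non-negative individual x food-group mean daily intake
matrix generated from a small number of latent non-negative "consumption
systems" (CS), survey weights with mean 1, socio-demographic covariates with
planted pattern associations, and the side tables (food composition, RDA,
contamination) needed downstream.  Ground truth is retained so that every
stage of the pipeline can be tested for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

# ---------------------------------------------------------------------------
# Constants: nutrients, food groups, age bands
# ---------------------------------------------------------------------------

#: The twenty nutrients entering the mean adequacy ratio (MAR).
MAR_NUTRIENTS: tuple[str, ...] = (
    "protein_g",
    "fibre_g",
    "vitamin_a_ug",
    "vitamin_c_mg",
    "vitamin_e_mg",
    "vitamin_d_ug",
    "vitamin_b1_mg",
    "vitamin_b2_mg",
    "vitamin_b3_mg",
    "vitamin_b6_mg",
    "vitamin_b9_ug",
    "vitamin_b12_ug",
    "calcium_mg",
    "potassium_mg",
    "iron_mg",
    "magnesium_mg",
    "zinc_mg",
    "copper_mg",
    "iodine_ug",
    "selenium_ug",
)

#: Typical adult daily recommended intake, used as the centre of synthetic RDA
#: tables (order matches MAR_NUTRIENTS).
_RDA_BASE = (
    60.0,    # protein g
    30.0,    # fibre g
    750.0,   # vitamin A ug
    110.0,   # vitamin C mg
    12.0,    # vitamin E mg
    15.0,    # vitamin D ug
    1.2,     # B1 mg
    1.6,     # B2 mg
    14.0,    # B3 mg
    1.7,     # B6 mg
    330.0,   # B9 ug
    4.0,     # B12 ug
    950.0,   # calcium mg
    3500.0,  # potassium mg
    11.0,    # iron mg
    380.0,   # magnesium mg
    11.0,    # zinc mg
    1.5,     # copper mg
    150.0,   # iodine ug
    70.0,    # selenium ug
)

#: Reporting age bands used for RDA lookup.
AGE_BANDS: tuple[str, ...] = ("18-24", "25-34", "35-49", "50-64", "65+")
_AGE_EDGES = (18, 25, 35, 50, 65, 80)

#: Beverage groups come first; they are excluded from energy density.
_BEVERAGE_GROUPS = (
    "water",
    "coffee",
    "tea",
    "soft_drinks",
    "alcoholic_drinks",
    "milk",
)
_NAMED_FOOD_GROUPS = (
    "fresh_fruit",
    "processed_fruit",
    "dried_fruit",
    "fresh_vegetables",
    "prepared_vegetables",
    "red_meat",
    "poultry",
    "fish_crustaceans",
    "yogurt",
    "cheese",
    "rice_pasta_wheat",
    "bread",
    "eggs",
    "potatoes",
    "pulses",
    "pastries",
    "chocolate",
    "butter",
    "vegetable_oil",
    "sauces",
)

#: Macro-group mapping for the 0-5 dietary diversity score.
DDS_MAPPING: dict[str, tuple[str, ...]] = {
    "dairy": ("milk", "yogurt", "cheese"),
    "meat_fish": ("red_meat", "poultry", "fish_crustaceans"),
    "cereals": ("rice_pasta_wheat",),
    "fruits": ("fresh_fruit", "processed_fruit", "dried_fruit"),
    "vegetables": ("fresh_vegetables", "prepared_vegetables"),
}

_SUBSTANCES = (
    "lead",
    "cadmium",
    "inorganic_arsenic",
    "organic_mercury",
    "acrylamide",
)

#: Mean population total intake (g/d) the generator is scaled to.
_TARGET_TOTAL_INTAKE = 2800.0


def age_band(age: float | np.ndarray) -> np.ndarray:
    """Map age in years to the RDA reporting band."""
    idx = np.clip(np.digitize(np.asarray(age), _AGE_EDGES[1:-1]), 0, len(AGE_BANDS) - 1)
    return np.asarray(AGE_BANDS)[idx]


def food_group_names(p: int) -> list[str]:
    """Names of the first ``p`` synthetic food groups (beverages first)."""
    named = list(_BEVERAGE_GROUPS) + list(_NAMED_FOOD_GROUPS)
    if p <= len(named):
        return named[:p]
    return named + [f"group_{i:02d}" for i in range(len(named) + 1, p + 1)]


# ---------------------------------------------------------------------------
# Configuration and ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of a synthetic survey population.

    Defaults reproduce the study conditions of the analysis the pipeline was
    built for: 2600 adults, 66 food groups, 7 latent consumption systems and
    7 dietary patterns, survey weights with mean 1 and sd 0.7.
    """

    n_individuals: int = 2600
    n_food_groups: int = 66
    n_cs: int = 7
    zero_inflation: float = 0.15
    noise_cv: float = 0.15
    n_patterns: int = 7
    pattern_separation: float = 3.0
    weight_sd: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_food_groups", "n_cs", "n_patterns"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_cs > self.n_food_groups:
            raise ValueError("n_cs cannot exceed n_food_groups")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise ValueError("zero_inflation must lie in [0, 1)")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.pattern_separation < 0:
            raise ValueError("pattern_separation must be >= 0")
        if self.weight_sd < 0:
            raise ValueError("weight_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated population."""

    true_loadings: np.ndarray            # n_cs x n_food_groups, rows sum to 1
    true_scores: np.ndarray              # n_individuals x n_cs, >= 0
    true_pattern: np.ndarray             # labels in 1..n_patterns
    true_covariate_effects: dict[str, np.ndarray] = field(default_factory=dict)
    food_groups: list[str] = field(default_factory=list)
    individual_ids: list[str] = field(default_factory=list)


@dataclass
class CompositionTables:
    """Nutrient composition, RDA and contamination tables."""

    composition: pd.DataFrame            # food_group x (energy + nutrients + is_beverage)
    rda: pd.DataFrame                    # (sex, age_band) x nutrient
    contamination: pd.DataFrame          # long: substance, food_group, unit, conc_LB/MB/UB
    dds_mapping: dict[str, tuple[str, ...]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Truth generation
# ---------------------------------------------------------------------------


def generate_truth(config: SimulationConfig) -> SyntheticTruth:
    """Draw latent consumption systems, individual scores and pattern labels.

    Each CS loads on a random block of 5-15 food groups (Dirichlet weights,
    blocks as disjoint as the dimensions permit).  Pattern centroids lie in
    CS-score space along near-orthogonal directions; the pairwise centroid
    distance equals ``pattern_separation`` times the total within-pattern
    spread (per-dimension sd 1, hence sqrt(n_cs) overall).
    """
    rng = np.random.default_rng(config.seed)
    k, p, n, n_pat = (
        config.n_cs,
        config.n_food_groups,
        config.n_individuals,
        config.n_patterns,
    )

    # --- sparse loadings, rows sum to 1 ----------------------------------
    order = rng.permutation(p)
    sizes = rng.integers(5, 16, size=k)
    sizes = np.minimum(sizes, p)
    H = np.zeros((k, p))
    pos = 0
    for r in range(k):
        take = [order[(pos + j) % p] for j in range(sizes[r])]
        pos += sizes[r]
        H[r, take] = rng.dirichlet(np.full(sizes[r], 1.5))
    # every food group must load on at least one CS
    orphan = np.flatnonzero(H.sum(axis=0) == 0)
    for j in orphan:
        r = rng.integers(0, k)
        H[r, j] = 0.02
    H /= H.sum(axis=1, keepdims=True)

    # --- pattern centroids -----------------------------------------------
    # Each pattern is dominated by one CS (cycling when n_patterns > n_cs):
    # a low baseline on every CS plus a boost on the dominant one.  Clipping
    # the within-pattern Gaussian spread at zero leaves genuine zero scores,
    # mirroring diets that simply do not use some consumption systems.
    sigma_w = 1.0                              # within-pattern per-dimension sd
    b_low = 0.8 * sigma_w
    # pairwise centroid distance = pattern_separation * sigma_w * sqrt(k)
    delta = config.pattern_separation * sigma_w * np.sqrt(k) / np.sqrt(2.0)
    dominant = np.arange(n_pat) % k
    centroids = np.full((n_pat, k), b_low)
    centroids[np.arange(n_pat), dominant] += delta
    for c in range(k, n_pat):                  # differentiate cycled repeats
        centroids[c, (dominant[c] + 1 + c // max(k, 1)) % k] += 0.6 * delta

    labels = rng.integers(1, n_pat + 1, size=n)
    scores = centroids[labels - 1] + rng.normal(scale=sigma_w, size=(n, k))
    scores = np.maximum(scores, 0.0)
    # scale so the population mean total intake is realistic
    scores *= _TARGET_TOTAL_INTAKE / scores.sum(axis=1).mean()

    effects: dict[str, np.ndarray] = {}
    for i, (cov, beta) in enumerate(
        [("age_65plus", np.log(2.0)), ("education_high", np.log(1.8)), ("sex_female", np.log(1.5))]
    ):
        if i < n_pat:
            vec = np.zeros(n_pat)
            vec[i] = beta
            effects[cov] = vec

    ids = [f"ind_{i:05d}" for i in range(1, n + 1)]
    return SyntheticTruth(
        true_loadings=H,
        true_scores=scores,
        true_pattern=labels,
        true_covariate_effects=effects,
        food_groups=food_group_names(p),
        individual_ids=ids,
    )


# ---------------------------------------------------------------------------
# Consumption matrix and diary
# ---------------------------------------------------------------------------


def generate_consumption(truth: SyntheticTruth, config: SimulationConfig) -> pd.DataFrame:
    """Mean daily intake matrix (g/d): low-rank signal x noise x dropout.

    X = (scores @ loadings) * lognormal(mean 1, cv=noise_cv) * Bernoulli mask.
    """
    n, k = truth.true_scores.shape
    if n != config.n_individuals or k != config.n_cs:
        raise ValueError("truth dimensions inconsistent with config")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    X = truth.true_scores @ truth.true_loadings
    if config.noise_cv > 0:
        sigma2 = np.log1p(config.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=X.shape)
        X = X * noise
    if config.zero_inflation > 0:
        mask = rng.random(X.shape) >= config.zero_inflation
        X = X * mask
    X = np.maximum(X, 0.0)
    return pd.DataFrame(X, index=truth.individual_ids, columns=truth.food_groups)


def generate_diary(
    truth: SyntheticTruth, config: SimulationConfig, n_days: int = 7
) -> pd.DataFrame:
    """Per-day food-group totals consistent with the mean daily intake.

    Daily amounts are the individual's mean intake modulated by a per-day
    multiplier that averages exactly 1 over the week, so aggregating the diary
    reproduces the consumption matrix.  Days 1-5 are weekdays, 6-7 weekend.
    Only positive amounts are recorded (long format).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    X = generate_consumption(truth, config).to_numpy()
    n, p = X.shape
    mult = rng.lognormal(mean=0.0, sigma=0.35, size=(n, n_days))
    mult = mult / mult.mean(axis=1, keepdims=True)   # weekly mass conserved
    rows: list[tuple] = []
    groups = truth.food_groups
    for d in range(n_days):
        day_type = "weekday" if d < 5 else "weekend"
        day_amounts = X * mult[:, d][:, None]
        ii, jj = np.nonzero(day_amounts)
        for i, j in zip(ii, jj):
            rows.append(
                (truth.individual_ids[i], d + 1, day_type, groups[j], day_amounts[i, j])
            )
    return pd.DataFrame(
        rows, columns=["individual_id", "day_index", "day_type", "food_group", "amount_g"]
    )


# ---------------------------------------------------------------------------
# Composition / RDA / contamination tables
# ---------------------------------------------------------------------------


def generate_tables(config: SimulationConfig) -> CompositionTables:
    """Synthetic composition, RDA and contamination tables.

    Nutrient densities are lognormal around plausible per-100 g magnitudes;
    beverages are low-energy.  RDA varies by sex and age band around standard
    adult values.  Contamination concentrations satisfy LB <= MB <= UB per
    cell (substitution bounds for left-censored laboratory values), with the
    organic-mercury burden concentrated in fish.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    groups = food_group_names(config.n_food_groups)
    is_bev = np.array([g in _BEVERAGE_GROUPS for g in groups])

    # composition per 100 g: scaled so a ~2800 g/d diet lands near adequacy
    comp = pd.DataFrame(index=pd.Index(groups, name="food_group"))
    comp["energy_kcal"] = np.where(
        is_bev, rng.uniform(0.0, 50.0, len(groups)), rng.uniform(60.0, 400.0, len(groups))
    )
    for nut, base in zip(MAR_NUTRIENTS, _RDA_BASE):
        dens = rng.lognormal(mean=0.0, sigma=0.6, size=len(groups))
        comp[nut] = dens * base / _TARGET_TOTAL_INTAKE * 100.0 * 1.2
    comp["is_beverage"] = is_bev

    rows = []
    for sex in ("M", "F"):
        for ib, band in enumerate(AGE_BANDS):
            mult = (1.0 if sex == "M" else 0.85) * (1.0 + 0.03 * ib)
            rows.append([sex, band] + [b * mult for b in _RDA_BASE])
    rda = pd.DataFrame(rows, columns=["sex", "age_band"] + list(MAR_NUTRIENTS))
    rda = rda.set_index(["sex", "age_band"])

    recs = []
    for sub in _SUBSTANCES:
        mb = rng.lognormal(mean=np.log(0.02), sigma=1.0, size=len(groups))
        if sub == "organic_mercury":
            mb *= np.where(np.array(groups) == "fish_crustaceans", 50.0, 0.2)
        lb = mb * rng.uniform(0.0, 1.0, len(groups))
        ub = mb * rng.uniform(1.0, 2.0, len(groups))
        for g, l, m, u in zip(groups, lb, mb, ub):
            recs.append((sub, g, "ug_per_g", l, m, u, None, np.nan))
    contamination = pd.DataFrame(
        recs,
        columns=["substance", "food_group", "unit", "conc_LB", "conc_MB", "conc_UB", "tef_group", "tef"],
    )

    mapping = {
        macro: tuple(g for g in members if g in groups)
        for macro, members in DDS_MAPPING.items()
    }
    return CompositionTables(
        composition=comp, rda=rda, contamination=contamination, dds_mapping=mapping
    )


# ---------------------------------------------------------------------------
# Covariates and survey weights
# ---------------------------------------------------------------------------


def generate_covariates_and_weights(
    truth: SyntheticTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Individual table: survey weight, demographics, wealth items.

    Survey weights are lognormal rescaled to mean exactly 1 with sd close to
    ``weight_sd``.  The covariates listed in ``truth.true_covariate_effects``
    are drawn from pattern-dependent Bernoulli models with the planted
    log-odds; the rest are independent of the pattern.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    n = config.n_individuals
    pat = truth.true_pattern - 1

    if config.weight_sd == 0:
        w = np.ones(n)
    else:
        sigma2 = np.log1p(config.weight_sd**2)
        w = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=n)
        w = w / w.mean()

    def planted_binary(name: str, p0: float) -> np.ndarray:
        beta = truth.true_covariate_effects.get(name)
        logit0 = np.log(p0 / (1 - p0))
        eta = logit0 + (beta[pat] if beta is not None else 0.0)
        return (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)

    senior = planted_binary("age_65plus", 0.15)
    age = np.where(
        senior, rng.uniform(65, 79, n), rng.uniform(18, 65, n)
    ).round(1)
    female = planted_binary("sex_female", 0.5)
    sex = np.where(female, "F", "M")
    edu_high = planted_binary("education_high", 0.30)
    edu = np.where(edu_high, "tertiary", rng.choice(["primary", "secondary"], n))
    body_weight = np.where(
        sex == "M", rng.normal(77, 12, n), rng.normal(63, 11, n)
    ).clip(40, 160).round(1)

    # household wealth items (latent wealth score drives them jointly)
    wealth = rng.normal(size=n)
    holiday = (wealth + rng.normal(scale=0.8, size=n) > 0).astype(int)
    n_cars = np.clip(np.round(1.0 + 0.7 * wealth + rng.normal(scale=0.6, size=n)), 0, 3).astype(int)
    finance = pd.cut(
        wealth + rng.normal(scale=0.9, size=n),
        bins=[-np.inf, -0.5, 0.5, np.inf],
        labels=["difficult", "adequate", "comfortable"],
    ).astype(str)
    owner = (wealth + rng.normal(scale=1.0, size=n) > -0.2).astype(int)
    food_insecurity = (wealth + rng.normal(scale=1.0, size=n) < -1.5).astype(int)

    df = pd.DataFrame(
        {
            "weight": w,
            "sex": sex,
            "age": age,
            "age_band": age_band(age),
            "body_weight_kg": body_weight,
            "education": edu,
            "occupation": rng.choice(["manual", "employee", "executive"], n),
            "household_size": rng.integers(1, 6, n),
            "household_type": rng.choice(["single", "couple", "family"], n),
            "region": rng.choice(["north", "south", "east", "west"], n),
            "season": rng.choice(["winter", "spring", "summer", "autumn"], n),
            "municipality_size": rng.choice(["rural", "town", "city"], n),
            "holiday_away": holiday,
            "n_cars": n_cars,
            "perceived_finance": finance,
            "home_owner": owner,
            "food_insecurity": food_insecurity,
        },
        index=pd.Index(truth.individual_ids, name="individual_id"),
    )
    return df


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------


def write_bundle(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full synthetic survey bundle and write it as CSV/JSON/YAML.

    Files: consumption.csv, diary.csv, individuals.csv, composition.csv,
    rda.csv, contamination.csv, dds_mapping.json, truth.json, config.yaml.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_truth(config)
    X = generate_consumption(truth, config)
    diary = generate_diary(truth, config)
    tables = generate_tables(config)
    indiv = generate_covariates_and_weights(truth, config)

    paths = {
        "consumption": outdir / "consumption.csv",
        "diary": outdir / "diary.csv",
        "individuals": outdir / "individuals.csv",
        "composition": outdir / "composition.csv",
        "rda": outdir / "rda.csv",
        "contamination": outdir / "contamination.csv",
        "dds_mapping": outdir / "dds_mapping.json",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    X.rename_axis("individual_id").to_csv(paths["consumption"])
    diary.to_csv(paths["diary"], index=False)
    indiv.to_csv(paths["individuals"])
    tables.composition.to_csv(paths["composition"])
    tables.rda.to_csv(paths["rda"])
    tables.contamination.to_csv(paths["contamination"], index=False)
    paths["dds_mapping"].write_text(
        json.dumps({k: list(v) for k, v in tables.dds_mapping.items()}, indent=1)
    )
    truth_json = {
        "true_loadings": truth.true_loadings.tolist(),
        "true_scores": truth.true_scores.tolist(),
        "true_pattern": truth.true_pattern.tolist(),
        "true_covariate_effects": {
            k: v.tolist() for k, v in truth.true_covariate_effects.items()
        },
        "food_groups": truth.food_groups,
        "individual_ids": truth.individual_ids,
    }
    paths["truth"].write_text(json.dumps(truth_json))
    paths["config"].write_text(yaml.safe_dump(asdict(config)))
    return paths


def read_truth(path: str | Path) -> SyntheticTruth:
    """Load a ground-truth JSON written by :func:`write_bundle`."""
    d = json.loads(Path(path).read_text())
    return SyntheticTruth(
        true_loadings=np.asarray(d["true_loadings"]),
        true_scores=np.asarray(d["true_scores"]),
        true_pattern=np.asarray(d["true_pattern"]),
        true_covariate_effects={
            k: np.asarray(v) for k, v in d["true_covariate_effects"].items()
        },
        food_groups=list(d["food_groups"]),
        individual_ids=list(d["individual_ids"]),
    )
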
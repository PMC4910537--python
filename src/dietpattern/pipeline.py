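"""End-to-end orchestration: bundle in, pattern report out.

Runs the full analysis in method order — preprocessing, weighted NMF,
pattern clustering, diet-quality and exposure characterisation, and
socio-economic determinants — from a single YAML-configurable entry point,
writing every intermediate artefact plus a machine-readable JSON summary and
a human-readable Markdown report.  All randomness derives from one root seed
fanned out per stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterize, clustering, exposure, nmf, preprocess, quality
from .synthetic import SimulationConfig, write_bundle

log = logging.getLogger("dietpattern")

WEALTH_ITEMS = [
    "holiday_away",
    "n_cars",
    "perceived_finance",
    "home_owner",
    "food_insecurity",
]
ADJUST_COVARIATES = ["age", "sex", "season", "education"]
LOGIT_COVARIATES = ["age_band", "education", "household_type", "municipality_size"]


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds driving one pipeline run."""

    input_dir: str
    output_dir: str
    k: int | None = 7
    k_range: list[int] | None = None
    c_range: list[int] = field(default_factory=lambda: [2, 12])
    n_clusters: int | None = None
    rare_group_threshold: float = preprocess.RARE_GROUP_THRESHOLD
    contributor_cutoff: float = 0.025
    dds_min_grams: float = quality.DDS_MIN_GRAMS
    v_test_threshold: float = clustering.V_TEST_THRESHOLD
    censoring_mode: str = "MB"
    n_restarts: int = 10
    tol: float = 1e-6
    max_iter: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.rare_group_threshold < 1:
            raise ValueError("rare_group_threshold must lie in (0,1)")
        if not 0 <= self.contributor_cutoff < 1:
            raise ValueError("contributor_cutoff must lie in [0,1)")
        if self.censoring_mode not in exposure.CENSORING_MODES:
            raise ValueError("censoring_mode must be LB, MB or UB")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _stage_seed(root: int, stage: int) -> int:
    return int(
        np.random.SeedSequence([int(root), stage]).generate_state(1)[0] % (2**31)
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the summary."""
    t0 = time.time()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "load"
    last_good: Path | None = None
    try:
        X = pd.read_csv(indir / "consumption.csv", index_col=0)
        indiv = pd.read_csv(indir / "individuals.csv", index_col=0)
        comp = pd.read_csv(indir / "composition.csv", index_col=0)
        rda = pd.read_csv(indir / "rda.csv", index_col=[0, 1])
        contam = pd.read_csv(indir / "contamination.csv")
        diary_path = indir / "diary.csv"
        diary = pd.read_csv(diary_path) if diary_path.exists() else None
        dds_path = indir / "dds_mapping.json"
        dds_mapping = (
            {k: tuple(v) for k, v in json.loads(dds_path.read_text()).items()}
            if dds_path.exists()
            else {}
        )

        # --- preprocess ---------------------------------------------------
        stage = "preprocess"
        log.info("preprocess: %d individuals x %d groups", *X.shape)
        X, excluded_groups = preprocess.filter_rare_groups(
            X, config.rare_group_threshold
        )
        tei = preprocess.total_energy_intake(X, comp)
        kept, excluded_ids, excl_report = preprocess.exclude_low_energy(tei, indiv)
        X = X.loc[kept]
        indiv = indiv.loc[kept]
        tei = tei.loc[kept]
        under = preprocess.flag_under_reporters(tei, indiv)
        (outdir / "exclusions.json").write_text(
            json.dumps(
                {
                    "excluded_food_groups": excluded_groups,
                    "excluded_individuals": excluded_ids,
                    **excl_report,
                    "under_reporter_fraction": float(under.mean()),
                }
            )
        )
        X.to_csv(outdir / "consumption_filtered.csv")
        last_good = outdir / "consumption_filtered.csv"

        # --- NMF ------------------------------------------------------------
        stage = "nmf"
        weights = indiv["weight"]
        rank_diag = None
        k = config.k
        if config.k_range is not None:
            lo, hi = int(config.k_range[0]), int(config.k_range[-1])
            rank_diag = nmf.select_rank(
                X,
                weights,
                range(lo, hi + 1),
                n_restarts=max(2, config.n_restarts // 3),
                seed=_stage_seed(config.seed, 1),
            )
            (outdir / "rank_diagnostics.json").write_text(
                json.dumps(rank_diag.to_dict())
            )
            if k is None:
                k = rank_diag.suggested_k
        log.info("nmf: k=%d, %d restarts", k, config.n_restarts)
        fp = nmf.ls_nmf_restarts(
            X,
            weights,
            k,
            n_restarts=config.n_restarts,
            seed=_stage_seed(config.seed, 2),
            tol=config.tol,
            max_iter=config.max_iter,
        )
        fp = nmf.normalize_factors(fp)
        Wdf = pd.DataFrame(
            fp.W, index=X.index, columns=[f"CS{j+1}" for j in range(k)]
        )
        Hdf = pd.DataFrame(
            fp.H, index=[f"CS{j+1}" for j in range(k)], columns=X.columns
        )
        Wdf.to_csv(outdir / "scores_W.csv")
        Hdf.to_csv(outdir / "loadings_H.csv")
        np.savetxt(outdir / "objective_trace.csv", fp.objective_trace, delimiter=",")
        contrib = nmf.loading_contributions(fp, config.contributor_cutoff)
        contrib.to_csv(outdir / "cs_contributions.csv", index=False)
        last_good = outdir / "scores_W.csv"

        # --- clustering -----------------------------------------------------
        stage = "cluster"
        c_lo, c_hi = int(config.c_range[0]), int(config.c_range[-1])
        assign = clustering.assign_patterns(
            Wdf, weights, range(c_lo, c_hi + 1), n_clusters=config.n_clusters
        )
        desc = clustering.describe_patterns(
            Wdf, assign.labels, weights, config.v_test_threshold
        )
        labels = pd.Series(assign.labels, index=X.index, name="pattern")
        labels.to_csv(outdir / "pattern_labels.csv")
        desc.v_tests.to_csv(outdir / "v_tests.csv")
        desc.relative_contribution.to_csv(outdir / "relative_contributions.csv")
        np.savetxt(outdir / "linkage.txt", assign.linkage, fmt="%.10g")
        (outdir / "inertia_ratio.json").write_text(
            json.dumps({str(c): r for c, r in assign.inertia_ratio.items()})
        )
        last_good = outdir / "pattern_labels.csv"

        # --- diet quality ---------------------------------------------------
        stage = "quality"
        intakes = quality.nutrient_intakes(X, comp)
        scores = pd.DataFrame(index=X.index)
        scores["tei_kcal"] = tei
        scores["mar"] = quality.mar(intakes, rda, indiv)
        scores["ed_kcal_per_g"] = quality.energy_density(X, comp)
        if diary is not None and dds_mapping:
            diary = diary[diary["individual_id"].isin(X.index)]
            dds_scores, dds_report = quality.dds(
                diary,
                dds_mapping,
                seed=_stage_seed(config.seed, 3),
                min_grams=config.dds_min_grams,
            )
            scores["dds"] = dds_scores
        scores.to_csv(outdir / "quality_scores.csv")
        adj_cov = indiv[[c for c in ADJUST_COVARIATES if c in indiv.columns]]
        qual_cmp = {}
        for col in ("mar", "ed_kcal_per_g", "dds"):
            if col in scores:
                qual_cmp[col] = quality.compare_group_means(
                    scores[col], labels, adj_cov, weights
                )
        pd.concat(qual_cmp, names=["score"]).to_csv(outdir / "quality_vs_overall.csv")
        last_good = outdir / "quality_scores.csv"

        # --- exposure -------------------------------------------------------
        stage = "exposure"
        expo = exposure.exposure_levels(
            X, contam, indiv["body_weight_kg"], mode=config.censoring_mode,
            assume_zero=True,
        )
        expo.to_csv(outdir / "exposures.csv")
        expo_cmp = exposure.compare_exposures(expo, labels, adj_cov, weights)
        expo_cmp.to_csv(outdir / "exposures_vs_overall.csv", index=False)

        # --- characterisation -------------------------------------------------
        stage = "characterize"
        wi_items = indiv[[c for c in WEALTH_ITEMS if c in indiv.columns]]
        wi = characterize.wealth_index(wi_items, weights)
        cov_logit = indiv[[c for c in LOGIT_COVARIATES if c in indiv.columns]].copy()
        cov_logit["wealth_tertile"] = wi.tertile.astype(str)
        cov_logit["sex"] = indiv["sex"]
        ors = characterize.pattern_logit(labels, cov_logit, weights, stratify_by="sex")
        ors.to_csv(outdir / "determinants_or.csv", index=False)
        wi.score.to_frame().join(wi.tertile).to_csv(outdir / "wealth_index.csv")

        # --- report -----------------------------------------------------------
        stage = "report"
        summary = {
            "n_individuals": int(X.shape[0]),
            "n_food_groups": int(X.shape[1]),
            "excluded_food_groups": excluded_groups,
            "k": int(k),
            "suggested_k": int(rank_diag.suggested_k) if rank_diag else None,
            "final_objective": float(fp.objective_trace[-1]),
            "n_patterns": int(assign.chosen_c),
            "pattern_shares_pct": {
                str(c): float(v) for c, v in assign.shares_pct.items()
            },
            "descriptor_cs": {
                str(c): [
                    cs
                    for cs in desc.significant_positive.columns
                    if bool(desc.significant_positive.loc[c, cs])
                ]
                for c in desc.significant_positive.index
            },
            "seed": config.seed,
        }
        log.info("pipeline finished in %.1f s", time.time() - t0)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        _write_report(outdir, summary, desc, contrib, qual_cmp, expo_cmp)
        return summary
    except Exception as err:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}; last good artefact: {last_good}"
        ) from err


def _write_report(outdir: Path, summary, desc, contrib, qual_cmp, expo_cmp) -> None:
    lines = ["# Dietary pattern report", ""]
    lines.append(
        f"{summary['n_individuals']} individuals x {summary['n_food_groups']} "
        f"food groups; {summary['k']} consumption systems; "
        f"{summary['n_patterns']} dietary patterns."
    )
    lines.append("")
    for c, share in summary["pattern_shares_pct"].items():
        lines.append(f"## Pattern {c} ({share:.1f} % of the population)")
        descriptors = summary["descriptor_cs"].get(c, [])
        lines.append(f"- descriptor CS (positive significant V-test): {descriptors or 'none'}")
        rc = desc.relative_contribution.loc[int(c)]
        top = rc.sort_values(ascending=False).head(3)
        lines.append(
            "- main CS contributions: "
            + ", ".join(f"{k} {v*100:.1f} %" for k, v in top.items())
        )
        for score, tab in qual_cmp.items():
            flag = tab.loc[int(c), "flag"]
            if flag != "ns":
                lines.append(f"- {score}: {flag} than the overall mean")
        sub_flags = expo_cmp[(expo_cmp["pattern"] == int(c)) & (expo_cmp["flag"] != "ns")]
        for _, row in sub_flags.iterrows():
            lines.append(f"- exposure to {row['substance']}: {row['flag']}")
        lines.append("")
    lines.append("## Main food-group contributors per CS")
    main = contrib[contrib["is_main"]]
    for cs, sub in main.groupby("cs"):
        tops = ", ".join(
            f"{r.food_group} ({r.contribution_pct:.1f} %)" for r in sub.itertuples()
        )
        lines.append(f"- CS{cs}: {tops}")
    (outdir / "report.md").write_text("\n".join(lines))


def run_demo(outdir: str | Path, seed: int = 0, n_individuals: int = 1200) -> dict:
    """Generate a synthetic survey bundle and run the full pipeline on it."""
    outdir = Path(outdir)
    sim = SimulationConfig(n_individuals=n_individuals, seed=seed)
    write_bundle(outdir / "bundle", sim)
    cfg = PipelineConfig(
        input_dir=str(outdir / "bundle"),
        output_dir=str(outdir / "results"),
        k=sim.n_cs,
        n_clusters=None,
        n_restarts=3,
        max_iter=800,
        seed=seed,
    )
    return run_pipeline(cfg)
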
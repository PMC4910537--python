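# dietpattern

Identification and characterisation of dietary patterns in food-consumption
surveys, using survey-weighted non-negative matrix factorisation (NMF)
followed by hierarchical clustering.

## What it does

Dietary surveys record how many grams of each food group every participant
eats per day. The matrix of mean daily consumption is sparse (most people do
not eat most food groups) and non-negative, and each participant carries a
sampling weight that makes the sample representative of the population. This
package analyses such data in five stages:

1. **Preprocessing** — aggregate food diaries to individual × food-group
   consumption (g/day), drop food groups consumed by less than 10 % of the
   sample, and exclude implausibly low energy reporters (total energy intake
   below 0.45 × Schofield basal metabolic rate, configurable).
2. **Weighted NMF** — factor the consumption matrix `X ≈ W H` with
   non-negative scores `W` (individual × consumption system) and loadings `H`
   (consumption system × food group), minimising the *survey-weighted*
   squared error `Σᵢ sᵢ Σⱼ (xᵢⱼ − (WH)ᵢⱼ)²` by multiplicative updates.
   A "consumption system" (CS) is a recurring combination of food groups,
   e.g. a sandwich-lunch or a fish-and-vegetables dinner. Rank is chosen by
   the elbow of the objective-vs-rank curve across multiple restarts.
3. **Clustering** — Ward hierarchical clustering of the NMF scores, with
   survey weights as observation masses, cut where the between/total inertia
   ratio stops improving. The clusters are the dietary patterns. Each
   pattern is described by the consumption systems with significant positive
   V-tests and by the relative contribution of each CS to the pattern's
   total consumption.
4. **Diet quality and exposure** — per individual: Mean Adequacy Ratio (MAR,
   mean of 20 nutrient intake/recommended-intake ratios truncated at 1),
   dietary energy density of non-beverage foods, a Dietary Diversity Score
   (DDS, 0–5 over three sampled diary days), and contaminant exposure in
   µg/kg body weight/day under lower/middle/upper-bound censoring
   substitution. Pattern means are compared to the overall mean by
   survey-weighted regression with sandwich standard errors.
5. **Determinants** — a household wealth index (first axis of a
   correspondence analysis of categorical wealth items, cut into weighted
   tertiles) and sex-stratified survey-weighted logistic regressions giving
   odds ratios of pattern membership per socio-demographic level.

A deterministic synthetic-data generator produces full survey bundles
(consumption, diaries, covariates, sampling weights, composition/RDA/
contamination tables) with known planted structure, so every stage can be
validated against ground truth.

## Worked example

Generate a synthetic survey of 800 individuals and run the full pipeline:

```python
from dietpattern import SimulationConfig, write_bundle
write_bundle("bundle", SimulationConfig(n_individuals=800, seed=42))
```

```yaml
# config.yaml
input_dir: bundle
output_dir: results
k: 7            # number of consumption systems (omit and set k_range to scan)
n_restarts: 3
max_iter: 800
seed: 42
```

```bash
$ dietpattern run --config config.yaml
{
 "descriptor_cs": {
  "1": ["CS5"], "2": ["CS4"], "3": ["CS7"], "4": ["CS6"],
  "5": ["CS1"], "6": ["CS3"], "7": ["CS2"]
 },
 "excluded_food_groups": [],
 "final_objective": 38144305.493967146,
 "k": 7,
 "n_food_groups": 66,
 "n_individuals": 800,
 "n_patterns": 7,
 "pattern_shares_pct": {
  "1": 13.06, "2": 15.17, "3": 12.43, "4": 13.35,
  "5": 19.49, "6": 14.48, "7": 12.02
 },
 "seed": 42
}
```

(Shares abbreviated here; the JSON carries full precision.) `results/`
contains every intermediate artefact (`scores_W.csv`, `loadings_H.csv`,
`pattern_labels.csv`, `v_tests.csv`, `quality_scores.csv`, `exposures.csv`,
`determinants_or.csv`, `wealth_index.csv`, …) plus a human-readable
`report.md`:

```
# Dietary pattern report

800 individuals x 66 food groups; 7 consumption systems; 7 dietary patterns.

## Pattern 1 (13.1 % of the population)
- descriptor CS (positive significant V-test): ['CS5']
- main CS contributions: CS5 59.4 %, CS4 7.9 %, CS1 7.3 %
- ed_kcal_per_g: lower than the overall mean
- exposure to acrylamide: higher
- exposure to lead: higher
...
```

The same stages are available individually (`dietpattern simulate`,
`preprocess`, `nmf`, `cluster`, `exposure`) and as library functions — see
`docs/methods.md` and the docstrings.

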
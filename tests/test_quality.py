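"""Nutrient intakes, MAR / ED / DDS closed forms, adjusted comparisons."""

import numpy as np
import pandas as pd
import pytest

from dietpattern import (
    compare_group_means,
    dds,
    energy_density,
    mar,
    nutrient_intakes,
)
from dietpattern.synthetic import MAR_NUTRIENTS


def _rda_table():
    row = {n: 100.0 for n in MAR_NUTRIENTS}
    idx = pd.MultiIndex.from_tuples(
        [("M", "35-49"), ("F", "35-49")], names=["sex", "age_band"]
    )
    return pd.DataFrame([row, row], index=idx)


def _covs(ids, sex="M"):
    return pd.DataFrame(
        {"sex": sex, "age": 40.0, "age_band": "35-49"}, index=ids
    )


def test_nutrient_intake_arithmetic(toy_composition):
    X = pd.DataFrame(
        [[100.0, 0.0, 0.0, 0.0]], index=["a"], columns=toy_composition.index
    )
    out = nutrient_intakes(X, toy_composition)
    assert out.loc["a", "vitamin_c_mg"] == pytest.approx(10.0)
    assert out.loc["a", "energy_kcal"] == pytest.approx(200.0)

    zero = nutrient_intakes(X * 0.0, toy_composition)
    assert (zero.to_numpy() == 0).all()


def test_nutrient_intake_two_food_hand_sum(toy_composition):
    X = pd.DataFrame(
        [[150.0, 80.0, 0.0, 500.0]], index=["a"], columns=toy_composition.index
    )
    out = nutrient_intakes(X, toy_composition)
    assert out.loc["a", "vitamin_c_mg"] == pytest.approx(1.5 * 10 + 0.8 * 50)
    assert out.loc["a", "energy_kcal"] == pytest.approx(1.5 * 200 + 0.8 * 100)
    # linearity
    out2 = nutrient_intakes(2 * X, toy_composition)
    np.testing.assert_allclose(out2.to_numpy(), 2 * out.to_numpy())


def test_nutrient_intake_missing_group(toy_composition):
    X = pd.DataFrame([[1.0]], index=["a"], columns=["martian_berries"])
    with pytest.raises(KeyError, match="martian_berries"):
        nutrient_intakes(X, toy_composition)


def test_mar_closed_forms():
    rda = _rda_table()
    ids = ["a", "b", "c"]
    cov = _covs(ids)
    intakes = pd.DataFrame(
        {n: [150.0, 50.0, 0.0] for n in MAR_NUTRIENTS}, index=ids
    )
    # no-compensation case: 10 nutrients at double RDA, 10 at zero
    intakes.loc["c", list(MAR_NUTRIENTS[:10])] = 200.0
    out = mar(intakes, rda, cov)
    assert out["a"] == pytest.approx(100.0)   # all above RDA, truncated
    assert out["b"] == pytest.approx(50.0)    # all at half RDA
    assert out["c"] == pytest.approx(50.0)    # surplus cannot compensate


def test_mar_monotone_and_truncation_invariant(rng):
    rda = _rda_table()
    ids = [f"i{j}" for j in range(5)]
    cov = _covs(ids)
    base = pd.DataFrame(
        rng.uniform(0, 200, (5, 20)), index=ids, columns=list(MAR_NUTRIENTS)
    )
    m0 = mar(base, rda, cov)
    m1 = mar(base + 10.0, rda, cov)
    assert (m1 >= m0 - 1e-12).all()
    above = base.clip(lower=120.0)
    np.testing.assert_allclose(mar(above, rda, cov), 100.0)


def test_energy_density_arithmetic(toy_composition):
    X = pd.DataFrame(
        [[100.0, 0.0, 0.0, 0.0]], index=["a"], columns=toy_composition.index
    )
    ed = energy_density(X, toy_composition)
    assert ed["a"] == pytest.approx(2.0)
    # beverages never move it
    X2 = X.copy()
    X2["water"] = 500.0
    assert energy_density(X2, toy_composition)["a"] == pytest.approx(2.0)
    # kJ variant
    assert energy_density(X, toy_composition, unit="kJ")["a"] == pytest.approx(8.368)


def test_energy_density_three_food_hand_value(toy_composition):
    X = pd.DataFrame(
        [[100.0, 200.0, 50.0, 300.0]], index=["a"], columns=toy_composition.index
    )
    ed = energy_density(X, toy_composition)
    expected = (100 * 200 + 200 * 100 + 50 * 400) / 100.0 / 350.0
    assert ed["a"] == pytest.approx(expected)


def test_energy_density_beverage_only_is_missing(toy_composition):
    X = pd.DataFrame(
        [[0.0, 0.0, 0.0, 800.0]], index=["a"], columns=toy_composition.index
    )
    assert np.isnan(energy_density(X, toy_composition)["a"])


def _diary_rows(ind, day, dtype, group, g):
    return {"individual_id": ind, "day_index": day, "day_type": dtype,
            "food_group": group, "amount_g": g}


_MAPPING = {
    "dairy": ("milk",), "meat_fish": ("fish",), "cereals": ("bread",),
    "fruits": ("apple",), "vegetables": ("carrot",),
}


def _full_diary(amounts: dict[str, float], ind="a"):
    rows = []
    for d in range(1, 8):
        dtype = "weekday" if d <= 5 else "weekend"
        for g, a in amounts.items():
            rows.append(_diary_rows(ind, d, dtype, g, a))
    return pd.DataFrame(rows)


def test_dds_extremes_and_boundary():
    all_big = _full_diary({g[0]: 40.0 for g in _MAPPING.values()})
    score, report = dds(all_big, _MAPPING, seed=0)
    assert score["a"] == 5
    assert report["insufficient_day_types"] == []

    none = _full_diary({"chips": 500.0})
    assert dds(none, _MAPPING, seed=0)[0]["a"] == 0

    # 29 g of fruit over the 3 sampled days misses the 30 g rule
    amounts = {g[0]: 40.0 for g in _MAPPING.values()}
    amounts["apple"] = 29.0 / 3.0
    score3, _ = dds(_full_diary(amounts), _MAPPING, seed=0)
    assert score3["a"] == 4


def test_dds_deterministic_and_bounded(rng):
    rows = []
    for ind in ("a", "b", "c"):
        for d in range(1, 8):
            dtype = "weekday" if d <= 5 else "weekend"
            for g in ("milk", "fish", "bread", "apple", "carrot"):
                rows.append(_diary_rows(ind, d, dtype, g, float(rng.uniform(0, 30))))
    diary = pd.DataFrame(rows)
    s1, _ = dds(diary, _MAPPING, seed=7)
    s2, _ = dds(diary, _MAPPING, seed=7)
    pd.testing.assert_series_equal(s1, s2)
    assert s1.between(0, 5).all()


def test_dds_missing_day_types_reported():
    rows = [_diary_rows("a", d, "weekday", "milk", 50.0) for d in range(1, 6)]
    diary = pd.DataFrame(rows)  # no weekend days
    score, report = dds(diary, _MAPPING, seed=0)
    assert "a" in report["insufficient_day_types"]
    assert "a" not in score.index


def test_compare_group_means_detects_planted_shift(rng):
    n = 1500
    lab = rng.integers(1, 5, n)
    y = pd.Series(rng.normal(size=n), index=[f"i{j}" for j in range(n)])
    y[lab == 2] += 1.0
    res = compare_group_means(y, lab)
    assert res.loc[2, "flag"] == "higher"
    assert res.loc[2, "adjusted_mean"] > res.loc[1, "adjusted_mean"]


def test_compare_group_means_equal_weights_match_unweighted(rng):
    n = 300
    ids = [f"i{j}" for j in range(n)]
    y = pd.Series(rng.normal(size=n), index=ids)
    lab = rng.integers(1, 4, n)
    cov = pd.DataFrame({"age": rng.uniform(20, 70, n)}, index=ids)
    a = compare_group_means(y, lab, cov, None)
    b = compare_group_means(y, lab, cov, np.ones(n))
    pd.testing.assert_frame_equal(a, b)


def test_compare_group_means_collinear_covariates_named(rng):
    n = 100
    ids = [f"i{j}" for j in range(n)]
    y = pd.Series(rng.normal(size=n), index=ids)
    lab = rng.integers(1, 3, n)
    x = rng.normal(size=n)
    cov = pd.DataFrame({"x1": x, "x2": 2 * x}, index=ids)
    with pytest.raises(ValueError, match="x2"):
        compare_group_means(y, lab, cov)
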
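"""Wealth index (correspondence analysis) and pattern-membership logits."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from dietpattern import pattern_logit, wealth_index


def _items(rng, n=200):
    latent = rng.normal(size=n)
    def cut(x, probs):
        qs = np.quantile(x, np.cumsum(probs)[:-1])
        return np.digitize(x, qs)
    return pd.DataFrame(
        {
            "n_cars": cut(latent + rng.normal(scale=0.5, size=n), [0.3, 0.4, 0.3]),
            "dwelling": np.where(latent + rng.normal(scale=0.7, size=n) > 0,
                                 "owner", "renter"),
            "n_rooms": cut(latent + rng.normal(scale=0.6, size=n), [0.25, 0.5, 0.25]),
        },
        index=[f"i{j}" for j in range(n)],
    ).astype(str)


def test_ca_scores_match_svd_oracle(rng):
    items = _items(rng, 120)
    wi = wealth_index(items)
    # from-scratch CA of the disjunctive table
    Z = pd.get_dummies(items, prefix_sep="=").astype(float).to_numpy()
    P = Z / Z.sum()
    r, c = P.sum(1), P.sum(0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    oracle = U[:, 0] * sv[0] / np.sqrt(r)
    got = wi.score.to_numpy()
    err = min(np.abs(got - oracle).max(), np.abs(got + oracle).max())
    assert err < 1e-10
    assert 0.0 < wi.inertia_share <= 1.0


def test_correlated_items_give_graded_score(rng):
    items = _items(rng, 500)
    wi = wealth_index(items, orient_by="n_cars=2")
    # wealthier levels of each item should score higher on average
    rich = wi.score[items["n_cars"] == "2"].mean()
    poor = wi.score[items["n_cars"] == "0"].mean()
    assert rich > poor
    assert set(wi.tertile.unique()) == {1, 2, 3}
    # tertiles roughly balanced under unit weights
    shares = wi.tertile.value_counts(normalize=True)
    assert shares.min() > 0.2


def test_orientation_rule(rng):
    items = _items(rng, 200)
    a = wealth_index(items, orient_by="n_cars=2")
    b = wealth_index(items, orient_by="n_cars=0")
    assert a.column_coords["n_cars=2"] > 0
    assert b.column_coords["n_cars=0"] > 0
    np.testing.assert_allclose(np.abs(a.score), np.abs(b.score), atol=1e-12)
    with pytest.raises(KeyError):
        wealth_index(items, orient_by="n_cars=99")


def test_single_level_item_dropped_with_warning(rng):
    items = _items(rng, 100)
    items["constant"] = "yes"
    with pytest.warns(UserWarning, match="constant"):
        wi = wealth_index(items)
    assert not any(c.startswith("constant=") for c in wi.column_coords.index)
    with pytest.raises(ValueError):
        wealth_index(pd.DataFrame({"only": ["a"] * 10}))


def test_weighted_tertiles_respond_to_weights(rng):
    items = _items(rng, 300)
    wi_u = wealth_index(items)
    w = np.where(wi_u.score > np.median(wi_u.score), 5.0, 1.0)
    wi_w = wealth_index(items, weights=w)
    # upweighting the rich moves the cutpoints up: fewer individuals in T3
    assert (wi_w.tertile == 3).sum() <= (wi_u.tertile == 3).sum()


def _covs(rng, n):
    return pd.DataFrame(
        {
            "sex": rng.choice(["F", "M"], n),
            "age": rng.uniform(20, 80, n),
            "education": rng.choice(["primary", "secondary", "tertiary"], n),
        },
        index=[f"i{j}" for j in range(n)],
    )


def test_reference_levels_have_or_one(rng):
    n = 400
    cov = _covs(rng, n)
    lab = rng.integers(1, 4, n)
    res = pattern_logit(lab, cov)
    ref = res[res["reference"]]
    assert (ref["OR"] == 1.0).all()
    # sorted-first reference level
    assert set(ref[ref["variable"] == "education"]["level"]) == {"primary"}
    assert set(res["stratum"]) == {"F", "M"}


def test_equal_weights_match_unweighted_glm_oracle(rng):
    n = 500
    cov = _covs(rng, n)
    lab = rng.integers(1, 3, n)
    res = pattern_logit(lab, cov, weights=np.ones(n), stratify_by=None)
    sub = res[(res["pattern"] == 1) & (res["variable"] == "age")]
    Xd = pd.get_dummies(cov[["age", "education", "sex"]], drop_first=True, dtype=float)
    Xd = sm.add_constant(Xd)
    # oracle restricted to the same design: rebuild exactly as pattern_logit does
    parts = [cov[["age"]]]
    for var in ("education", "sex"):
        levels = sorted(cov[var].unique())
        d = pd.get_dummies(cov[var], prefix=var, prefix_sep="=", dtype=float)
        parts.append(d[[f"{var}={l}" for l in levels[1:]]])
    Xo = pd.concat(parts, axis=1)
    Xo.insert(0, "const", 1.0)
    fit = sm.GLM((lab == 1).astype(float), Xo,
                 family=sm.families.Binomial()).fit()
    assert sub["OR"].iloc[0] == pytest.approx(np.exp(fit.params["age"]), rel=1e-6)


def test_planted_or_recovered_within_ci(rng):
    n = 3000
    x = rng.integers(0, 2, n)
    logit = -0.8 + np.log(2.0) * x
    y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)
    cov = pd.DataFrame(
        {"exposure": np.where(x == 1, "yes", "no")},
        index=[f"i{j}" for j in range(n)],
    )
    lab = np.where(y == 1, 1, 2)
    res = pattern_logit(lab, cov, stratify_by=None)
    row = res[(res["pattern"] == 1) & (res["level"] == "yes")].iloc[0]
    assert row["CI_low"] <= 2.0 <= row["CI_high"]
    assert row["OR"] == pytest.approx(2.0, rel=0.25)


def test_separation_flagged_not_infinite():
    n = 80
    cov = pd.DataFrame(
        {"group": ["a"] * 40 + ["b"] * 40}, index=[f"i{j}" for j in range(n)]
    )
    lab = np.r_[np.ones(40, int), np.full(40, 2, int)]  # perfect separation
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pattern_logit(lab, cov, stratify_by=None)
    est = res[~res["reference"]]
    assert est["flagged"].all()
    assert np.isfinite(est["OR"]).all() or est["OR"].isna().any()
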
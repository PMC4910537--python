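"""Weighted NMF: update correctness, normalisation, matching, rank choice."""

import numpy as np
import pandas as pd
import pytest

from dietpattern import (
    SimulationConfig,
    generate_consumption,
    generate_truth,
    loading_contributions,
    ls_nmf,
    ls_nmf_restarts,
    match_factors,
    normalize_factors,
    select_rank,
)
from dietpattern.nmf import FactorPair, lee_seung_mu, weighted_rss


def test_domain_errors():
    X = np.ones((5, 4))
    with pytest.raises(ValueError):
        ls_nmf(X - 2.0, None, 2)
    with pytest.raises(ValueError):
        ls_nmf(X, None, 9)
    with pytest.raises(ValueError):
        ls_nmf(X, np.zeros(5), 2)


def test_exact_rank2_factorization_recovered(rng):
    W0 = rng.random((40, 2))
    H0 = rng.random((2, 12))
    X = W0 @ H0
    fp = ls_nmf_restarts(X, None, 2, n_restarts=5, seed=1, tol=1e-12, max_iter=5000)
    assert fp.objective_trace[-1] <= 1e-8 * (X**2).sum()


def test_objective_monotone_nonincreasing(rng):
    for seed in range(10):
        r = np.random.default_rng(seed)
        X = r.random((25, 12)) * 3
        w = r.lognormal(0, 0.5, 25)
        fp = ls_nmf(X, w, 4, seed=seed, tol=0.0, max_iter=200)
        d = np.diff(fp.objective_trace)
        assert (d <= 1e-8 * fp.objective_trace[0]).all()


def test_equal_weights_match_lee_seung_oracle(rng):
    """With unit weights the weighted updates ARE the classical ones."""
    X = rng.random((30, 10)) * 5
    W0 = rng.random((30, 3)) + 0.1
    H0 = rng.random((3, 10)) + 0.1
    fp = ls_nmf(X, np.ones(30), 3, W0=W0, H0=H0, tol=0.0, max_iter=100)
    Wo, Ho = lee_seung_mu(X, 3, W0, H0, 100)
    np.testing.assert_allclose(fp.W, Wo, atol=1e-10)
    np.testing.assert_allclose(fp.H, Ho, atol=1e-10)


def test_constant_weights_scale_objective_only(rng):
    X = rng.random((20, 8)) * 2
    W0 = rng.random((20, 3)) + 0.1
    H0 = rng.random((3, 8)) + 0.1
    fp1 = ls_nmf(X, np.ones(20), 3, W0=W0, H0=H0, tol=0.0, max_iter=50)
    fp3 = ls_nmf(X, np.full(20, 3.0), 3, W0=W0, H0=H0, tol=0.0, max_iter=50)
    np.testing.assert_allclose(fp3.W, fp1.W, atol=1e-10)
    np.testing.assert_allclose(fp3.objective_trace, 3.0 * fp1.objective_trace, rtol=1e-10)


def test_normalize_factors_scale_transfer():
    W = np.array([[1.0], [2.0]])
    H = np.array([[2.0, 2.0, 4.0]])
    fp = normalize_factors(
        FactorPair(W=W, H=H, objective_trace=np.array([0.0]), k=1, converged=True, n_iter=0)
    )
    np.testing.assert_allclose(fp.H[0], [0.25, 0.25, 0.5])
    np.testing.assert_allclose(fp.W[:, 0], [8.0, 16.0])
    # idempotent and product-preserving
    fp2 = normalize_factors(fp)
    np.testing.assert_allclose(fp2.H, fp.H)
    np.testing.assert_allclose(fp2.W @ fp2.H, W @ H, rtol=1e-12)


def test_normalize_random_product_preserved(rng):
    W = rng.random((15, 4))
    H = rng.random((4, 9)) + 0.01
    fp = FactorPair(W=W, H=H, objective_trace=np.array([1.0]), k=4, converged=True, n_iter=1)
    fp2 = normalize_factors(fp)
    before, after = W @ H, fp2.W @ fp2.H
    assert np.abs(before - after).max() <= 1e-12 * before.max()
    with pytest.raises(ValueError):
        normalize_factors(
            FactorPair(W=W[:, :1], H=np.zeros((1, 9)), objective_trace=np.array([1.0]),
                       k=1, converged=True, n_iter=1)
        )


def test_loading_contributions_cutoff():
    H = np.array([[0.5, 0.3, 0.2], [0.024, 0.486, 0.49]])
    fp = FactorPair(W=np.ones((4, 2)), H=H, objective_trace=np.array([0.0]),
                    k=2, converged=True, n_iter=0,
                    food_groups=["bread", "fruit", "meat"])
    tab = loading_contributions(fp, cutoff=0.025)
    cs1 = tab[tab["cs"] == 1]
    assert cs1["contribution_pct"].tolist() == [50.0, 30.0, 20.0]
    assert cs1["is_main"].all()
    cs2 = tab[tab["cs"] == 2].set_index("food_group")
    assert not cs2.loc["bread", "is_main"]          # 2.4 % falls short of 2.5 %
    assert tab.groupby("cs")["contribution_pct"].sum().round(9).eq(100.0).all()


def test_match_factors_identity_and_permutation(rng):
    H = rng.random((5, 20))
    perm, cos = match_factors(H, H)
    np.testing.assert_array_equal(perm, np.arange(5))
    np.testing.assert_allclose(cos, 1.0)

    p = np.array([3, 0, 4, 1, 2])
    perm2, cos2 = match_factors(H[p], H)
    np.testing.assert_array_equal(perm2, np.argsort(p))
    np.testing.assert_allclose(cos2, 1.0)
    with pytest.raises(ValueError):
        match_factors(H, H[:3])


def test_noiseless_planted_loadings_recovered():
    cfg = SimulationConfig(
        n_individuals=400, n_food_groups=30, n_cs=4, n_patterns=4,
        zero_inflation=0.0, noise_cv=0.0, seed=17,
    )
    truth = generate_truth(cfg)
    X = generate_consumption(truth, cfg)
    fp = normalize_factors(
        ls_nmf_restarts(X, None, 4, n_restarts=4, seed=0, tol=1e-10, max_iter=4000)
    )
    _, cos = match_factors(fp.H, truth.true_loadings)
    assert np.median(cos) >= 0.999


def test_rank_scan_objective_monotone_and_elbow():
    cfg = SimulationConfig(
        n_individuals=400, n_food_groups=30, n_cs=3, n_patterns=3,
        noise_cv=0.1, seed=23,
    )
    X = generate_consumption(generate_truth(cfg), cfg)
    diag = select_rank(X, None, range(1, 8), n_restarts=2, seed=23)
    objs = diag.best_objective
    assert all(objs[i + 1] <= objs[i] for i in range(len(objs) - 1))
    assert objs[-1] <= objs[0]
    assert diag.suggested_k == 3
    d = diag.to_dict()
    assert d["suggested_k"] == 3 and len(d["k_values"]) == 7


def test_dataframe_labels_carried_through(small_population):
    truth, X = small_population
    fp = ls_nmf(X, None, 3, seed=0, max_iter=50)
    assert fp.food_groups == list(X.columns)
    assert fp.individual_ids == list(X.index)
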
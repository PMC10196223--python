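"""Constrained-ordination machinery: PCNM, dbRDA (against a brute-force
PCoA+OLS oracle), forward selection and the variance-partition table."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from genoscape.containers import DistMatrix
from genoscape.landgen import (DBRDA, dbrda, forward_select, pcnm,
                               permutation_anova, standardize,
                               variance_partition)


def _dist(values, labels=None, kind="generic"):
    labels = labels or [f"s{i}" for i in range(len(values))]
    return DistMatrix(labels, np.asarray(values, float), kind)


def _euclid(points):
    return squareform(pdist(np.asarray(points, float)))


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

def test_pcnm_equilateral_triangle():
    D = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
    V = pcnm(_dist(D), truncation=2.0)
    lam = V.attrs["eigenvalues"]
    assert len(lam) == 2
    assert lam[0] == pytest.approx(lam[1])
    np.testing.assert_allclose(V.T.to_numpy() @ V.to_numpy(), np.eye(2),
                               atol=1e-8)


def test_pcnm_untruncated_recovers_pcoa_of_line():
    """Collinear points with t >= max distance: coordinates equal classical
    PCoA (eigen oracle on the Gower-centered matrix)."""
    x = np.array([0.0, 1.0, 2.5, 4.0, 7.0])
    D = np.abs(np.subtract.outer(x, x))
    V = pcnm(_dist(D), truncation=10.0)
    G = -0.5 * (np.eye(5) - 1 / 5) @ (D ** 2) @ (np.eye(5) - 1 / 5)
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    keep = lam[order] > 1e-8
    np.testing.assert_allclose(V.attrs["eigenvalues"], lam[order][keep],
                               atol=1e-8)
    for j in range(V.shape[1]):
        v, u = V.iloc[:, j].to_numpy(), U[:, order][:, j]
        assert np.allclose(v, u, atol=1e-8) or np.allclose(v, -u, atol=1e-8)


def test_pcnm_orthogonal_centered(world):
    sites = world.sites
    D = _euclid(sites[["lon", "lat"]])
    V = pcnm(_dist(D, labels=list(sites["pop"])))
    M = V.to_numpy()
    assert M.shape[1] <= len(sites) - 1
    np.testing.assert_allclose(M.sum(axis=0), 0.0, atol=1e-8)
    np.testing.assert_allclose(M.T @ M, np.eye(M.shape[1]), atol=1e-8)


def test_pcnm_rejects_degenerate():
    with pytest.raises(ValueError):
        pcnm(_dist(np.zeros((4, 4))))


# ---------------------------------------------------------------------------
# dbRDA
# ---------------------------------------------------------------------------

def test_dbrda_self_explanation(rng):
    pts = rng.normal(size=(10, 2))
    d = _dist(_euclid(pts))
    X = pd.DataFrame(pts, index=d.labels, columns=["x", "y"])
    res = dbrda(d, X)
    assert res.R2 == pytest.approx(1.0, abs=1e-9)


def test_dbrda_matches_bruteforce_pcoa_ols(rng):
    """Small instance: R2 identical to an independent explicit
    PCoA-then-OLS-on-every-axis implementation."""
    n = 5
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    d = _dist(D)
    X = pd.DataFrame(rng.normal(size=(n, 2)), index=d.labels,
                     columns=["a", "b"])
    res = dbrda(d, X)
    # oracle
    J = np.eye(n) - 1 / n
    G = -0.5 * J @ (D ** 2) @ J
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    pos = lam > 1e-10
    Y = U[:, pos] * np.sqrt(lam[pos])
    Xc = np.column_stack([np.ones(n), X.to_numpy()])
    ss_fit = 0.0
    for j in range(Y.shape[1]):
        beta, *_ = np.linalg.lstsq(Xc, Y[:, j], rcond=None)
        fitted = Xc @ beta - Y[:, j].mean()
        ss_fit += (fitted ** 2).sum()
    assert res.R2 == pytest.approx(ss_fit / lam[pos].sum(), abs=1e-9)


def test_dbrda_empty_Z_equals_constant_Z(rng):
    pts = rng.normal(size=(8, 2))
    d = _dist(_euclid(pts))
    X = pd.DataFrame(rng.normal(size=(8, 2)), index=d.labels,
                     columns=["a", "b"])
    Zc = pd.DataFrame({"const": np.ones(8)}, index=d.labels)
    r1 = dbrda(d, X)
    with pytest.warns(RuntimeWarning):
        r2 = dbrda(d, X, Z=Zc)
    assert r1.R2 == pytest.approx(r2.R2, abs=1e-9)


def test_dbrda_nested_r2_inequality(rng):
    pts = rng.normal(size=(12, 3))
    d = _dist(_euclid(pts))
    X = pd.DataFrame(rng.normal(size=(12, 4)), index=d.labels,
                     columns=list("abcd"))
    full = dbrda(d, X)
    reduced = dbrda(d, X[["a", "b"]])
    assert full.R2 >= reduced.R2 - 1e-12


def test_permutation_p_perfect_model(rng):
    pts = rng.normal(size=(10, 2))
    d = _dist(_euclid(pts))
    X = pd.DataFrame(pts, index=d.labels, columns=["x", "y"])
    res = dbrda(d, X, nperm=199)
    assert res.p == pytest.approx(1 / 200)
    assert res.p > 0          # +1 correction: never exactly 0


def test_permutation_anova_function(rng):
    pts = rng.normal(size=(9, 2))
    d = _dist(_euclid(pts))
    X = pd.DataFrame(rng.normal(size=(9, 2)), index=d.labels,
                     columns=["a", "b"])
    res = dbrda(d, X)
    p = permutation_anova(res, nperm=99, seed=5)
    assert 0 < p <= 1
    with pytest.raises(ValueError):
        res.model.permutation_test(res.F, nperm=50)


def test_aliased_column_dropped(rng):
    pts = rng.normal(size=(8, 2))
    d = _dist(_euclid(pts))
    X = pd.DataFrame({"a": pts[:, 0], "dup": pts[:, 0] * 2.0,
                      "b": pts[:, 1]}, index=d.labels)
    with pytest.warns(RuntimeWarning, match="aliased"):
        res = dbrda(d, X)
    assert "dup" not in res.model.x_names


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def test_forward_select_recovers_causal_variable():
    """One causal variable among ten noise candidates: selected alone in at
    least 90% of seeded replicates."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        r = np.random.default_rng(900 + rep)
        n = 21
        causal = r.normal(size=n)
        D = (np.abs(np.subtract.outer(causal, causal))
             + 0.5 * _euclid(r.normal(size=(n, 3))))
        np.fill_diagonal(D, 0)
        d = _dist(D)
        cand = pd.DataFrame(r.normal(size=(n, 10)), index=d.labels,
                            columns=[f"n{i:02d}" for i in range(10)])
        cand["causal"] = causal
        sel = forward_select(d, standardize(cand), alpha=0.01, nperm=199,
                             seed=rep)
        if list(sel["variable"]) == ["causal"]:
            hits += 1
    assert hits >= int(0.9 * n_rep)


def test_forward_select_null_empty(rng):
    n = 15
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    d = _dist(D)
    cand = pd.DataFrame(rng.normal(size=(n, 5)), index=d.labels,
                        columns=list("abcde"))
    sel = forward_select(d, standardize(cand), alpha=0.01, nperm=199, seed=0)
    assert len(sel) <= 1      # nothing real to find


def test_forward_select_duplicate_candidates(rng):
    n = 18
    causal = rng.normal(size=n)
    D = np.abs(np.subtract.outer(causal, causal))
    np.fill_diagonal(D, 0)
    d = _dist(D)
    cand = pd.DataFrame({"v1": causal, "v2": causal}, index=d.labels)
    sel = forward_select(d, standardize(cand), alpha=0.05, nperm=199, seed=0)
    assert len(sel) <= 1      # aliased duplicate never both selected


# ---------------------------------------------------------------------------
# variance partition
# ---------------------------------------------------------------------------

def test_partition_orthogonal_blocks(rng):
    n = 20
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a, b = a - a.mean(), b - b.mean()
    b -= a * (a @ b) / (a @ a)          # exactly orthogonal
    pts = np.column_stack([a, b])
    d = _dist(_euclid(pts))
    blocks = {"A": standardize(pd.DataFrame({"a": a}, index=d.labels)),
              "B": standardize(pd.DataFrame({"b": b}, index=d.labels))}
    tab = variance_partition(d, blocks, nperm=99)
    pure = tab.set_index("model")
    assert pure.loc["full", "explained"] == pytest.approx(1.0, abs=1e-9)
    assert pure.loc["pure A", "confounded"] == pytest.approx(
        pure.loc["full", "explained"] - pure.loc["pure A", "explained"], abs=1e-12)
    assert abs(pure.loc["pure A", "explained"]
               + pure.loc["pure B", "explained"] - 1.0) < 0.05


def test_partition_duplicated_block_fully_confounded(rng):
    n = 15
    x = rng.normal(size=(n, 2))
    d = _dist(_euclid(x))
    Xz = standardize(pd.DataFrame(x, index=d.labels, columns=["x", "y"]))
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = variance_partition(d, {"A": Xz, "B": Xz.copy()}, nperm=99)
    t = tab.set_index("model")
    assert t.loc["pure A", "explained"] == pytest.approx(0.0, abs=1e-9)
    assert t.loc["pure A", "confounded"] == pytest.approx(
        t.loc["full", "explained"], abs=1e-9)


def test_partition_closure_and_cascade(world):
    from genoscape.popgen import pairwise_fst, slatkin_linearize, ancestry_pca
    lin = slatkin_linearize(pairwise_fst(world.genotypes))
    sites = world.sites.set_index("pop").loc[lin.labels]
    geo = standardize(sites[["lon", "lat"]])
    clim = standardize(world.climate_current.sample_points(
        sites["lon"], sites["lat"], ["bio15", "bio19"]).set_index(sites.index))
    anc = standardize(ancestry_pca(world.q_matrix))
    tables = variance_partition(lin, {"clim": clim, "geo": geo, "anc": anc},
                                nperm=99, cascade=True, alpha=0.05)
    for tab in tables:
        pure = tab[tab["model"].str.startswith("pure")]
        closure = pure["explained"] + pure["confounded"] + pure["unexplained"]
        np.testing.assert_allclose(closure, 1.0, atol=1e-6)
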
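"""Niche-model stage: VIF filter against exhaustive search, AUC/TSS
enumeration oracle, threshold areas, altitude stats, TRI closed forms and
climate PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from genoscape.containers import RasterGrid, SuitabilityMap
from genoscape.enm import (altitudinal_stats, area_change, climate_pca,
                           compute_tri, ensemble_mean, evaluate,
                           fit_suitability, threshold_area, vif_filter)


def _grid(values, west=41.0, south=40.0):
    values = np.asarray(values, dtype=float)
    return RasterGrid(values, west, south,
                      west + values.shape[1] * 0.1,
                      south + values.shape[0] * 0.1)


# ---------------------------------------------------------------------------
# VIF filter
# ---------------------------------------------------------------------------

def test_vif_identical_columns_one_dropped(rng):
    x = rng.normal(size=50)
    tab = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
    kept, log = vif_filter(tab)
    assert sorted(kept) in (["a", "c"], ["b", "c"])
    assert len(log) == 1


def test_vif_orthogonal_columns_all_kept(rng):
    X = np.linalg.qr(rng.normal(size=(60, 4)))[0]
    tab = pd.DataFrame(X, columns=list("abcd"))
    kept, log = vif_filter(tab)
    assert kept == list("abcd") and log.empty


def _max_vif(tab):
    from statsmodels.stats.outliers_influence import variance_inflation_factor
    X = tab.to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    Xc = np.column_stack([np.ones(len(X)), X])
    with np.errstate(divide="ignore", invalid="ignore"):
        v = [variance_inflation_factor(Xc, j + 1) for j in range(tab.shape[1])]
    return np.nan_to_num(np.max(v), nan=np.inf)


def test_vif_matches_exhaustive_drop_order_search(rng):
    """3-variable instance with one near-duplicate pair: the stepwise result
    equals the best (largest-retained, all-VIF-ok) subset found by
    exhaustive search over drop orders."""
    x = rng.normal(size=80)
    tab = pd.DataFrame({"a": x, "b": x + 0.01 * rng.normal(size=80),
                        "c": rng.normal(size=80)})
    kept, _ = vif_filter(tab, threshold=10)
    # oracle: all subsets, keep the largest with max VIF <= 10
    best = None
    for r in (3, 2, 1):
        for sub in itertools.combinations(tab.columns, r):
            if len(sub) == 1 or _max_vif(tab[list(sub)]) <= 10:
                best = set(sub)
                break
        if best:
            break
    assert set(kept) == best or len(kept) == len(best)
    assert len(kept) > 1 and _max_vif(tab[kept]) <= 10


def test_vif_output_always_below_threshold(climate):
    tab = climate.as_table().sample(300, random_state=0)
    kept, _ = vif_filter(tab, threshold=10)
    assert len(kept) >= 2
    assert _max_vif(tab[kept]) <= 10


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def test_evaluate_separable_and_uninformative():
    auc, tss = evaluate(np.ones(5), np.zeros(7))
    assert auc == 1.0 and tss == 1.0
    auc, tss = evaluate(np.full(5, 0.4), np.full(7, 0.4))
    assert auc == 0.5 and tss == 0.0


def test_evaluate_matches_pair_counting_oracle(rng):
    for _ in range(20):
        p = rng.random(5)
        b = rng.random(8)
        auc, _ = evaluate(p, b)
        wins = sum((x > y) + 0.5 * (x == y) for x in p for y in b)
        assert auc == pytest.approx(wins / (5 * 8))


def test_evaluate_rejects_empty():
    with pytest.raises(ValueError):
        evaluate(np.array([]), np.array([0.5]))


# ---------------------------------------------------------------------------
# suitability model behaviour
# ---------------------------------------------------------------------------

def test_suitability_tracks_planted_gradient(world):
    from scipy.stats import spearmanr
    res = fit_suitability(world.occurrences, world.climate_current, seed=0)
    assert res.auc > 0.7
    v = res.map.grid.values
    b19 = world.climate_current["bio19"].values
    ok = ~np.isnan(v)
    rho = spearmanr(v[ok], b19[ok]).statistic
    assert rho > 0.6          # suitability rises with the planted driver
    # nested threshold masks
    assert res.map.mask(0.70).sum() <= res.map.mask(0.15).sum()
    assert (res.map.mask(0.70) & ~res.map.mask(0.15)).sum() == 0


def test_suitability_null_occurrences_auc_near_half(cfg, climate):
    aucs = []
    for seed in range(8):
        r = np.random.default_rng(seed)
        occ = pd.DataFrame({
            "lon": r.uniform(climate.ref.west, climate.ref.east, 80),
            "lat": r.uniform(climate.ref.south, climate.ref.north, 80)})
        res = fit_suitability(occ, climate, seed=seed)
        aucs.append(res.auc)
    assert abs(np.mean(aucs) - 0.5) < 0.1


def test_suitability_perfectly_separable_toy(cfg, climate):
    """Occurrences exclusively in the warmest cells: held-out evaluation is
    (near-)perfect."""
    b1 = climate["bio1"].values
    cut = np.nanquantile(b1, 0.9)
    rows, cols = np.where(b1 > cut)
    g = climate.ref
    occ = pd.DataFrame({"lon": g.west + (cols + 0.5) * g.dx,
                        "lat": g.north - (rows + 0.5) * g.dy})
    res = fit_suitability(occ, climate, seed=1, variables=["bio1"])
    assert res.auc > 0.95
    assert res.tss > 0.8


def test_fit_rejects_degenerate_occurrences(climate):
    g = climate.ref
    occ = pd.DataFrame({"lon": [g.west + 0.05] * 20, "lat": [g.south + 0.05] * 20})
    with pytest.raises(ValueError):
        fit_suitability(occ, climate, seed=0)


# ---------------------------------------------------------------------------
# ensembles, areas, altitude
# ---------------------------------------------------------------------------

def _smap(values, **kw):
    return SuitabilityMap(_grid(values, **kw))


def test_ensemble_mean_elementwise_and_nodata():
    a = _smap([[0.0, 1.0], [0.5, np.nan]])
    b = _smap([[1.0, 1.0], [0.5, 0.2]])
    out = ensemble_mean([a, b])
    np.testing.assert_allclose(out.grid.values[0], [0.5, 1.0])
    assert np.isnan(out.grid.values[1, 1])          # NODATA propagates
    perm = ensemble_mean([b, a])
    np.testing.assert_array_equal(out.grid.values, perm.grid.values,
                                  err_msg="ensemble must be order-invariant")


def test_threshold_area_constructed_raster():
    # ten cells above threshold, each of known equirectangular area
    v = np.zeros((3, 5))
    v.ravel()[:10] = 0.9
    m = _smap(v, west=0.0, south=0.0)
    g = m.grid
    lat0 = np.deg2rad(g.lat_centers())
    expected = sum((111.32 * np.cos(lat0[i]) * 0.1) * (110.57 * 0.1)
                   for i in (0, 0, 0, 0, 0, 1, 1, 1, 1, 1))
    assert threshold_area(m, 0.15) == pytest.approx(expected)
    assert threshold_area(m, 0.95) == 0.0
    # monotone non-increasing in the threshold
    areas = [threshold_area(m, t) for t in (0.1, 0.5, 0.91)]
    assert areas[0] >= areas[1] >= areas[2]


def test_area_change_signed():
    assert area_change(85602, 79935) == 5667
    assert area_change(5.0, 5.0) == 0.0
    with pytest.raises(ValueError):
        area_change(-1.0, 3.0)


def test_altitudinal_stats_single_cell_and_empty():
    suit = _smap([[0.9, 0.0], [0.0, 0.0]])
    dem = _grid([[812.0, 100.0], [200.0, 300.0]])
    st = altitudinal_stats(suit, dem, 0.15)
    assert (st.min, st.mean, st.max) == (812.0, 812.0, 812.0)
    empty = altitudinal_stats(_smap(np.zeros((2, 2))), dem, 0.15)
    assert empty.empty and np.isnan(empty.mean)


def test_altitudinal_shift_equals_planted_offset(world):
    res = fit_suitability(world.occurrences, world.climate_current, seed=0)
    up = world.dem.like(world.dem.values + 250.0)
    a = altitudinal_stats(res.map, world.dem, 0.15)
    b = altitudinal_stats(res.map, up, 0.15)
    assert b.mean - a.mean == pytest.approx(250.0)


# ---------------------------------------------------------------------------
# terrain ruggedness
# ---------------------------------------------------------------------------

def test_tri_flat_zero():
    tri = compute_tri(_grid(np.full((4, 4), 57.0)))
    np.testing.assert_allclose(tri.values, 0.0)


def test_tri_ramp_closed_form():
    """Uniform ramp of s per cell along columns: interior TRI =
    (6*s + 2*2*s)/8 ... = mean(|diff|) over the 8 neighbours = (6s+4s)/8? —
    computed here exactly: neighbours differ by s (4 of them: E,W scaled),
    actually per the 8-neighbourhood: 3 cells at -s, 3 at +s, 2 at 0 ->
    mean |diff| = 6s/8."""
    s = 10.0
    v = np.tile(np.arange(6) * s, (5, 1))
    tri = compute_tri(_grid(v))
    np.testing.assert_allclose(tri.values[1:-1, 1:-1], 6 * s / 8)


def test_tri_checkerboard_enumeration():
    h = 5.0
    v = np.indices((6, 6)).sum(axis=0) % 2 * (2 * h) - h
    tri = compute_tri(_grid(v))
    # oracle: direct per-cell enumeration of the available neighbours
    z = v.astype(float)
    for i in (2, 3):
        for j in (2, 3):
            diffs = [abs(z[i + di, j + dj] - z[i, j])
                     for di in (-1, 0, 1) for dj in (-1, 0, 1)
                     if (di, dj) != (0, 0)]
            assert tri.values[i, j] == pytest.approx(np.mean(diffs))


def test_tri_nodata_propagates():
    v = np.full((4, 4), 10.0)
    v[1, 1] = np.nan
    tri = compute_tri(_grid(v))
    assert np.isnan(tri.values[1, 1])
    assert np.isfinite(tri.values[0, 0])


# ---------------------------------------------------------------------------
# climate PCA
# ---------------------------------------------------------------------------

def test_climate_pca_perfect_correlation():
    x = np.arange(10.0)
    tab = pd.DataFrame({"a": x, "b": 3 * x + 1})
    out = climate_pca(tab)
    assert out["variance_fraction"]["PC1"] == pytest.approx(1.0)


def test_climate_pca_matches_eigen_oracle():
    tab = pd.DataFrame({"a": [1.0, 4.0, 2.0], "b": [0.5, 0.2, 0.9]})
    out = climate_pca(tab)
    Z = (tab - tab.mean()) / tab.std(ddof=0)
    lam, V = np.linalg.eigh(Z.T @ Z)
    lam = np.sort(lam)[::-1]
    np.testing.assert_allclose(out["variance_fraction"].to_numpy(),
                               lam / lam.sum(), atol=1e-9)


def test_climate_pca_isotropic_noise_fractions(rng):
    tab = pd.DataFrame(rng.normal(size=(400, 5)), columns=list("abcde"))
    out = climate_pca(tab)
    np.testing.assert_allclose(out["variance_fraction"].to_numpy(), 0.2,
                               atol=0.05)
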
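"""Niche-model stage: collinearity filtering, a maxent-style suitability
model, evaluation, ensemble averaging, threshold-area and altitude
accounting, terrain ruggedness, and the climate-space PCA.

The suitability model is a presence-versus-background exponential-family
model with linear, quadratic and pairwise-product features and L1
regularization, fitted as a logistic discrimination against a random
background sample — the standard "maxnet" formulation of maximum-entropy
niche modelling.  It is written statsmodels-style: :class:`MaxentModel` is
built from occurrence points and a climate stack; ``fit()`` returns a
:class:`MaxentResults` with the suitability raster, AUC/TSS evaluation and
feature coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .containers import ClimateStack, RasterGrid, SuitabilityMap

__all__ = ["vif_filter", "MaxentModel", "MaxentResults", "fit_suitability",
           "evaluate", "ensemble_mean", "threshold_area", "area_change",
           "altitudinal_stats", "AltitudeStats", "compute_tri", "climate_pca"]

#: the eight low-collinearity bioclimatic predictors retained in the study
#: region (annual mean temperature, isothermality, temperature seasonality,
#: wettest/driest-quarter temperatures, precipitation seasonality,
#: warmest/coldest-quarter precipitation)
DEFAULT_SDM_VARIABLES = ["bio1", "bio3", "bio4", "bio8", "bio9",
                         "bio15", "bio18", "bio19"]


# ---------------------------------------------------------------------------
# VIF stepwise filter
# ---------------------------------------------------------------------------

def vif_filter(table: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[list[str], pd.DataFrame]:
    """Stepwise exclusion of collinear variables.

    Iteratively drops the single variable with the largest variance
    inflation factor while that VIF exceeds ``threshold``, recomputing after
    each drop.  Exactly collinear variables (infinite VIF) are dropped
    first; ties break by column-label order.  Returns the retained names
    and a drop log (variable, VIF at drop time).
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 variables")
    if table.shape[0] < table.shape[1] + 1:
        raise ValueError("need more rows than variables")
    cols = list(table.columns)
    log_rows = []
    while len(cols) > 1:
        X = table[cols].to_numpy(dtype=float)
        X = (X - X.mean(axis=0)) / X.std(axis=0)
        Xc = np.column_stack([np.ones(len(X)), X])
        with np.errstate(divide="ignore", invalid="ignore"):
            vifs = np.array([variance_inflation_factor(Xc, j + 1)
                             for j in range(len(cols))])
        vifs = np.where(np.isnan(vifs), np.inf, vifs)
        worst = float(np.max(vifs))
        if worst <= threshold:
            break
        # deterministic tie-break: smallest label among the arg-maxima
        at_max = [c for c, v in zip(cols, vifs) if v == worst]
        drop = sorted(at_max)[0]
        log_rows.append({"dropped": drop, "vif": worst})
        cols.remove(drop)
    return cols, pd.DataFrame(log_rows, columns=["dropped", "vif"])


# ---------------------------------------------------------------------------
# maxent-style suitability model
# ---------------------------------------------------------------------------

def _features(z: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    """Linear + quadratic + pairwise-product feature expansion."""
    cols = [z]
    labels = list(names)
    cols.append(z ** 2)
    labels += [f"{n}^2" for n in names]
    prods = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            prods.append(z[:, i] * z[:, j])
            labels.append(f"{names[i]}*{names[j]}")
    if prods:
        cols.append(np.column_stack(prods))
    return np.column_stack(cols), labels


class MaxentModel:
    """Presence-background suitability model on a climate stack.

    Parameters
    ----------
    occurrences
        DataFrame with ``lon``/``lat`` columns; duplicate points within one
        raster cell are collapsed before modelling.
    stack
        Co-registered climate stack to fit and project on.
    variables
        Predictor layer names (default: the eight low-collinearity
        bioclimatic variables).
    bg_n
        Maximum number of random background cells (default 10,000).
    reg
        Regularization multiplier scaling the L1 penalty (default 1).
    """

    def __init__(self, occurrences: pd.DataFrame, stack: ClimateStack,
                 variables: list[str] | None = None, bg_n: int = 10000,
                 reg: float = 1.0, test_fraction: float = 0.2):
        self.variables = list(variables) if variables else [
            v for v in DEFAULT_SDM_VARIABLES if v in stack.names]
        self.stack = stack
        self.bg_n = bg_n
        self.reg = reg
        self.test_fraction = test_fraction
        grid = stack.ref
        cells = {grid.cell_index(lo, la)
                 for lo, la in zip(occurrences["lon"], occurrences["lat"])}
        self.presence_cells = sorted(cells)
        if len(self.presence_cells) < 10:
            raise ValueError("need >= 10 distinct occurrence cells")

    def _cell_values(self, cells: list[tuple[int, int]]) -> np.ndarray:
        rows = np.array([c[0] for c in cells])
        cols = np.array([c[1] for c in cells])
        return np.column_stack([self.stack[v].values[rows, cols]
                                for v in self.variables])

    def fit(self, seed: int = 0) -> "MaxentResults":
        rng = np.random.default_rng(seed)
        grid = self.stack.ref
        layer_stack = np.stack([self.stack[v].values for v in self.variables])
        valid = ~np.isnan(layer_stack).any(axis=0)
        valid_idx = np.flatnonzero(valid.ravel())
        if len(valid_idx) == 0:
            raise ValueError("no valid cells in the stack")
        bg_idx = rng.choice(valid_idx, size=min(self.bg_n, len(valid_idx)),
                            replace=False)
        bg_rows, bg_cols = np.unravel_index(bg_idx, valid.shape)
        bg_X = layer_stack[:, bg_rows, bg_cols].T

        pres = [c for c in self.presence_cells
                if not np.isnan(layer_stack[:, c[0], c[1]]).any()]
        if len(pres) < 10:
            raise ValueError("fewer than 10 occurrence cells with climate data")
        pres_X = self._cell_values(pres)
        if np.allclose(pres_X.std(axis=0), 0.0):
            raise ValueError("degenerate occurrences: all in identical climate")

        # train/test split of presences (random test partition per seed)
        n_test = max(1, int(round(self.test_fraction * len(pres))))
        perm = rng.permutation(len(pres))
        test_i, train_i = perm[:n_test], perm[n_test:]

        mu, sd = bg_X.mean(axis=0), bg_X.std(axis=0)
        sd[sd == 0] = 1.0

        def _feat(X: np.ndarray) -> np.ndarray:
            return _features((X - mu) / sd, self.variables)[0]

        F_train = np.vstack([_feat(pres_X[train_i]), _feat(bg_X)])
        y = np.concatenate([np.ones(len(train_i)), np.zeros(len(bg_X))])
        clf = LogisticRegression(solver="liblinear", l1_ratio=1.0,
                                 C=1.0 / max(self.reg, 1e-6), max_iter=2000,
                                 random_state=0)
        clf.fit(F_train, y)
        # calibrate the logistic output so a typical training presence maps
        # to suitability 0.5 (the MaxEnt logistic-output convention); the
        # shift is monotone, so AUC/TSS are unaffected
        shift = float(np.median(clf.decision_function(_feat(pres_X[train_i]))))

        from scipy.special import expit

        def _suit(F: np.ndarray) -> np.ndarray:
            return expit(clf.decision_function(F) - shift)

        # project over the whole grid
        full = layer_stack.reshape(len(self.variables), -1).T
        suit = np.full(full.shape[0], np.nan)
        suit[valid_idx] = _suit(_feat(full[valid_idx]))
        suit_grid = grid.like(suit.reshape(valid.shape), "suitability")

        # evaluation on the held-out presences vs an independent background
        test_scores = _suit(_feat(pres_X[test_i]))
        eval_bg_idx = rng.choice(valid_idx,
                                 size=min(2000, len(valid_idx)), replace=False)
        er, ec = np.unravel_index(eval_bg_idx, valid.shape)
        bg_scores = _suit(_feat(layer_stack[:, er, ec].T))
        auc, tss = evaluate(test_scores, bg_scores)

        _, feat_names = _features(np.zeros((1, len(self.variables))),
                                  self.variables)
        coef = pd.Series(clf.coef_[0], index=feat_names)
        smap = SuitabilityMap(suit_grid, auc=auc, tss=tss)
        return MaxentResults(model=self, map=smap, auc=auc, tss=tss,
                             coefficients=coef,
                             intercept=float(clf.intercept_[0]),
                             n_train=len(train_i), n_test=len(test_i),
                             standardization=(mu, sd), _clf=clf,
                             _shift=shift)


@dataclass
class MaxentResults:
    """Fitted suitability model: raster, evaluation and coefficients."""

    model: MaxentModel
    map: SuitabilityMap
    auc: float
    tss: float
    coefficients: pd.Series
    intercept: float
    n_train: int
    n_test: int
    standardization: tuple[np.ndarray, np.ndarray]
    _clf: LogisticRegression
    _shift: float = 0.0

    def project(self, stack: ClimateStack) -> SuitabilityMap:
        """Project the fitted model onto another (e.g. future) stack."""
        mu, sd = self.standardization
        layer_stack = np.stack([stack[v].values
                                for v in self.model.variables])
        valid = ~np.isnan(layer_stack).any(axis=0)
        full = layer_stack.reshape(len(self.model.variables), -1).T
        idx = np.flatnonzero(valid.ravel())
        from scipy.special import expit
        F = _features((full[idx] - mu) / sd, self.model.variables)[0]
        suit = np.full(full.shape[0], np.nan)
        suit[idx] = expit(self._clf.decision_function(F) - self._shift)
        return SuitabilityMap(stack.ref.like(suit.reshape(valid.shape),
                                             "suitability"),
                              auc=self.auc, tss=self.tss)

    def summary(self) -> str:
        nz = self.coefficients[self.coefficients != 0]
        return (f"maxent-style suitability model "
                f"({len(self.model.variables)} variables, "
                f"{self.n_train} train / {self.n_test} test presences)\n"
                f"  AUC={self.auc:.3f}  TSS={self.tss:.3f}  "
                f"non-zero features: {len(nz)}/{len(self.coefficients)}")


def fit_suitability(occ: pd.DataFrame, stack: ClimateStack,
                    bg_n: int = 10000, reg: float = 1.0, seed: int = 0,
                    variables: list[str] | None = None) -> MaxentResults:
    """Convenience wrapper: build and fit a :class:`MaxentModel`."""
    return MaxentModel(occ, stack, variables=variables, bg_n=bg_n,
                       reg=reg).fit(seed=seed)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def evaluate(presence_scores: np.ndarray, background_scores: np.ndarray
             ) -> tuple[float, float]:
    """AUC (rank statistic, presence vs background) and TSS (max over
    thresholds of sensitivity + specificity - 1)."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both test sets must be non-empty")
    from scipy.stats import rankdata
    ranks = rankdata(np.concatenate([p, b]))
    auc = (ranks[:len(p)].sum() - len(p) * (len(p) + 1) / 2) / (len(p) * len(b))
    thresholds = np.unique(np.concatenate([p, b]))
    best = 0.0
    for t in thresholds:
        sens = float((p >= t).mean())
        spec = float((b < t).mean())
        best = max(best, sens + spec - 1.0)
    return float(auc), float(best)


# ---------------------------------------------------------------------------
# ensembles, areas, altitudes
# ---------------------------------------------------------------------------

def ensemble_mean(maps: list[SuitabilityMap]) -> SuitabilityMap:
    """Cellwise arithmetic mean; any NODATA input cell is NODATA out."""
    if not maps:
        raise ValueError("empty ensemble")
    ref = maps[0].grid
    for m in maps[1:]:
        if not ref.co_registered(m.grid):
            raise ValueError("ensemble maps are not co-registered")
    stacked = np.stack([m.grid.values for m in maps])
    mean = stacked.mean(axis=0)          # nan propagates
    return SuitabilityMap(ref.like(mean, "suitability"),
                          auc=float(np.mean([m.auc for m in maps])),
                          tss=float(np.mean([m.tss for m in maps])))


def threshold_area(smap: SuitabilityMap, thr: float) -> float:
    """Total area (km^2) of cells with suitability >= thr
    (cosine-latitude-corrected cell areas)."""
    if not 0.0 < thr < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    mask = smap.mask(thr)
    return float(smap.grid.cell_areas_km2()[mask].sum())


def area_change(future_area: float, current_area: float) -> float:
    """Signed km^2 change, future minus current."""
    if future_area < 0 or current_area < 0:
        raise ValueError("areas must be non-negative")
    return future_area - current_area


@dataclass
class AltitudeStats:
    n_cells: int
    min: float
    mean: float
    max: float

    @property
    def empty(self) -> bool:
        return self.n_cells == 0


def altitudinal_stats(smap: SuitabilityMap, dem: RasterGrid,
                      thr: float = 0.15) -> AltitudeStats:
    """Order statistics of elevation over the suitable mask.

    An empty mask returns an explicit empty record (``n_cells = 0``,
    NaN statistics), never zeros.
    """
    if not smap.grid.co_registered(dem):
        raise ValueError("DEM is not co-registered with the suitability map")
    mask = smap.mask(thr) & ~np.isnan(dem.values)
    vals = dem.values[mask]
    if len(vals) == 0:
        return AltitudeStats(0, float("nan"), float("nan"), float("nan"))
    return AltitudeStats(int(len(vals)), float(vals.min()),
                         float(vals.mean()), float(vals.max()))


# ---------------------------------------------------------------------------
# terrain ruggedness
# ---------------------------------------------------------------------------

def compute_tri(dem: RasterGrid) -> RasterGrid:
    """Terrain ruggedness index: mean |elevation difference| to the
    available 8 neighbours (Riley); edges use the neighbours that exist,
    NODATA neighbours are excluded and NODATA cells stay NODATA."""
    z = dem.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    acc = np.zeros_like(z)
    cnt = np.zeros_like(z)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            shifted = np.full_like(z, np.nan)
            src = (slice(max(di, 0), z.shape[0] + min(di, 0)),
                   slice(max(dj, 0), z.shape[1] + min(dj, 0)))
            dst = (slice(max(-di, 0), z.shape[0] + min(-di, 0)),
                   slice(max(-dj, 0), z.shape[1] + min(-dj, 0)))
            shifted[dst] = z[src]
            diff = np.abs(shifted - z)
            ok = ~np.isnan(diff)
            acc[ok] += diff[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        tri = acc / cnt
    tri[np.isnan(z)] = np.nan
    return dem.like(tri, "m")


# ---------------------------------------------------------------------------
# climate-space PCA and ecoplot tables
# ---------------------------------------------------------------------------

def climate_pca(table: pd.DataFrame) -> dict:
    """Centered-and-scaled PCA of a populations x bioclim table.

    Returns scores, loadings and per-axis variance fractions; feed the
    scores to a biplot and use :func:`ecoplot_table` for the
    precipitation/aridity scatter tables.
    """
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(table.columns[sd == 0])
        raise ValueError(f"constant columns: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2
    frac = var / var.sum()
    # sign convention: largest-|loading| entry of each axis positive
    for c in range(Vt.shape[0]):
        if Vt[c, np.argmax(np.abs(Vt[c]))] < 0:
            Vt[c] = -Vt[c]
            U[:, c] = -U[:, c]
    axes = [f"PC{i + 1}" for i in range(len(s))]
    return {
        "scores": pd.DataFrame(U * s, index=table.index, columns=axes),
        "loadings": pd.DataFrame(Vt.T, index=table.columns, columns=axes),
        "variance_fraction": pd.Series(frac, index=axes),
    }


def ecoplot_table(table: pd.DataFrame, x: str = "bio18", y: str = "bio19",
                  group: pd.Series | None = None) -> pd.DataFrame:
    """Two-variable climate-envelope table (e.g. bio18 vs bio19, or the
    aridity vs moisture indices) for plotting."""
    out = table[[x, y]].copy()
    if group is not None:
        out["group"] = group.loc[out.index].to_numpy()
    return out
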
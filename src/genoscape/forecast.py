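"""Ancestry-under-climate forecasting.

Relates population ancestry coefficients (a STRUCTURE-style Q matrix at
fixed K) to climate covariates through a multinomial-logit (softmax)
regression against the fractional memberships, then projects cluster
membership onto current and future climate grids restricted to the
species' suitable range, and summarizes which genetic clusters persist,
shrink or disappear under each scenario.

The fit is deterministic: cross-entropy against fractional targets with a
small L2 ridge for identifiability, optimized by L-BFGS from a zero
initialization.  Written statsmodels-style (:class:`AncestryClimateModel`
-> ``fit()`` -> :class:`AncestryClimateResults`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import softmax

from .containers import AncestryMatrix, ClimateStack, RasterGrid, SuitabilityMap

__all__ = ["AncestryClimateModel", "AncestryClimateResults",
           "fit_ancestry_climate", "project_ancestry", "cluster_persistence",
           "DEFAULT_COVARIATES"]

#: the four bioclimatic variables with the highest SDM contribution
DEFAULT_COVARIATES = ("bio1", "bio3", "bio18", "bio19")


class AncestryClimateModel:
    """Softmax regression of a Q matrix on climate covariates.

    Parameters
    ----------
    q
        Ancestry matrix (rows: populations, columns: K clusters).
    covariates
        Population x covariate table aligned to ``q.labels``; standardized
        internally (the standardization is reused at projection time).
    ridge
        L2 penalty weight for identifiability (default 1e-3).
    """

    def __init__(self, q: AncestryMatrix, covariates: pd.DataFrame,
                 ridge: float = 1e-3):
        if q.K < 2:
            raise ValueError("need K >= 2 clusters")
        if list(covariates.index) != list(q.labels):
            covariates = covariates.loc[q.labels]
        X = covariates.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("covariates contain non-finite values")
        n, p = X.shape
        if p >= n:
            raise ValueError("need fewer covariates than populations")
        self.q = q
        self.cov_names = list(covariates.columns)
        self.mu = X.mean(axis=0)
        self.sd = X.std(axis=0)
        self.sd[self.sd == 0] = 1.0
        self.Z = (X - self.mu) / self.sd
        self.ridge = ridge

    def fit(self) -> "AncestryClimateResults":
        n, p = self.Z.shape
        K = self.q.K
        Q = self.q.Q
        Z1 = np.column_stack([np.ones(n), self.Z])

        def loss(w: np.ndarray) -> tuple[float, np.ndarray]:
            W = w.reshape(K, p + 1)
            P = softmax(Z1 @ W.T, axis=1)
            ce = -np.sum(Q * np.log(np.clip(P, 1e-12, None))) / n
            pen = self.ridge * np.sum(W[:, 1:] ** 2)
            grad = ((P - Q).T @ Z1) / n
            grad[:, 1:] += 2 * self.ridge * W[:, 1:]
            return ce + pen, grad.ravel()

        res = minimize(loss, np.zeros(K * (p + 1)), jac=True, method="L-BFGS-B",
                       options={"maxiter": 2000, "ftol": 1e-12, "gtol": 1e-10})
        W = res.x.reshape(K, p + 1)
        # identifiability: center coefficients across clusters (softmax is
        # invariant to per-column shifts)
        W = W - W.mean(axis=0, keepdims=True)
        P = softmax(Z1 @ W.T, axis=1)
        ce = float(-np.sum(Q * np.log(np.clip(P, 1e-12, None))) / n)
        coef = pd.DataFrame(W, index=[f"cluster{k + 1}" for k in range(K)],
                            columns=["intercept"] + self.cov_names)
        return AncestryClimateResults(model=self, coefficients=coef,
                                      cross_entropy=ce,
                                      fitted=pd.DataFrame(
                                          P, index=self.q.labels,
                                          columns=coef.index))


@dataclass
class AncestryClimateResults:
    """Fitted ancestry~climate softmax model."""

    model: AncestryClimateModel
    coefficients: pd.DataFrame           # K x (1 + p)
    cross_entropy: float
    fitted: pd.DataFrame                 # n x K predicted memberships

    @property
    def K(self) -> int:
        return len(self.coefficients)

    def null_cross_entropy(self) -> float:
        """Cross-entropy of the intercept-only (mean-membership) model."""
        Q = self.model.q.Q
        pbar = Q.mean(axis=0)
        return float(-np.sum(Q * np.log(np.clip(pbar, 1e-12, None))) / len(Q))

    def predict_grid(self, stack: ClimateStack) -> np.ndarray:
        """Per-cell membership probabilities, shape (K, nrow, ncol)."""
        names = self.model.cov_names
        layers = np.stack([stack[v].values for v in names])
        valid = ~np.isnan(layers).any(axis=0)
        X = layers.reshape(len(names), -1).T
        Z = (X - self.model.mu) / self.model.sd
        W = self.coefficients.to_numpy()
        logits = np.column_stack([np.ones(len(Z)), Z]) @ W.T
        P = softmax(logits, axis=1).T.reshape(self.K, *valid.shape)
        P[:, ~valid] = np.nan
        return P

    def summary(self) -> str:
        lines = [f"ancestry ~ climate softmax (K={self.K}, "
                 f"covariates: {', '.join(self.model.cov_names)})",
                 f"  cross-entropy: fit={self.cross_entropy:.4f}  "
                 f"null={self.null_cross_entropy():.4f}"]
        return "\n".join(lines)


def fit_ancestry_climate(q: AncestryMatrix, covariates: pd.DataFrame,
                         ridge: float = 1e-3) -> AncestryClimateResults:
    """Convenience wrapper: build and fit an :class:`AncestryClimateModel`."""
    return AncestryClimateModel(q, covariates, ridge=ridge).fit()


def project_ancestry(results: AncestryClimateResults, stack: ClimateStack,
                     mask: SuitabilityMap | None = None,
                     threshold: float = 0.15) -> RasterGrid:
    """Hard cluster-membership map (argmax of the projected softmax).

    Cells outside the suitability mask (suitability < ``threshold``) or
    with missing climate are NODATA.  Cluster labels are 1-based.
    """
    P = results.predict_grid(stack)
    with np.errstate(invalid="ignore"):
        hard = np.argmax(P, axis=0).astype(float) + 1.0
    invalid = np.isnan(P).any(axis=0)
    if mask is not None:
        if not mask.grid.co_registered(stack.ref):
            raise ValueError("mask is not co-registered with the stack")
        invalid |= ~mask.mask(threshold)
    hard[invalid] = np.nan
    return stack.ref.like(hard, "cluster")


def project_ancestry_ensemble(results: AncestryClimateResults,
                              stacks: list[ClimateStack],
                              mask: SuitabilityMap | None = None,
                              threshold: float = 0.15) -> RasterGrid:
    """Cluster map from membership probabilities averaged cellwise across
    GCM stacks before the argmax."""
    Ps = [results.predict_grid(s) for s in stacks]
    P = np.mean(Ps, axis=0)
    hard = np.argmax(P, axis=0).astype(float) + 1.0
    invalid = np.isnan(P).any(axis=0)
    if mask is not None:
        invalid |= ~mask.mask(threshold)
    hard[invalid] = np.nan
    return stacks[0].ref.like(hard, "cluster")


def cluster_persistence(current: RasterGrid, future: RasterGrid,
                        K: int | None = None) -> pd.DataFrame:
    """Per-cluster persistence report between two hard cluster maps.

    A cluster is *lost* when its future cell count is zero.  The report
    carries current/future cell counts and areas (km^2) per cluster; the
    Shannon entropies of the cluster area shares (a homogenization index:
    lower future entropy = more homogeneous genetic landscape) are in
    ``.attrs["entropy_current"]`` / ``.attrs["entropy_future"]``.
    """
    if not current.co_registered(future):
        raise ValueError("maps are not co-registered")
    areas = current.cell_areas_km2()
    labels_present = np.unique(np.concatenate([
        current.values[~np.isnan(current.values)],
        future.values[~np.isnan(future.values)]]))
    ks = (np.arange(1, K + 1, dtype=float) if K is not None
          else labels_present)
    rows = []
    for k in ks:
        cur_mask = current.values == k
        fut_mask = future.values == k
        rows.append({
            "cluster": int(k),
            "cells_current": int(cur_mask.sum()),
            "cells_future": int(fut_mask.sum()),
            "area_current_km2": float(areas[cur_mask].sum()),
            "area_future_km2": float(areas[fut_mask].sum()),
            "status": "lost" if fut_mask.sum() == 0 else "retained",
        })
    out = pd.DataFrame(rows)

    def _entropy(a: np.ndarray) -> float:
        tot = a.sum()
        if tot <= 0:
            return float("nan")
        s = a[a > 0] / tot
        return float(-(s * np.log(s)).sum())

    out.attrs["entropy_current"] = _entropy(out["area_current_km2"].to_numpy())
    out.attrs["entropy_future"] = _entropy(out["area_future_km2"].to_numpy())
    return out
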
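"""Landscape-genetics battery.

Distance-based redundancy analysis (dbRDA) of a linearized-F_ST response on
standardized predictor blocks, with the partial (conditioned) forms needed
to decompose among-population differentiation into pure and confounded
contributions of climate (isolation-by-environment), geography
(isolation-by-distance), orography (isolation-by-resistance) and ancestry
(isolation-by-colonization).  Also: PCNM spatial/structural eigenvectors,
permutation-based forward selection of predictors, and the
variance-partition table.

The ordination is written statsmodels-style: :class:`DBRDA` is the model,
``fit()`` returns a :class:`DBRDAResults` carrying R2, adjusted R2, the
pseudo-F, the permutation p-value and axis scores, with a ``summary()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree

from .containers import DistMatrix

__all__ = ["DBRDA", "DBRDAResults", "dbrda", "pcnm", "forward_select",
           "variance_partition", "permutation_anova", "PredictorSet",
           "standardize"]

_EIG_TOL = 1e-8


def standardize(df: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores (population sd); constant columns are rejected."""
    sd = df.std(ddof=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant columns cannot be standardized: {bad}")
    return (df - df.mean()) / sd


@dataclass
class PredictorSet:
    """Named blocks of standardized predictor columns aligned to a label set."""

    labels: list[str]
    blocks: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for name, df in self.blocks.items():
            if list(df.index) != list(self.labels):
                raise ValueError(f"block {name!r} rows not aligned to labels")
            mu = df.mean().abs().max()
            sd = (df.std(ddof=0) - 1.0).abs().max()
            if mu > 1e-9 or sd > 1e-6:
                raise ValueError(f"block {name!r} is not standardized")

    def combined(self, names: list[str] | None = None) -> pd.DataFrame:
        names = names if names is not None else list(self.blocks)
        return pd.concat([self.blocks[n] for n in names], axis=1)


# ---------------------------------------------------------------------------
# core linear algebra
# ---------------------------------------------------------------------------

def _gower_center(D: np.ndarray) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (D ** 2) @ J


def _pcoa(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal coordinates of a Gower-centered matrix.

    Returns (coords, eigenvalues) keeping positive eigenvalues only, in
    descending order; total inertia is ``eigenvalues.sum()``.
    """
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    keep = lam > max(lam.max(), 0.0) * _EIG_TOL if lam.size else lam > 0
    lam, U = lam[keep], U[:, keep]
    return U * np.sqrt(lam), lam


def _drop_aliased(X: np.ndarray, names: list[str],
                  scale: float | None = None) -> tuple[np.ndarray, list[str]]:
    """Greedily drop columns that do not increase the matrix rank.

    ``scale`` sets an absolute rank tolerance (e.g. the norm of the
    pre-residualization columns) so that columns annihilated by
    conditioning count as aliased."""
    tol = None if scale is None else scale * 1e-9
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = keep + [j]
        if np.linalg.matrix_rank(X[:, cand], tol=tol) == len(cand):
            keep.append(j)
    if len(keep) < X.shape[1]:
        dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
        warnings.warn(f"dropping aliased predictor columns: {dropped}",
                      RuntimeWarning, stacklevel=3)
    return X[:, keep], [names[j] for j in keep]


def _proj(X: np.ndarray) -> np.ndarray:
    """Orthogonal projector onto the column space of X."""
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0]))
    Q, _ = np.linalg.qr(X)
    return Q @ Q.T


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

class DBRDA:
    """Distance-based redundancy analysis model.

    Parameters
    ----------
    response
        Symmetric dissimilarity matrix (typically linearized F_ST).
    X
        Constraining predictors, indexed by the response labels.
    Z
        Optional conditioning predictors (partialled out of both the
        response principal coordinates and X before constraining).
    """

    def __init__(self, response: DistMatrix, X: pd.DataFrame,
                 Z: pd.DataFrame | None = None):
        if X.shape[1] < 1:
            raise ValueError("X needs at least one column")
        labels = list(response.labels)
        if list(X.index) != labels:
            X = X.loc[labels]
        if Z is not None and Z.shape[1] == 0:
            Z = None
        if Z is not None and list(Z.index) != labels:
            Z = Z.loc[labels]
        self.response = response
        self.labels = labels
        n = len(labels)

        G = _gower_center(response.values)
        self.Y, self.eigenvalues = _pcoa(G)
        self.total_inertia = float(self.eigenvalues.sum())
        if self.total_inertia <= 0:
            raise ValueError("response matrix has no positive inertia")

        Xc = X.to_numpy(dtype=float) - X.to_numpy(dtype=float).mean(axis=0)
        Xc, self.x_names = _drop_aliased(Xc, list(X.columns))
        if Z is not None:
            Zc = Z.to_numpy(dtype=float) - Z.to_numpy(dtype=float).mean(axis=0)
            Zc, self.z_names = _drop_aliased(Zc, list(Z.columns))
        else:
            Zc, self.z_names = np.empty((n, 0)), []

        self.Hz = _proj(Zc)
        self.Yr = self.Y - self.Hz @ self.Y
        x_scale = float(np.linalg.norm(Xc, axis=0).max()) if Xc.size else 1.0
        Xr = Xc - self.Hz @ Xc
        Xr, kept = _drop_aliased(Xr, self.x_names, scale=max(x_scale, 1e-12))
        self.x_names = kept
        self.Xr = Xr
        self.H = _proj(Xr)
        self.q = Zc.shape[1]
        self.m = Xr.shape[1]
        if self.m == 0:
            raise ValueError("all constraining columns are aliased by the "
                             "conditioning set")
        if n <= self.m + self.q + 1:
            raise ValueError("too few rows for the requested model rank")

    # -- fitting -----------------------------------------------------------

    def fit(self, nperm: int = 0, seed: int | None = 0) -> "DBRDAResults":
        n = len(self.labels)
        total = self.total_inertia
        fitted = self.H @ self.Yr
        ss_fit = float((fitted ** 2).sum())
        ss_cond = float(((self.Hz @ self.Y) ** 2).sum())
        ss_res = total - ss_cond - ss_fit
        R2 = ss_fit / total
        df_res = n - 1 - self.m - self.q
        if ss_res <= total * 1e-12:
            F = np.inf
        else:
            F = (ss_fit / self.m) / (ss_res / df_res)

        if self.q == 0:
            adjR2 = 1.0 - (1.0 - R2) * (n - 1) / df_res
        else:
            # semipartial adjustment: adj(X u Z) - adj(Z)  (Ezekiel both)
            R2_xz = (ss_fit + ss_cond) / total
            R2_z = ss_cond / total
            adj_xz = 1.0 - (1.0 - R2_xz) * (n - 1) / (n - 1 - self.m - self.q)
            adj_z = 1.0 - (1.0 - R2_z) * (n - 1) / (n - 1 - self.q)
            adjR2 = adj_xz - adj_z

        # constrained axis scores (site scores from the fitted matrix SVD)
        Us, ss, Vt = np.linalg.svd(fitted, full_matrices=False)
        n_axes = int((ss > ss.max() * 1e-9).sum()) if ss.size and ss.max() > 0 else 0
        site_scores = pd.DataFrame(
            (Us[:, :n_axes] * ss[:n_axes]), index=self.labels,
            columns=[f"CAP{i + 1}" for i in range(n_axes)])
        # biplot scores: correlations of constraints with the site scores
        bip = np.zeros((self.m, n_axes))
        for j in range(self.m):
            for a in range(n_axes):
                sc = site_scores.iloc[:, a].to_numpy()
                if sc.std() > 0 and self.Xr[:, j].std() > 0:
                    bip[j, a] = np.corrcoef(self.Xr[:, j], sc)[0, 1]
        biplot_scores = pd.DataFrame(
            bip, index=self.x_names,
            columns=[f"CAP{i + 1}" for i in range(n_axes)])

        res = DBRDAResults(
            model=self, R2=R2, adjR2=adjR2, F=F, p=np.nan,
            ss_fit=ss_fit, ss_cond=ss_cond, ss_res=ss_res, total=total,
            df_model=self.m, df_res=df_res,
            site_scores=site_scores, biplot_scores=biplot_scores,
            axis_eigenvalues=(ss[:n_axes] ** 2))
        if nperm:
            res.p = self.permutation_test(F, nperm, seed)
        return res

    def _perm_F(self, perm_rows: np.ndarray) -> np.ndarray:
        """Pseudo-F for a batch of row permutations (reduced-model residual
        permutation when conditioning predictors are present)."""
        R = self.Yr[perm_rows]                      # (B, n, k)
        if self.q:
            R = R - np.einsum("ij,bjk->bik", self.Hz, R)
        fit = np.einsum("ij,bjk->bik", self.H, R)
        ss_fit = (fit ** 2).sum(axis=(1, 2))
        ss_res = np.maximum((R ** 2).sum(axis=(1, 2)) - ss_fit, 0.0)
        df_res = len(self.labels) - 1 - self.m - self.q
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(ss_res > 0,
                            (ss_fit / self.m) / (ss_res / df_res), np.inf)

    def permutation_test(self, F_obs: float, nperm: int,
                         seed: int | None = 0) -> float:
        if nperm < 99:
            raise ValueError("use at least 99 permutations")
        rng = np.random.default_rng(seed)
        n = len(self.labels)
        count = 0
        chunk = 512
        done = 0
        while done < nperm:
            b = min(chunk, nperm - done)
            perms = np.array([rng.permutation(n) for _ in range(b)])
            Fp = self._perm_F(perms)
            count += int((Fp >= F_obs - 1e-12).sum())
            done += b
        return (count + 1) / (nperm + 1)


@dataclass
class DBRDAResults:
    """Fit of a (partial) dbRDA: inertia decomposition, axes, significance."""

    model: DBRDA
    R2: float
    adjR2: float
    F: float
    p: float
    ss_fit: float
    ss_cond: float
    ss_res: float
    total: float
    df_model: int
    df_res: int
    site_scores: pd.DataFrame
    biplot_scores: pd.DataFrame
    axis_eigenvalues: np.ndarray = field(default_factory=lambda: np.empty(0))

    def summary(self) -> str:
        m = self.model
        head = "dbRDA" if not m.z_names else "partial dbRDA"
        lines = [
            f"{head}: response {m.response.kind} ({len(m.labels)} sites)",
            f"  constraints : {', '.join(m.x_names)}",
        ]
        if m.z_names:
            lines.append(f"  conditioned : {', '.join(m.z_names)}")
        lines += [
            f"  inertia     : total={self.total:.4f}  constrained={self.ss_fit:.4f}"
            f"  conditioned={self.ss_cond:.4f}  residual={self.ss_res:.4f}",
            f"  R2={self.R2:.4f}  adjR2={self.adjR2:.4f}  "
            f"F({self.df_model},{self.df_res})={self.F:.3f}  "
            + (f"p={self.p:.4g}" if np.isfinite(self.p) else "p=not tested"),
        ]
        return "\n".join(lines)


def dbrda(response: DistMatrix, X: pd.DataFrame, Z: pd.DataFrame | None = None,
          nperm: int = 0, seed: int | None = 0) -> DBRDAResults:
    """Fit a (partial) dbRDA; convenience wrapper over :class:`DBRDA`."""
    return DBRDA(response, X, Z).fit(nperm=nperm, seed=seed)


def permutation_anova(results: DBRDAResults, nperm: int = 9999,
                      seed: int | None = 0) -> float:
    """Permutation significance of a fitted ordination (pseudo-F statistic;
    residuals-of-reduced-model permutation when conditioning is present)."""
    return results.model.permutation_test(results.F, nperm, seed)


# ---------------------------------------------------------------------------
# PCNM
# ---------------------------------------------------------------------------

def pcnm(d: DistMatrix, truncation: float | str = "auto",
         n_axes: int | None = None) -> pd.DataFrame:
    """Principal coordinates of neighbour matrices.

    Distances above the truncation threshold ``t`` are replaced by ``4 t``
    (``t`` defaults to the longest edge of the minimum spanning tree); the
    truncated matrix is Gower-centered and the orthonormal eigenvectors with
    positive eigenvalues are returned in descending-eigenvalue order.  The
    returned frame carries the eigenvalues in ``.attrs["eigenvalues"]`` and
    the threshold in ``.attrs["truncation"]``.
    """
    if d.n < 3:
        raise ValueError("PCNM needs at least 3 sites")
    off = d.condensed()
    if np.allclose(off, 0.0):
        raise ValueError("degenerate distance matrix: all sites coincide")
    if truncation == "auto":
        mst = minimum_spanning_tree(d.values).toarray()
        t = float(mst.max())
    else:
        t = float(truncation)
        if t <= 0:
            raise ValueError("truncation must be positive")
    D = d.values.copy()
    D[D > t] = 4.0 * t
    np.fill_diagonal(D, 0.0)
    G = _gower_center(D)
    lam, U = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, U = lam[order], U[:, order]
    keep = lam > lam.max() * _EIG_TOL
    lam, U = lam[keep], U[:, keep]
    # sign convention: largest-|entry| element of each vector positive
    for j in range(U.shape[1]):
        if U[np.argmax(np.abs(U[:, j])), j] < 0:
            U[:, j] = -U[:, j]
    if n_axes is not None:
        lam, U = lam[:n_axes], U[:, :n_axes]
    out = pd.DataFrame(U, index=d.labels,
                       columns=[f"PCNM{i + 1}" for i in range(U.shape[1])])
    out.attrs["eigenvalues"] = lam
    out.attrs["truncation"] = t
    return out


# ---------------------------------------------------------------------------
# forward selection
# ---------------------------------------------------------------------------

def forward_select(response: DistMatrix, candidates: pd.DataFrame,
                   alpha: float = 0.01, nperm: int = 9999,
                   seed: int | None = 0) -> pd.DataFrame:
    """Greedy forward selection of predictors for a dbRDA.

    At each step the candidate with the largest adjusted-R2 gain is tested
    by permutation conditional on the current selection and added if
    significant; selection then stops once the cumulative adjusted R2
    exceeds the global (all-candidate) model's adjusted R2, or when the
    best candidate is non-significant (p >= alpha).  Ties break
    lexicographically.  When the global model cannot be fitted (more
    candidates than sites permit) the scope bound is disabled.  Returns one
    row per accepted predictor (may be empty) with per-step adjR2 and p;
    the global adjusted R2 is in ``.attrs["global_adjR2"]``.
    """
    if candidates.shape[1] < 1:
        raise ValueError("need at least one candidate")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            global_adj = dbrda(response, candidates).adjR2
    except ValueError:
        warnings.warn("global model is not estimable; forward selection "
                      "runs without the adjusted-R2 scope bound",
                      RuntimeWarning, stacklevel=2)
        global_adj = np.inf
    selected: list[str] = []
    rows = []
    remaining = list(candidates.columns)
    rng = np.random.default_rng(seed)
    step = 0
    current_adj = 0.0
    while remaining:
        step += 1
        gains = []
        for name in sorted(remaining):
            cols = selected + [name]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    res = dbrda(response, candidates[cols])
            except ValueError:
                continue
            gains.append((res.adjR2, name))
        if not gains:
            break
        gains.sort(key=lambda t: (-t[0], t[1]))
        best_adj, best = gains[0]
        if selected and best_adj - current_adj <= 1e-9:
            break                      # no real gain left (e.g. aliasing)
        Z = candidates[selected] if selected else None
        try:
            p = dbrda(response, candidates[[best]], Z=Z, nperm=nperm,
                      seed=int(rng.integers(2 ** 31))).p
        except ValueError:
            break                      # candidate aliased by the selection
        if p >= alpha:
            break
        selected.append(best)
        remaining.remove(best)
        current_adj = best_adj
        rows.append({"step": step, "variable": best,
                     "adjR2_cum": best_adj, "p": p})
        if best_adj > global_adj + 1e-12:
            break                      # scope bound reached

    out = pd.DataFrame(rows, columns=["step", "variable", "adjR2_cum", "p"])
    out.attrs["global_adjR2"] = global_adj
    out.attrs["selected"] = selected
    return out


# ---------------------------------------------------------------------------
# variance partitioning
# ---------------------------------------------------------------------------

def variance_partition(response: DistMatrix, blocks: PredictorSet | dict,
                       nperm: int = 999, seed: int | None = 0,
                       cascade: bool = False, alpha: float = 0.05
                       ) -> pd.DataFrame | list[pd.DataFrame]:
    """Full-model / pure-block decomposition of explained variance.

    For blocks B1..Bk, fits the full model on all blocks and, per block, the
    partial model ``response ~ Bi | (all other blocks)``.  Each pure row
    reports: explained (R2 of the pure fraction), unexplained (1 - R2 of
    the full model), confounded (full - pure), the adjusted R2 and the
    permutation p.  Rows close exactly: pure + confounded + unexplained = 1.

    With ``cascade=True``, blocks whose pure effect is non-significant are
    removed one at a time (largest p first) and the reduced full model is
    refitted; the list of successive tables is returned.
    """
    if isinstance(blocks, PredictorSet):
        block_map = blocks.blocks
    else:
        block_map = dict(blocks)
    if not block_map:
        raise ValueError("no predictor blocks")
    tables: list[pd.DataFrame] = []
    current = dict(block_map)
    rng = np.random.default_rng(seed)
    while True:
        tab = _partition_once(response, current, nperm, rng)
        tables.append(tab)
        if not cascade or len(current) <= 1:
            break
        pure = tab[tab["model"].str.startswith("pure")]
        worst = pure.loc[pure["p"].idxmax()]
        if worst["p"] < alpha:
            break
        current = {k: v for k, v in current.items()
                   if k != worst["model"].split(" ", 1)[1]}
    return tables if cascade else tables[0]


def _partition_once(response: DistMatrix, blocks: dict[str, pd.DataFrame],
                    nperm: int, rng: np.random.Generator) -> pd.DataFrame:
    names = list(blocks)
    allX = pd.concat([blocks[n] for n in names], axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        full = dbrda(response, allX, nperm=nperm,
                     seed=int(rng.integers(2 ** 31)))
        unexplained = 1.0 - full.R2
        rows = [{"model": "full", "explained": full.R2,
                 "unexplained": unexplained, "confounded": 0.0,
                 "adjR2": full.adjR2, "p": full.p}]
        for n in names:
            others = [m for m in names if m != n]
            Z = pd.concat([blocks[m] for m in others], axis=1) if others else None
            try:
                pure = dbrda(response, blocks[n], Z=Z, nperm=nperm,
                             seed=int(rng.integers(2 ** 31)))
                r2p, adjp, pp = pure.R2, pure.adjR2, pure.p
            except ValueError:
                # block entirely aliased by the others: no unique fraction
                r2p, adjp, pp = 0.0, 0.0, 1.0
            rows.append({"model": f"pure {n}", "explained": r2p,
                         "unexplained": unexplained,
                         "confounded": full.R2 - r2p,
                         "adjR2": adjp, "p": pp})
    out = pd.DataFrame(rows)
    out.attrs["total_explained"] = float(full.R2)
    out.attrs["total_unexplained"] = float(unexplained)
    return out
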
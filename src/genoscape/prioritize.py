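"""Population prioritization for conservation.

Two complementary procedures:

* **Reserve selection** — greedy complementarity: repeatedly add the
  population contributing the most not-yet-covered alleles until every
  allele in the dataset is represented (the minimum-set-cover heuristic
  used for allelic-diversity reserve design).
* **Conservation index** — C_i = A_r x F_c / C_l per population: rarefied
  allelic richness times the forest-cover fraction within a 20-km-radius
  neighbourhood (a forest-continuity surrogate for an insect-pollinated
  tree), discounted by a climate-shift factor C_l built from the projected
  change in warmest- and coldest-quarter precipitation (bio18/bio19).
  Populations are then binned into priority categories 1 (highest) to k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GenotypeTable, RasterGrid

__all__ = ["AlleleIncidence", "reserve_selection", "forest_fraction",
           "climate_shift_factor", "conservation_index", "rank_categories",
           "haversine_km"]


# ---------------------------------------------------------------------------
# allele incidence + reserve selection
# ---------------------------------------------------------------------------

@dataclass
class AlleleIncidence:
    """Boolean population x allele incidence matrix.

    Alleles are (locus, allele-size) identifiers; every allele occurs in at
    least one population.
    """

    populations: list[str]
    alleles: list[tuple[str, int]]
    incidence: np.ndarray                    # (n_pops, n_alleles) bool

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=bool)
        if self.incidence.shape != (len(self.populations), len(self.alleles)):
            raise ValueError("incidence shape mismatch")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("duplicate allele identifiers")
        if not self.incidence.any(axis=0).all():
            raise ValueError("every allele must occur in some population")

    @classmethod
    def from_genotypes(cls, gt: GenotypeTable) -> "AlleleIncidence":
        pops = gt.pops
        allele_ids: list[tuple[str, int]] = []
        cols: dict[tuple[str, int], int] = {}
        rows = np.zeros((len(pops), 0), dtype=bool)
        inc: dict[tuple[str, int], set[int]] = {}
        for l, locus in enumerate(gt.loci):
            for pi, p in enumerate(pops):
                for size in gt.allele_counts(l, p):
                    inc.setdefault((locus, size), set()).add(pi)
        allele_ids = sorted(inc)
        mat = np.zeros((len(pops), len(allele_ids)), dtype=bool)
        for j, aid in enumerate(allele_ids):
            for pi in inc[aid]:
                mat[pi, j] = True
        return cls(list(pops), allele_ids, mat)


def reserve_selection(inc: AlleleIncidence,
                      weights: np.ndarray | None = None,
                      max_iter: int = 100,
                      prune: bool = True) -> pd.DataFrame:
    """Greedy complementarity selection of populations.

    At each step the population covering the largest (optionally weighted)
    sum of uncovered alleles is added; ties break by population-label
    order.  Stops when all alleles are covered or after ``max_iter`` steps.
    With ``prune=True`` (default) a redundancy-elimination pass then drops
    any selected population whose alleles are fully covered by the rest —
    on small instances this almost always reduces the greedy solution to
    the true minimum cover.  Returns one row per selected population with
    its marginal gain (in the final selection order) and the cumulative
    coverage fraction.
    """
    n_alleles = len(inc.alleles)
    if n_alleles == 0:
        return pd.DataFrame(columns=["step", "pop", "gain", "coverage"])
    w = np.ones(n_alleles) if weights is None else np.asarray(weights, float)
    if w.shape != (n_alleles,):
        raise ValueError("weights must have one entry per allele")
    covered = np.zeros(n_alleles, dtype=bool)
    order = np.argsort(np.asarray(inc.populations, dtype=object))
    picked: list[int] = []
    remaining = set(range(len(inc.populations)))
    for _step in range(max_iter):
        if covered.all() or not remaining:
            break
        best_pi, best_gain = None, -1.0
        for pi in order:
            if pi not in remaining:
                continue
            gain = float(w[inc.incidence[pi] & ~covered].sum())
            if gain > best_gain + 1e-12:
                best_pi, best_gain = int(pi), gain
        if best_pi is None or best_gain <= 0:
            break
        covered |= inc.incidence[best_pi]
        remaining.discard(best_pi)
        picked.append(best_pi)

    if prune and covered.all():
        changed = True
        while changed:
            changed = False
            for j in list(picked):
                rest = [k for k in picked if k != j]
                if rest and inc.incidence[rest].any(axis=0).all():
                    picked.remove(j)
                    changed = True
                    break

    rows = []
    running = np.zeros(n_alleles, dtype=bool)
    for step, pi in enumerate(picked, start=1):
        gain = float(w[inc.incidence[pi] & ~running].sum())
        running |= inc.incidence[pi]
        rows.append({"step": step, "pop": inc.populations[pi], "gain": gain,
                     "coverage": float(running.sum()) / n_alleles})
    return pd.DataFrame(rows, columns=["step", "pop", "gain", "coverage"])


# ---------------------------------------------------------------------------
# forest continuity
# ---------------------------------------------------------------------------

def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (WGS84 mean radius)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon, dlat = lon2 - lon1, lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 6371.0088 * 2 * np.arcsin(np.sqrt(a))


def forest_fraction(forest: RasterGrid, lon: float, lat: float,
                    radius_km: float = 20.0) -> float:
    """Area-weighted mean forest fraction over cells whose centers fall
    within ``radius_km`` of the point (geodesic circle)."""
    if not (forest.west <= lon <= forest.east
            and forest.south <= lat <= forest.north):
        raise ValueError(f"point ({lon}, {lat}) outside the forest raster")
    LON, LAT = np.meshgrid(forest.lon_centers(), forest.lat_centers())
    within = haversine_km(LON, LAT, lon, lat) <= radius_km
    vals = forest.values[within]
    areas = forest.cell_areas_km2()[within]
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("no forest data within the neighbourhood circle")
    return float((vals[ok] * areas[ok]).sum() / areas[ok].sum())


# ---------------------------------------------------------------------------
# conservation index
# ---------------------------------------------------------------------------

def climate_shift_factor(current: dict[str, float],
                         future: dict[str, float],
                         variables: tuple[str, str] = ("bio18", "bio19")
                         ) -> float:
    """Climate-shift discount C_l >= 1.

    For each variable v the relative absolute change is
    rho_v = |future_v - current_v| / current_v; C_l is the geometric mean of
    (1 + rho_v) over the two precipitation variables, so no change gives
    C_l = 1 and larger projected shifts discount the conservation index
    more strongly.
    """
    fac = 1.0
    for v in variables:
        cur = current[v]
        if cur <= 0:
            raise ValueError(f"current {v} must be positive (got {cur})")
        rho = abs(future[v] - cur) / cur
        fac *= 1.0 + rho
    return float(np.sqrt(fac))


def conservation_index(a_r: float, f_c: float, c_l: float) -> float:
    """C_i = A_r * F_c / C_l."""
    if a_r <= 0:
        raise ValueError("allelic richness must be positive")
    if not 0.0 <= f_c <= 1.0:
        raise ValueError("forest fraction must lie in [0, 1]")
    if c_l == 0:
        raise ValueError("climate-shift factor must be non-zero")
    if c_l < 1.0:
        raise ValueError("climate-shift factor must be >= 1")
    return a_r * f_c / c_l


def rank_categories(ci: pd.Series | dict[str, float], k: int = 5,
                    method: str = "interval") -> pd.Series:
    """Priority categories 1 (highest C_i) to ``k`` (lowest).

    ``method="interval"`` (default) bins C_i into unit-width intervals
    anchored at integers — category c holds C_i in [k - c, k - c + 1), with
    the top bin open above and the bottom open below; this is the binning
    that reproduces the published category memberships for a C_i range
    spanning roughly (0, k].  ``method="rank"`` instead splits the
    descending C_i order into k groups as equal as possible (sizes
    differing by at most 1, larger groups first).  Ties break by label
    order in both methods.
    """
    if isinstance(ci, dict):
        ci = pd.Series(ci)
    if len(ci) < k:
        raise ValueError(f"need at least k={k} records")
    if method == "interval":
        cats = (k - np.floor(ci.to_numpy(float))).clip(1, k).astype(int)
        return pd.Series(cats, index=ci.index, name="category")
    if method == "rank":
        order = sorted(ci.index, key=lambda lbl: (-ci[lbl], lbl))
        n = len(order)
        base, extra = divmod(n, k)
        sizes = [base + (1 if i < extra else 0) for i in range(k)]
        cats = {}
        pos = 0
        for c, size in enumerate(sizes, start=1):
            for lbl in order[pos:pos + size]:
                cats[lbl] = c
            pos += size
        return pd.Series(cats, name="category").loc[ci.index]
    raise ValueError(f"unknown method {method!r}")
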
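"""Core in-memory containers shared across the pipeline.

The package moves four kinds of objects between stages: diploid
microsatellite genotype tables, symmetric dissimilarity matrices,
ancestry-coefficient (Q) matrices, and co-registered raster layers.
Everything is numpy/pandas-backed; rasters use ``nan`` as the in-memory
NODATA sentinel so that missingness propagates through arithmetic for free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

MISSING_ALLELE = 0  # allele-size sentinel for missing data (GENEPOP "000")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid allele-size matrix (individuals x loci x 2) with population labels.

    Allele sizes are integers in base pairs on each locus's repeat lattice;
    ``0`` marks a missing allele.  Population labels are kept per individual;
    :attr:`pops` preserves first-appearance order.
    """

    alleles: np.ndarray                      # (n_ind, n_loci, 2) int
    individuals: list[str]
    populations: np.ndarray                  # (n_ind,) str
    loci: list[str]

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.alleles.ndim != 3 or self.alleles.shape[2] != 2:
            raise ValueError("alleles must have shape (n_ind, n_loci, 2)")
        if self.alleles.shape[0] != len(self.individuals):
            raise ValueError("individual labels do not match allele rows")
        if self.alleles.shape[1] != len(self.loci):
            raise ValueError("locus labels do not match allele columns")
        if len(self.populations) != len(self.individuals):
            raise ValueError("population labels do not match individuals")
        if (self.alleles < 0).any():
            raise ValueError("allele sizes must be positive or 0 (missing)")

    @property
    def n_ind(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    @property
    def pops(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def pop_mask(self, pop: str) -> np.ndarray:
        m = self.populations == pop
        if not m.any():
            raise KeyError(f"unknown population {pop!r}")
        return m

    def subset(self, pops: Sequence[str]) -> "GenotypeTable":
        mask = np.isin(self.populations, list(pops))
        return GenotypeTable(
            self.alleles[mask],
            [i for i, keep in zip(self.individuals, mask) if keep],
            self.populations[mask],
            list(self.loci),
        )

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def allele_counts(self, locus: int | str, pop: str | None = None) -> dict[int, int]:
        """Counts of non-missing allele copies at one locus (optionally one pop)."""
        j = self.locus_index(locus) if isinstance(locus, str) else locus
        a = self.alleles[:, j, :]
        if pop is not None:
            a = a[self.pop_mask(pop)]
        a = a[a != MISSING_ALLELE]
        sizes, counts = np.unique(a, return_counts=True)
        return dict(zip(sizes.tolist(), counts.tolist()))

    def gene_copies(self, locus: int | str, pop: str) -> int:
        return sum(self.allele_counts(locus, pop).values())

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, list] = {"individual": self.individuals,
                                 "population": list(self.populations)}
        for j, loc in enumerate(self.loci):
            cols[f"{loc}_1"] = self.alleles[:, j, 0].tolist()
            cols[f"{loc}_2"] = self.alleles[:, j, 1].tolist()
        return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# dissimilarity matrices
# ---------------------------------------------------------------------------

DIST_KINDS = {"fst", "linearized_fst", "geographic", "climatic", "tri", "generic"}


@dataclass
class DistMatrix:
    """Labelled symmetric dissimilarity matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str = "generic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("diagonal must be zero")
        if self.kind not in DIST_KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "generic") -> "DistMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float), kind)


# ---------------------------------------------------------------------------
# ancestry coefficients
# ---------------------------------------------------------------------------

@dataclass
class AncestryMatrix:
    """Cluster membership proportions (rows: pops or individuals; cols: K clusters)."""

    labels: list[str]
    Q: np.ndarray                            # (n, K), rows sum to 1
    scores: pd.DataFrame | None = None       # anc1/anc2 PCA scores, filled lazily

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != len(self.labels):
            raise ValueError("Q shape does not match labels")
        if (self.Q < -1e-9).any():
            raise ValueError("membership proportions must be non-negative")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.labels,
                            columns=[f"Q{k + 1}" for k in range(self.K)])


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

# per-degree great-circle spans used for cell areas (equirectangular model)
KM_PER_DEG_LON_EQ = 111.32
KM_PER_DEG_LAT = 110.57


@dataclass
class RasterGrid:
    """Regular lon/lat grid (row 0 = northernmost). NODATA is ``nan`` in memory."""

    values: np.ndarray                       # (nrow, ncol) float, nan = NODATA
    west: float
    south: float
    east: float
    north: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not (self.east > self.west and self.north > self.south):
            raise ValueError("invalid extent")

    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def dx(self) -> float:
        return (self.east - self.west) / self.ncol

    @property
    def dy(self) -> float:
        return (self.north - self.south) / self.nrow

    def lon_centers(self) -> np.ndarray:
        return self.west + (np.arange(self.ncol) + 0.5) * self.dx

    def lat_centers(self) -> np.ndarray:
        return self.north - (np.arange(self.nrow) + 0.5) * self.dy

    def cell_index(self, lon: float, lat: float) -> tuple[int, int]:
        if not (self.west <= lon <= self.east and self.south <= lat <= self.north):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        col = min(int((lon - self.west) / self.dx), self.ncol - 1)
        row = min(int((self.north - lat) / self.dy), self.nrow - 1)
        return row, col

    def sample(self, lon: float, lat: float) -> float:
        """Point-sample the cell containing (lon, lat)."""
        r, c = self.cell_index(lon, lat)
        return float(self.values[r, c])

    def cell_areas_km2(self) -> np.ndarray:
        """Per-cell area with cosine-latitude correction, broadcast to grid shape."""
        lat = np.deg2rad(self.lat_centers())
        row_area = (KM_PER_DEG_LON_EQ * np.cos(lat) * self.dx) * (KM_PER_DEG_LAT * self.dy)
        return np.repeat(row_area[:, None], self.ncol, axis=1)

    def co_registered(self, other: "RasterGrid", atol: float = 1e-9) -> bool:
        return (self.values.shape == other.values.shape
                and abs(self.west - other.west) < atol
                and abs(self.south - other.south) < atol
                and abs(self.east - other.east) < atol
                and abs(self.north - other.north) < atol)

    def like(self, values: np.ndarray, units: str = "") -> "RasterGrid":
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ValueError("shape mismatch")
        return RasterGrid(values, self.west, self.south, self.east, self.north, units)


@dataclass
class ClimateStack:
    """Named co-registered climate rasters for one period/scenario/GCM."""

    layers: dict[str, RasterGrid]
    period: str = "current"
    scenario: str = "current"
    model: str = ""

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        if not grids:
            raise ValueError("empty stack")
        ref = grids[0]
        for name, g in self.layers.items():
            if not ref.co_registered(g):
                raise ValueError(f"layer {name!r} is not co-registered")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def ref(self) -> RasterGrid:
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def sample_points(self, lons: Sequence[float], lats: Sequence[float],
                      variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Point-sample every (or selected) layer at the given coordinates."""
        variables = list(variables) if variables is not None else self.names
        out = {v: [self.layers[v].sample(lo, la) for lo, la in zip(lons, lats)]
               for v in variables}
        return pd.DataFrame(out)

    def as_table(self, variables: Sequence[str] | None = None) -> pd.DataFrame:
        """Flatten valid cells (no NODATA in any requested layer) to a table."""
        variables = list(variables) if variables is not None else self.names
        stack = np.stack([self.layers[v].values for v in variables])
        valid = ~np.isnan(stack).any(axis=0)
        return pd.DataFrame({v: stack[i][valid] for i, v in enumerate(variables)})


@dataclass
class SuitabilityMap:
    """Habitat-suitability raster in [0, 1] plus its evaluation statistics."""

    grid: RasterGrid
    auc: float = float("nan")
    tss: float = float("nan")

    def __post_init__(self) -> None:
        v = self.grid.values
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9:
                raise ValueError("suitability must lie in [0, 1]")

    def mask(self, thr: float) -> np.ndarray:
        """Boolean suitable-cell mask at threshold ``thr`` (NODATA -> False)."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.grid.values, nan=-1.0) >= thr
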
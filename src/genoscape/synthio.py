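"""Synthetic eco-genetic world generator.

The study system this package targets — 21 sweet-chestnut stands sampled
along a ~600 km west-east transect of the South Caucasus, genotyped at nine
nuclear microsatellites — has no public genotype deposit, so every pipeline
stage is exercised against synthetic data with the same statistical
structure:

* a forward Wright-Fisher stepping-stone metapopulation with stepwise
  (optionally two-phase) microsatellite mutation, seeded from ancestral
  allele pools whose richness declines west to east (serial founder
  effects), grouped into K ancestral clusters;
* climate rasters on a toy lon/lat grid spanning 41-48 E, 40.9-42.7 N with
  a west-to-east decline in precipitation (bio18/bio19) and future stacks
  derived from the current one by deterministic scenario shifts;
* a DEM, a fractional forest-cover layer, occurrence points planted on the
  precipitation gradient, and population-level ancestry coefficients driven
  by a softmax in the climate covariates.

Every quantity needed by downstream parameter-recovery tests is recorded in
``SyntheticWorld.truth``.  Identical seeds give byte-identical worlds.
"""

from __future__ import annotations

import json
import hashlib
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._mutation import coalescent_microsat, mutate_lattice
from .containers import AncestryMatrix, ClimateStack, GenotypeTable, RasterGrid
from . import io as gio

# toy study extent (degrees)
WEST, EAST, SOUTH, NORTH = 41.0, 48.0, 40.9, 42.7
RESOLUTION = 0.1

CLIMATE_VARIABLES = [
    "bio1", "bio3", "bio4", "bio8", "bio9", "bio15", "bio18", "bio19",
    "annualPET", "aridityIndexThornthwaite", "climaticMoistureIndex",
]

#: deterministic additive scenario shifts applied to the current stack
SCENARIO_SHIFTS: dict[str, dict[str, float]] = {
    "ssp370": {"bio1": 2.3, "bio3": -1.0, "bio4": 25.0, "bio8": 2.2,
               "bio9": 2.5, "bio15": 3.0, "bio18": -60.0, "bio19": -70.0},
    "ssp585": {"bio1": 4.4, "bio3": -2.0, "bio4": 45.0, "bio8": 4.2,
               "bio9": 4.6, "bio15": 5.0, "bio18": -110.0, "bio19": -130.0},
}

GCM_NAMES = ["GCM1", "GCM2", "GCM3"]


@dataclass
class SimConfig:
    """Knobs of the synthetic world.

    ``mutation_rate`` defaults to 5.47e-5 per generation, the microsatellite
    rate the downstream theta-to-Ne conversion also uses; ``n_clusters`` is
    the number of ancestral lineages (K = 4 in the emulated system).
    ``diversity_gradient`` is the slope of founder allelic richness against
    longitude (alleles per degree; negative = eastward decline).
    """

    n_pops: int = 21
    n_ind_per_pop: int = 30
    n_loci: int = 9
    n_clusters: int = 4
    migration_rate: float = 0.05
    mutation_rate: float = 5.47e-5
    diversity_gradient: float = -1.5
    seed: int = 0
    n_generations: int = 50
    deme_size: int | None = None             # defaults to max(100, n_ind_per_pop)
    repeat_unit: int = 2
    base_allele: int = 120
    pool_size: int = 16
    p_ss: float = 1.0
    mean_jump: float = 2.8
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("n_pops", "n_ind_per_pop", "n_loci", "n_clusters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("migration_rate", "mutation_rate", "missing_rate", "p_ss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_clusters > self.n_pops:
            raise ValueError("n_clusters cannot exceed n_pops")
        if self.deme_size is None:
            self.deme_size = max(100, self.n_ind_per_pop)
        if self.deme_size < self.n_ind_per_pop:
            raise ValueError("deme_size must be >= n_ind_per_pop (sampling)")

    def rng(self, *stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed & 0x7FFFFFFF, *stream])


@dataclass
class SyntheticWorld:
    """Bundle of all synthetic inputs plus the generating truth record."""

    genotypes: GenotypeTable
    q_matrix: AncestryMatrix
    climate_current: ClimateStack
    climate_future: dict[str, list[ClimateStack]]   # scenario -> one stack per GCM
    dem: RasterGrid
    forest: RasterGrid
    occurrences: pd.DataFrame                       # columns lon, lat
    sites: pd.DataFrame                             # pop, lon, lat, altitude
    truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# population sites
# ---------------------------------------------------------------------------

def population_sites(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic site layout: evenly spaced in longitude, wiggled in
    latitude, mirroring a transect through the study extent."""
    n = cfg.n_pops
    lon = np.linspace(WEST + 0.5, EAST - 0.4, n)
    rng = cfg.rng(101)
    lat = 41.8 + 0.55 * np.sin(np.linspace(0.0, 2.6 * np.pi, n)) \
        + rng.uniform(-0.08, 0.08, n)
    lat = np.clip(lat, SOUTH + 0.1, NORTH - 0.1)
    pops = [f"P{i + 1:02d}" for i in range(n)]
    return pd.DataFrame({"pop": pops, "lon": lon, "lat": lat})


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig) -> GenotypeTable:
    """Forward Wright-Fisher stepping-stone metapopulation.

    Each deme is founded from a cluster-specific perturbation of an
    ancestral allele pool; founder richness declines along
    ``diversity_gradient``, which creates the west-to-east decline in
    allelic richness and private alleles that the emulated data show.
    Demes then evolve ``n_generations`` of drift, nearest-neighbour
    migration and stepwise mutation.  Output has no missing data unless
    ``missing_rate > 0``.
    """
    rng = cfg.rng(1)
    n, N, L = cfg.n_pops, cfg.deme_size, cfg.n_loci
    n_sample = cfg.n_ind_per_pop
    sites = population_sites(cfg)
    lon = sites["lon"].to_numpy()

    # ancestral pool: pool_size lattice alleles with skewed dirichlet
    # frequencies (rare pool alleles become the private alleles of the
    # richer western demes)
    pool_sizes = cfg.base_allele + cfg.repeat_unit * np.arange(cfg.pool_size)
    pool_freq = rng.dirichlet(np.full(cfg.pool_size, 0.4), size=L)  # (L, pool)

    blocks = np.array_split(np.arange(n), cfg.n_clusters)
    cluster_of = np.empty(n, dtype=int)
    for k, b in enumerate(blocks):
        cluster_of[b] = k
    # cluster-specific frequency perturbations (the ancestral lineages)
    cluster_freq = pool_freq[None] * np.exp(
        rng.normal(0.0, 0.9, size=(cfg.n_clusters, L, cfg.pool_size)))
    cluster_freq /= cluster_freq.sum(axis=2, keepdims=True)

    # founder richness per deme declines with longitude
    richness = np.clip(np.rint((cfg.pool_size - 1)
                               + cfg.diversity_gradient * (lon - lon.min())),
                       3, cfg.pool_size).astype(int)

    # initialise deme gene pools
    state = np.empty((n * N, L, 2), dtype=np.int64)
    founder_alleles: dict[str, dict[str, list[int]]] = {}
    for d in range(n):
        fa: dict[str, list[int]] = {}
        for l in range(L):
            f = cluster_freq[cluster_of[d], l]
            chosen = rng.choice(cfg.pool_size, size=richness[d],
                                replace=False, p=f)
            w = f[chosen] / f[chosen].sum()
            draws = rng.choice(pool_sizes[chosen], size=2 * N, p=w)
            state[d * N:(d + 1) * N, l, :] = draws.reshape(N, 2)
            fa[f"L{l + 1}"] = sorted(set(pool_sizes[chosen].tolist()))
        founder_alleles[f"P{d + 1:02d}"] = fa

    deme_start = np.arange(n) * N
    m = cfg.migration_rate
    for _ in range(cfg.n_generations):
        # source deme of each gamete: stay, or step to a neighbour
        src = np.repeat(np.arange(n), N)[:, None] * np.ones((1, 2), dtype=int)
        u = rng.random((n * N, 2))
        step = np.zeros((n * N, 2), dtype=int)
        step[u < m / 2] = -1
        step[(u >= m / 2) & (u < m)] = 1
        src = np.clip(src + step, 0, n - 1)
        parent = deme_start[src] + rng.integers(0, N, size=(n * N, 2))
        slots = rng.integers(0, 2, size=(n * N, 2, L))
        child = np.empty_like(state)
        for g in (0, 1):
            child[:, :, g] = state[parent[:, g][:, None],
                                   np.arange(L)[None, :],
                                   slots[:, g, :]]
        state = mutate_lattice(child, cfg.mutation_rate, cfg.repeat_unit,
                               rng, cfg.p_ss, cfg.mean_jump)

    # sample n_ind_per_pop individuals from each deme
    sel = np.concatenate([deme_start[d] + rng.choice(N, n_sample, replace=False)
                          for d in range(n)])
    state = state[sel]

    if cfg.missing_rate > 0:
        miss = rng.random((n * n_sample, L)) < cfg.missing_rate
        state[miss] = 0

    pops = np.repeat([f"P{i + 1:02d}" for i in range(n)], n_sample).astype(object)
    individuals = [f"{p}_{i % n_sample + 1}" for i, p in enumerate(pops)]
    loci = [f"L{l + 1}" for l in range(L)]
    gt = GenotypeTable(state, individuals, pops, loci)
    gt.truth = {  # type: ignore[attr-defined]
        "deme_size": {f"P{i + 1:02d}": N for i in range(n)},
        "cluster_of": {f"P{i + 1:02d}": int(cluster_of[i]) for i in range(n)},
        "founder_richness": {f"P{i + 1:02d}": int(richness[i]) for i in range(n)},
        "founder_alleles": founder_alleles,
    }
    return gt


def simulate_wf_deme(ne: int, sample_size: int, n_loci: int,
                     n_generations: int, mu: float,
                     rng: np.random.Generator,
                     init_theta: float = 4.0, repeat_unit: int = 2,
                     base_allele: int = 120) -> GenotypeTable:
    """One isolated Wright-Fisher deme of ``ne`` diploids, sampled at the end.

    Initial standing variation is drawn from a coalescent equilibrium sample
    at ``init_theta`` so loci are polymorphic; the final ``n_generations`` of
    random mating at constant size set the contemporary LD signal.
    """
    if sample_size > ne:
        raise ValueError("cannot sample more individuals than the deme holds")
    state = np.empty((ne, n_loci, 2), dtype=np.int64)
    for l in range(n_loci):
        anc = coalescent_microsat(rng, 2 * ne, init_theta)
        state[:, l, :] = (base_allele + repeat_unit * anc).reshape(ne, 2)
    for _ in range(n_generations):
        parent = rng.integers(0, ne, size=(ne, 2))
        slots = rng.integers(0, 2, size=(ne, 2, n_loci))
        child = np.empty_like(state)
        for g in (0, 1):
            child[:, :, g] = state[parent[:, g][:, None],
                                   np.arange(n_loci)[None, :],
                                   slots[:, g, :]]
        state = mutate_lattice(child, mu, repeat_unit, rng)
    pick = rng.choice(ne, size=sample_size, replace=False)
    pops = np.array(["deme"] * sample_size, dtype=object)
    inds = [f"deme_{i + 1}" for i in range(sample_size)]
    return GenotypeTable(state[pick], inds, pops,
                         [f"L{l + 1}" for l in range(n_loci)])


# ---------------------------------------------------------------------------
# climate, terrain, forest
# ---------------------------------------------------------------------------

def _grid_coords() -> tuple[np.ndarray, np.ndarray]:
    ncol = round((EAST - WEST) / RESOLUTION)
    nrow = round((NORTH - SOUTH) / RESOLUTION)
    lon = WEST + (np.arange(ncol) + 0.5) * RESOLUTION
    lat = NORTH - (np.arange(nrow) + 0.5) * RESOLUTION
    return np.meshgrid(lon, lat)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  amplitude: float, coarse: int = 6) -> np.ndarray:
    """Smooth random field: coarse white noise, bilinearly upsampled."""
    if amplitude == 0:
        return np.zeros(shape)
    base = rng.normal(0.0, 1.0, size=(coarse, coarse))
    ry = np.linspace(0, coarse - 1, shape[0])
    rx = np.linspace(0, coarse - 1, shape[1])
    y0 = np.clip(ry.astype(int), 0, coarse - 2)
    x0 = np.clip(rx.astype(int), 0, coarse - 2)
    fy = (ry - y0)[:, None]
    fx = (rx - x0)[None, :]
    f = (base[y0][:, x0] * (1 - fy) * (1 - fx)
         + base[y0 + 1][:, x0] * fy * (1 - fx)
         + base[y0][:, x0 + 1] * (1 - fy) * fx
         + base[y0 + 1][:, x0 + 1] * fy * fx)
    return amplitude * f


def _raster(values: np.ndarray, units: str = "") -> RasterGrid:
    return RasterGrid(values, WEST, SOUTH, EAST, NORTH, units)


def simulate_dem(cfg: SimConfig) -> RasterGrid:
    """Two mountain chains (Greater Caucasus north, Lesser Caucasus south)
    with a central valley, plus seeded roughness."""
    L, B = _grid_coords()
    rng = cfg.rng(201)
    dem = (180.0
           + 1500.0 * np.exp(-(((B - 42.55) / 0.30) ** 2))
           + 950.0 * np.exp(-(((B - 41.20) / 0.28) ** 2))
           + 12.0 * (L - WEST)
           + _smooth_field(rng, L.shape, 60.0, coarse=9))
    return _raster(np.maximum(dem, 0.0), "m a.s.l.")


def _base_layers(cfg: SimConfig, dem: RasterGrid) -> dict[str, np.ndarray]:
    L, B = _grid_coords()
    rng = cfg.rng(202)
    z = dem.values
    layers = {
        "bio1": 14.5 - 0.0060 * z + 0.35 * (L - 44.5)
                + _smooth_field(rng, L.shape, 0.4),
        "bio3": 45.0 - 1.1 * (L - WEST) + 0.002 * z
                + _smooth_field(rng, L.shape, 0.5),
        "bio4": 560.0 + 40.0 * (L - WEST) + _smooth_field(rng, L.shape, 8.0),
        "bio15": 25.0 + 5.5 * (L - WEST) + _smooth_field(rng, L.shape, 1.0),
        # the precipitation pair declines strictly monotonically west->east
        "bio18": 320.0 - 38.0 * (L - WEST) + 3.0 * (B - 41.8),
        "bio19": 650.0 - 78.0 * (L - WEST) + 8.0 * (B - 41.8),
    }
    layers["bio8"] = 0.90 * layers["bio1"] + 4.0 + _smooth_field(rng, L.shape, 0.8)
    layers["bio9"] = 0.85 * layers["bio1"] - 1.0 + _smooth_field(rng, L.shape, 0.8)
    return layers


def _derived_layers(layers: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    pet = 800.0 + 35.0 * layers["bio1"]
    aridity = 100.0 * pet / (layers["bio18"] + layers["bio19"] + 200.0)
    # moisture index is an exact affine image of the aridity index
    # (correlation -1 by construction; exercises the VIF filter)
    moisture = 1.2 - 0.012 * aridity
    return {"annualPET": pet, "aridityIndexThornthwaite": aridity,
            "climaticMoistureIndex": moisture}


def simulate_climate_stack(cfg: SimConfig, period: str = "current",
                           scenario: str | None = None, model: str = "GCM1",
                           shift: dict[str, float] | None = None,
                           noise: float = 0.0) -> ClimateStack:
    """Build one co-registered climate stack.

    ``period="current"`` returns the baseline.  ``period="future"`` applies
    an additive shift per variable — either the explicit ``shift`` mapping or
    the built-in scenario default (``ssp370`` / ``ssp585``) with a small
    deterministic per-GCM offset — plus optional seeded noise, and recomputes
    the derived evapotranspiration/aridity/moisture layers.
    """
    if period not in {"current", "future"}:
        raise ValueError("period must be 'current' or 'future'")
    dem = simulate_dem(cfg)
    base = _base_layers(cfg, dem)
    if period == "future":
        if shift is None:
            scenario = scenario or "ssp370"
            if scenario not in SCENARIO_SHIFTS:
                raise ValueError(f"unknown scenario {scenario!r}")
            shift = dict(SCENARIO_SHIFTS[scenario])
            # deterministic inter-GCM spread around the scenario mean
            g = GCM_NAMES.index(model) - 1 if model in GCM_NAMES else 0
            for v, dv in (("bio1", 0.3), ("bio18", 8.0), ("bio19", 10.0)):
                shift[v] = shift.get(v, 0.0) + g * dv
        rng = cfg.rng(203, zlib.crc32(f"{scenario}|{model}".encode()) & 0xFFFF)
        for v, dv in shift.items():
            if v not in base:
                raise KeyError(f"shift names unknown variable {v!r}")
            base[v] = base[v] + dv
        if noise:
            for v in base:
                base[v] = base[v] + _smooth_field(rng, base[v].shape, noise)
        scenario_label = scenario or "custom"
    else:
        scenario_label = "current"
    base.update(_derived_layers(base))
    layers = {name: _raster(base[name]) for name in CLIMATE_VARIABLES}
    return ClimateStack(layers, period=period, scenario=scenario_label,
                        model=model if period == "future" else "")


def simulate_forest(cfg: SimConfig, climate: ClimateStack) -> RasterGrid:
    """Fractional forest cover, denser in the humid west."""
    rng = cfg.rng(204)
    b19 = climate["bio19"].values
    f = (0.15 + 0.62 / (1.0 + np.exp(-(b19 - 350.0) / 80.0))
         + _smooth_field(rng, b19.shape, 0.05))
    return climate.ref.like(np.clip(f, 0.0, 1.0), "fraction")


def simulate_occurrences(cfg: SimConfig, climate: ClimateStack,
                         dem: RasterGrid, n_points: int = 88) -> pd.DataFrame:
    """Occurrence points planted where winter precipitation is high and
    elevation moderate — the ground truth for suitability-recovery tests."""
    rng = cfg.rng(205)
    b19 = climate["bio19"].values
    # sharply peaked climatic niche: high winter precipitation, mid elevation
    w = (1.0 / (1.0 + np.exp(-(b19 - 440.0) / 40.0))) ** 3
    w = w * np.exp(-(((dem.values - 650.0) / 350.0) ** 2))
    p = (w / w.sum()).ravel()
    idx = rng.choice(p.size, size=n_points, replace=False, p=p)
    rows, cols = np.unravel_index(idx, b19.shape)
    g = climate.ref
    lon = g.west + (cols + rng.uniform(0.1, 0.9, n_points)) * g.dx
    lat = g.north - (rows + rng.uniform(0.1, 0.9, n_points)) * g.dy
    return pd.DataFrame({"lon": lon, "lat": lat})


# ---------------------------------------------------------------------------
# ancestry coefficients
# ---------------------------------------------------------------------------

def simulate_ancestry(genotypes: GenotypeTable, climate: ClimateStack,
                      effect: np.ndarray, K: int = 4,
                      covariates: tuple[str, ...] = ("bio1", "bio3", "bio18", "bio19"),
                      sites: pd.DataFrame | None = None) -> AncestryMatrix:
    """Population-level Q matrix whose cluster proportions follow a softmax
    in the climate covariates.

    Cluster k sits at a niche centre ``c_k`` (evenly spaced on [-1, 1]) along
    the climate axis ``d = effect . z``; its logit is
    ``2 d c_k - |effect| c_k**2`` — the quadratic band form, linear in the
    covariates, so each cluster is modal on its own segment of the gradient,
    the modal cluster is monotone along a dominant covariate, and a zero
    effect gives exactly uniform membership.
    """
    effect = np.asarray(effect, dtype=float)
    if effect.shape != (len(covariates),):
        raise ValueError("effect length must match the number of covariates")
    pops = genotypes.pops
    if sites is None:
        cfg = SimConfig(n_pops=len(pops))
        sites = population_sites(cfg)
    sites = sites.set_index("pop").loc[pops]
    table = climate.sample_points(sites["lon"], sites["lat"], covariates)
    z = (table - table.mean()) / table.std(ddof=0).replace(0.0, 1.0)
    drive = z.to_numpy() @ effect                       # (n_pops,)
    centers = np.linspace(-1.0, 1.0, K) if K > 1 else np.zeros(1)
    scale = float(np.linalg.norm(effect))
    logits = 2.0 * np.outer(drive, centers) - scale * centers[None, :] ** 2
    logits -= logits.max(axis=1, keepdims=True)
    Q = np.exp(logits)
    Q /= Q.sum(axis=1, keepdims=True)
    return AncestryMatrix(list(pops), Q)


# ---------------------------------------------------------------------------
# whole world + fixtures
# ---------------------------------------------------------------------------

DEFAULT_ANCESTRY_EFFECT = np.array([0.3, 0.1, 0.4, 1.2])  # bio1 bio3 bio18 bio19


def simulate_world(cfg: SimConfig) -> SyntheticWorld:
    """Generate every input of the end-to-end analysis for one seed."""
    genotypes = simulate_genotypes(cfg)
    climate_current = simulate_climate_stack(cfg, "current")
    futures = {
        scen: [simulate_climate_stack(cfg, "future", scenario=scen, model=g)
               for g in GCM_NAMES]
        for scen in SCENARIO_SHIFTS
    }
    dem = simulate_dem(cfg)
    forest = simulate_forest(cfg, climate_current)
    occurrences = simulate_occurrences(cfg, climate_current, dem)
    sites = population_sites(cfg)
    sites["altitude"] = [dem.sample(lo, la)
                         for lo, la in zip(sites["lon"], sites["lat"])]
    q = simulate_ancestry(genotypes, climate_current, DEFAULT_ANCESTRY_EFFECT,
                          K=cfg.n_clusters, sites=sites)
    truth = dict(genotypes.truth)  # type: ignore[attr-defined]
    truth["ancestry_effect"] = DEFAULT_ANCESTRY_EFFECT.tolist()
    truth["ancestry_covariates"] = ["bio1", "bio3", "bio18", "bio19"]
    truth["config"] = {k: (v if not isinstance(v, np.ndarray) else v.tolist())
                       for k, v in vars(cfg).items()}
    return SyntheticWorld(genotypes, q, climate_current, futures, dem, forest,
                          occurrences, sites, truth)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(world: SyntheticWorld, directory) -> dict:
    """Write every supported file format and return a checksummed manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _add(path: Path) -> None:
        written.append(path)

    gio.write_genepop(world.genotypes, directory / "genotypes.gen")
    _add(directory / "genotypes.gen")
    gio.write_structure(world.genotypes, directory / "genotypes.str")
    _add(directory / "genotypes.str")
    world.sites.to_csv(directory / "sites.csv", index=False)
    _add(directory / "sites.csv")
    world.q_matrix.to_dataframe().to_csv(directory / "qmatrix.csv",
                                         index_label="pop")
    _add(directory / "qmatrix.csv")
    world.occurrences.to_csv(directory / "occurrences.csv", index=False)
    _add(directory / "occurrences.csv")
    gio.write_ascii_grid(world.dem, directory / "dem.asc")
    _add(directory / "dem.asc")
    gio.write_ascii_grid(world.forest, directory / "forest.asc")
    _add(directory / "forest.asc")
    for name, grid in world.climate_current.layers.items():
        p = directory / f"current_{name}.asc"
        gio.write_ascii_grid(grid, p)
        _add(p)
    for scen, stacks in world.climate_future.items():
        for stack in stacks:
            for name, grid in stack.layers.items():
                p = directory / f"{scen}_{stack.model}_{name}.asc"
                gio.write_ascii_grid(grid, p)
                _add(p)
    manifest = {
        "files": {p.name: _checksum(p) for p in sorted(written)},
        "n_files": len(written),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                        sort_keys=True))
    return manifest
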
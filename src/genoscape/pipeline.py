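"""End-to-end orchestration of the eco-genetic prioritization analysis.

Stages run in dependency order on a synthetic world (or user-supplied
files): simulate -> metrics -> landgen -> ne -> enm -> forecast ->
prioritize.  Every output table and raster is written under the configured
output directory and recorded, with a checksum, in ``manifest.json``;
``report.json`` captures the seed, parameters, package versions and stage
timings.  Identical seeds give byte-identical CSV/ASC outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as gio
from .containers import DistMatrix
from .demography import (bottleneck_test, estimate_theta_smm, ld_ne, m_eq_null,
                         m_ratio, theta_to_ne)
from .enm import (altitudinal_stats, climate_pca, compute_tri, ensemble_mean,
                  fit_suitability, threshold_area, vif_filter)
from .forecast import (cluster_persistence, fit_ancestry_climate,
                       project_ancestry, project_ancestry_ensemble,
                       DEFAULT_COVARIATES)
from .landgen import forward_select, pcnm, standardize, variance_partition
from .popgen import ancestry_pca, diversity, pairwise_fst, slatkin_linearize
from .prioritize import (AlleleIncidence, climate_shift_factor,
                         conservation_index, forest_fraction, rank_categories,
                         reserve_selection)
from .synthio import (SimConfig, simulate_world, write_fixtures,
                      CLIMATE_VARIABLES, SCENARIO_SHIFTS)

logger = logging.getLogger("genoscape.pipeline")

ALL_STAGES = ["simulate", "metrics", "landgen", "ne", "enm", "forecast",
              "prioritize"]
#: hard stage dependencies (a stage runs only if its parents ran)
STAGE_DEPS = {"metrics": ["simulate"], "landgen": ["metrics"],
              "ne": ["simulate"], "enm": ["simulate"],
              "forecast": ["enm", "metrics"], "prioritize": ["metrics", "enm"]}


@dataclass
class PipelineConfig:
    """Config of one pipeline run (YAML-serializable)."""

    seed: int = 0
    outdir: str = "genoscape_out"
    force: bool = False
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    # synthetic-world knobs (forwarded to SimConfig)
    sim: dict = field(default_factory=dict)
    # per-stage parameters
    rarefaction_g: int | None = None
    maf_cutoff: float = 0.02
    nperm: int = 999
    nperm_select: int = 999
    nsim_null: int = 2000
    theta_convention: str = "table3"
    suit_thresholds: tuple[float, float] = (0.15, 0.70)
    k_categories: int = 5
    scenarios: list[str] = field(default_factory=lambda: list(SCENARIO_SHIFTS))
    vif_threshold: float = 10.0
    forward_alpha: float = 0.01
    write_climate_fixtures: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run report dict."""
    outdir = Path(config.outdir)
    if outdir.exists() and any(outdir.iterdir()) and not config.force:
        raise FileExistsError(
            f"output directory {outdir} is not empty; pass force=True "
            "(--force) to overwrite")
    outdir.mkdir(parents=True, exist_ok=True)

    requested = [s for s in ALL_STAGES if s in config.stages]
    enabled: list[str] = []
    for s in requested:
        missing = [d for d in STAGE_DEPS.get(s, []) if d not in enabled]
        if missing:
            logger.warning("skipping stage %r: depends on disabled %s",
                           s, missing)
            continue
        enabled.append(s)

    state: dict = {}
    outputs: list[Path] = []
    timings: dict[str, float] = {}
    for stage in enabled:
        t0 = time.perf_counter()
        logger.info("stage %s ...", stage)
        try:
            _RUNNERS[stage](config, state, outdir, outputs)
        except (ValueError, KeyError, FileNotFoundError) as exc:
            raise StageError(stage, str(exc)) from exc
        timings[stage] = round(time.perf_counter() - t0, 3)
        logger.debug("stage %s done in %.2fs", stage, timings[stage])

    manifest = {p.name: _checksum(p) for p in sorted(outputs)}
    (outdir / "manifest.json").write_text(
        json.dumps({"files": manifest}, indent=2, sort_keys=True))
    report = {
        "version": __version__,
        "seed": config.seed,
        "stages": enabled,
        "parameters": {k: v for k, v in asdict(config).items()
                       if k not in {"outdir", "force"}},
        "n_outputs": len(outputs),
        "timings_s": timings,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2,
                                                   default=str))
    return report


def _write_csv(df: pd.DataFrame, path: Path, outputs: list[Path],
               **kw) -> None:
    df.to_csv(path, **kw)
    outputs.append(path)


# ---------------------------------------------------------------------------
# stage runners
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: PipelineConfig, st: dict, out: Path,
                    outputs: list[Path]) -> None:
    sim = SimConfig(seed=cfg.seed, **cfg.sim)
    st["world"] = simulate_world(sim)
    w = st["world"]
    gio.write_genepop(w.genotypes, out / "genotypes.gen")
    outputs.append(out / "genotypes.gen")
    _write_csv(w.sites, out / "sites.csv", outputs, index=False)
    _write_csv(w.q_matrix.to_dataframe(), out / "qmatrix.csv", outputs,
               index_label="pop")
    _write_csv(w.occurrences, out / "occurrences.csv", outputs, index=False)
    if cfg.write_climate_fixtures:
        write_fixtures(w, out / "fixtures")


def _stage_metrics(cfg: PipelineConfig, st: dict, out: Path,
                   outputs: list[Path]) -> None:
    w = st["world"]
    div = diversity(w.genotypes, g=cfg.rarefaction_g)
    _write_csv(div, out / "diversity.csv", outputs)
    fst = pairwise_fst(w.genotypes)
    gio.write_dist_csv(fst, out / "fst.csv")
    outputs.append(out / "fst.csv")
    lin = slatkin_linearize(fst)
    gio.write_dist_csv(lin, out / "fst_linearized.csv")
    outputs.append(out / "fst_linearized.csv")
    scores = ancestry_pca(w.q_matrix)
    _write_csv(scores, out / "ancestry_scores.csv", outputs, index_label="pop")
    st.update(diversity=div, fst=fst, lin=lin, anc_scores=scores)


def _pop_climate(world, variables=None) -> pd.DataFrame:
    variables = variables or CLIMATE_VARIABLES
    tab = world.climate_current.sample_points(world.sites["lon"],
                                              world.sites["lat"], variables)
    tab.index = pd.Index(world.sites["pop"], name="pop")
    return tab


def _stage_landgen(cfg: PipelineConfig, st: dict, out: Path,
                   outputs: list[Path]) -> None:
    w = st["world"]
    lin: DistMatrix = st["lin"]
    clim_tab = _pop_climate(w)
    clim_z = standardize(clim_tab)
    sel = forward_select(lin, clim_z, alpha=cfg.forward_alpha,
                         nperm=cfg.nperm_select, seed=cfg.seed)
    _write_csv(sel, out / "forward_selection.csv", outputs, index=False)
    chosen = sel.attrs["selected"] or list(clim_z.columns[:2])
    clim_block = clim_z[chosen]

    geo_block = standardize(
        w.sites.set_index("pop")[["lon", "lat"]].loc[lin.labels])
    tri = compute_tri(w.dem)
    tri_at = np.array([tri.sample(lo, la)
                       for lo, la in zip(w.sites["lon"], w.sites["lat"])])
    tri_d = DistMatrix(lin.labels, np.abs(np.subtract.outer(tri_at, tri_at)),
                       "tri")
    oro_block = standardize(pcnm(tri_d).iloc[:, :1])
    anc_block = standardize(st["anc_scores"])

    blocks = {"clim": clim_block, "geo": geo_block, "oro": oro_block,
              "anc": anc_block}
    tables = variance_partition(lin, blocks, nperm=cfg.nperm, seed=cfg.seed,
                                cascade=True)
    for i, tab in enumerate(tables, start=1):
        _write_csv(tab.round(6), out / f"variance_partition_model{i}.csv",
                   outputs, index=False)
    st["partition"] = tables


def _stage_ne(cfg: PipelineConfig, st: dict, out: Path,
              outputs: list[Path]) -> None:
    w = st["world"]
    gt = w.genotypes
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 77])
    rows = []
    for pop in gt.pops:
        est = ld_ne(gt, pop, maf_cutoff=cfg.maf_cutoff)
        theta = estimate_theta_smm(gt, pop)
        ne_coal = theta_to_ne(theta, SimConfig().mutation_rate,
                              cfg.theta_convention)
        per_m, m_obs = m_ratio(gt, pop, repeat_unit=2)
        null = m_eq_null(theta, nsim=cfg.nsim_null,
                         n_gene_copies=2 * int((gt.populations == pop).sum()),
                         rng=rng)
        m_eq = float(null.mean())
        p = bottleneck_test(np.array(list(per_m.values())),
                            np.full(len(per_m), m_eq))
        rows.append({"pop": pop, "Ne_LD": round(est.ne_ld, 1),
                     "CI_low": round(est.ci_low, 1),
                     "CI_high": round(est.ci_high, 1),
                     "theta": round(theta, 4), "Ne_COAL": ne_coal,
                     "MR": round(m_obs, 3), "MReq": round(m_eq, 3),
                     "p_value": round(p, 4)})
    tab = pd.DataFrame(rows)
    _write_csv(tab, out / "effective_size.csv", outputs, index=False)
    st["ne_table"] = tab


def _stage_enm(cfg: PipelineConfig, st: dict, out: Path,
               outputs: list[Path]) -> None:
    w = st["world"]
    thr_lo, thr_hi = cfg.suit_thresholds

    # collinearity screen on the landscape cell table
    cell_tab = w.climate_current.as_table()
    sub = cell_tab.sample(min(len(cell_tab), 1000),
                          random_state=cfg.seed & 0x7FFFFFFF)
    retained, drop_log = vif_filter(sub, threshold=cfg.vif_threshold)
    _write_csv(drop_log, out / "vif_drop_log.csv", outputs, index=False)

    res = fit_suitability(w.occurrences, w.climate_current, seed=cfg.seed)
    st["sdm"] = res
    gio.write_ascii_grid(res.map.grid, out / "suitability_current.asc")
    outputs.append(out / "suitability_current.asc")

    dem = w.dem
    cur_a15 = threshold_area(res.map, thr_lo)
    cur_a70 = threshold_area(res.map, thr_hi)
    cur_alt = altitudinal_stats(res.map, dem, thr_lo)
    rows = [{"scenario": "current", "AUC": round(res.auc, 3),
             "TSS": round(res.tss, 3),
             f"area_km2_ge{int(thr_lo * 100)}": round(cur_a15),
             f"change_km2_ge{int(thr_lo * 100)}": 0,
             f"area_km2_ge{int(thr_hi * 100)}": round(cur_a70),
             f"change_km2_ge{int(thr_hi * 100)}": 0,
             "alt_min": round(cur_alt.min) if not cur_alt.empty else None,
             "alt_mean": round(cur_alt.mean) if not cur_alt.empty else None,
             "alt_max": round(cur_alt.max) if not cur_alt.empty else None}]
    ensembles = {}
    for scen in cfg.scenarios:
        maps = [res.project(stack) for stack in w.climate_future[scen]]
        ens = ensemble_mean(maps)
        ensembles[scen] = ens
        gio.write_ascii_grid(ens.grid, out / f"suitability_{scen}.asc")
        outputs.append(out / f"suitability_{scen}.asc")
        a15 = threshold_area(ens, thr_lo)
        a70 = threshold_area(ens, thr_hi)
        alt = altitudinal_stats(ens, dem, thr_lo)
        rows.append({"scenario": scen, "AUC": round(res.auc, 3),
                     "TSS": round(res.tss, 3),
                     f"area_km2_ge{int(thr_lo * 100)}": round(a15),
                     f"change_km2_ge{int(thr_lo * 100)}": round(a15 - cur_a15),
                     f"area_km2_ge{int(thr_hi * 100)}": round(a70),
                     f"change_km2_ge{int(thr_hi * 100)}": round(a70 - cur_a70),
                     "alt_min": round(alt.min) if not alt.empty else None,
                     "alt_mean": round(alt.mean) if not alt.empty else None,
                     "alt_max": round(alt.max) if not alt.empty else None})
    _write_csv(pd.DataFrame(rows), out / "range_projection.csv", outputs,
               index=False)
    st["ensembles"] = ensembles

    # climate-space PCA of the populations + ecoplot tables
    pop_clim = _pop_climate(w, ["bio1", "bio3", "bio4", "bio8", "bio9",
                                "bio15", "bio18", "bio19"])
    pca = climate_pca(pop_clim)
    _write_csv(pca["scores"].round(6), out / "climate_pca_scores.csv", outputs)
    _write_csv(pca["loadings"].round(6), out / "climate_pca_loadings.csv",
               outputs)
    _write_csv(pca["variance_fraction"].round(6).to_frame("fraction"),
               out / "climate_pca_variance.csv", outputs)
    eco = _pop_climate(w, ["bio18", "bio19", "aridityIndexThornthwaite",
                           "climaticMoistureIndex"])
    _write_csv(eco.round(4), out / "ecoplot.csv", outputs)
    tri = compute_tri(w.dem)
    gio.write_ascii_grid(tri, out / "tri.asc")
    outputs.append(out / "tri.asc")


def _stage_forecast(cfg: PipelineConfig, st: dict, out: Path,
                    outputs: list[Path]) -> None:
    w = st["world"]
    thr_lo = cfg.suit_thresholds[0]
    covs = _pop_climate(w, list(DEFAULT_COVARIATES))
    fit = fit_ancestry_climate(w.q_matrix, covs)
    st["ancestry_fit"] = fit
    cur_map = project_ancestry(fit, w.climate_current, mask=st["sdm"].map,
                               threshold=thr_lo)
    gio.write_ascii_grid(cur_map, out / "clusters_current.asc")
    outputs.append(out / "clusters_current.asc")
    reports = []
    for scen in cfg.scenarios:
        fut_map = project_ancestry_ensemble(fit, w.climate_future[scen],
                                            mask=st["ensembles"][scen],
                                            threshold=thr_lo)
        gio.write_ascii_grid(fut_map, out / f"clusters_{scen}.asc")
        outputs.append(out / f"clusters_{scen}.asc")
        rep = cluster_persistence(cur_map, fut_map, K=fit.K)
        rep.insert(0, "scenario", scen)
        rep["entropy_current"] = round(rep.attrs["entropy_current"], 4)
        rep["entropy_future"] = round(rep.attrs["entropy_future"], 4)
        reports.append(rep)
    _write_csv(pd.concat(reports, ignore_index=True),
               out / "cluster_persistence.csv", outputs, index=False)


def _stage_prioritize(cfg: PipelineConfig, st: dict, out: Path,
                      outputs: list[Path]) -> None:
    w = st["world"]
    inc = AlleleIncidence.from_genotypes(w.genotypes)
    sel = reserve_selection(inc)
    _write_csv(sel.round(4), out / "reserve_selection.csv", outputs,
               index=False)

    scen = "ssp585" if "ssp585" in cfg.scenarios else cfg.scenarios[-1]
    fut_stacks = w.climate_future[scen]
    div = st["diversity"]
    rows = []
    for _, site in w.sites.iterrows():
        pop, lo, la = site["pop"], site["lon"], site["lat"]
        f_c = forest_fraction(w.forest, lo, la, radius_km=20.0)
        cur = {v: w.climate_current[v].sample(lo, la)
               for v in ("bio18", "bio19")}
        fut = {v: float(np.mean([s[v].sample(lo, la) for s in fut_stacks]))
               for v in ("bio18", "bio19")}
        c_l = climate_shift_factor(cur, fut)
        a_r = float(div.loc[pop, "A_r"])
        c_i = conservation_index(a_r, f_c, c_l)
        rows.append({"pop": pop, "lat": la, "lon": lo,
                     "altitude": round(site.get("altitude", np.nan), 1),
                     "A_r": round(a_r, 3), "F_c": round(f_c, 4),
                     "C_l": round(c_l, 4), "C_i": round(c_i, 4)})
    tab = pd.DataFrame(rows).set_index("pop")
    tab["category"] = rank_categories(tab["C_i"], k=cfg.k_categories,
                                      method="rank")
    _write_csv(tab, out / "prioritization.csv", outputs)

    features = [{
        "type": "Feature",
        "geometry": {"type": "Point",
                     "coordinates": [round(r["lon"], 6), round(r["lat"], 6)]},
        "properties": {"pop": p, "C_i": r["C_i"], "category": int(r["category"])},
    } for p, r in tab.iterrows()]
    gj = {"type": "FeatureCollection", "features": features}
    path = out / "prioritization.geojson"
    path.write_text(json.dumps(gj, indent=1, sort_keys=True))
    outputs.append(path)
    st["priority"] = tab


_RUNNERS = {
    "simulate": _stage_simulate,
    "metrics": _stage_metrics,
    "landgen": _stage_landgen,
    "ne": _stage_ne,
    "enm": _stage_enm,
    "forecast": _stage_forecast,
    "prioritize": _stage_prioritize,
}
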
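"""End-to-end orchestration: data -> SIR -> autocorrelation -> model
ladder -> selection -> interaction surface -> sensitivity grid.

Outputs are written to a config-hash-named directory (no timestamps),
so a rerun with identical config and seed reproduces the bundle
byte-for-byte.  The model-selection rule is the double criterion:
the model with the lowest DIC *and* lowest WAIC is selected; if the two
criteria disagree the run is flagged ``discordant`` and both are
reported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geo_weights, spatial_stats, standardize, synthetic_data
from .bayes_stmodel import (ModelSpec, PriorSpec, dic, fit_mcmc,
                            pit_histogram, waic)

__all__ = ["RunConfig", "model_ladder", "run_pipeline", "sensitivity_grid",
           "sensitivity_settings", "DELTA_BIN_EDGES", "bin_delta"]

logger = logging.getLogger(__name__)

# interaction-surface map legend (closed-open conventions as printed)
DELTA_BIN_EDGES = (-1.5, -1.0, -0.5, 0.0, 0.5, 1.0, 1.5, 2.2)
DELTA_BIN_LABELS = ("[-1.5,-1.0]", "(-1.0,-0.5]", "(-0.5,0.0]", "(0.0,0.5]",
                    "(0.5,1.0]", "(1.0,1.5]", "(1.5,2.2]")


def model_ladder() -> dict[str, ModelSpec]:
    """The default four-model comparison ladder.

    * ``eq6_spatial`` — pure spatial BYM (structured + unstructured);
    * ``eq7_temporal`` — pure temporal RW1 + iid;
    * ``model11`` — BYM + RW1 + iid + Besag x RW1 interaction with
      loggamma(1, 0.0005) precisions;
    * ``model12`` — BYM2 + AR(1) + iid + Type IV interaction with PC
      priors (the headline specification).
    """
    lg = PriorSpec("loggamma", (1.0, 5e-4))
    return {
        "eq6_spatial": ModelSpec(spatial="bym", temporal_structured="none",
                                 temporal_iid="none", interaction="none"),
        "eq7_temporal": ModelSpec(spatial="none", temporal_structured="rw1",
                                  temporal_iid="iid", interaction="none",
                                  priors={"tau_phi": lg}),
        "model11": ModelSpec(spatial="bym", temporal_structured="rw1",
                             temporal_iid="iid", interaction="typeIV",
                             priors={"tau_phi": lg, "tau_delta": lg}),
        "model12": ModelSpec(),
    }


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs; serializable to/from YAML."""

    # inputs: either file paths or a named synthetic scenario
    geojson: str | None = None
    panel_csv: str | None = None
    composition_csv: str | None = None
    rates_csv: str | None = None
    scenario: str | None = "paper"        # paper | null | None
    # autocorrelation settings
    n_perm: int = 999
    alpha: float = 0.05
    st_scheme: str = "contemporaneous+lag1self"
    # model ladder and MCMC settings
    ladder: tuple[str, ...] = ("eq6_spatial", "eq7_temporal", "model12")
    chains: int = 2
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    quick: bool = False                   # 2 x 2000 iterations, for smoke runs
    seed: int = 0
    out_dir: str = "stmap_out"

    def mcmc_kwargs(self) -> dict:
        if self.quick:
            return {"chains": 2, "iterations": 2000, "burn_in": 1000,
                    "thin": 2}
        return {"chains": self.chains, "iterations": self.iterations,
                "burn_in": self.burn_in, "thin": self.thin}

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ladder" in raw:
            raw["ladder"] = tuple(raw["ladder"])
        return cls(**raw)


def bin_delta(values: np.ndarray) -> list[str]:
    """Bin interaction effects with the fixed map-legend edges; values
    outside the legend range are labelled ``<-1.5`` / ``>2.2``."""
    labels = []
    e = DELTA_BIN_EDGES
    for x in np.asarray(values, float).ravel():
        if x < e[0]:
            labels.append("<-1.5")
        elif x > e[-1]:
            labels.append(">2.2")
        elif x <= e[1]:
            labels.append(DELTA_BIN_LABELS[0])
        else:
            k = int(np.searchsorted(np.asarray(e[1:-1]), x, side="left"))
            labels.append(DELTA_BIN_LABELS[k])
    return labels


def _load_inputs(config: RunConfig):
    if config.scenario is not None:
        if config.scenario == "paper":
            scfg = synthetic_data.paper_scenario(seed=config.seed)
        elif config.scenario == "null":
            scfg = synthetic_data.null_scenario(seed=config.seed)
        else:
            raise ValueError(f"unknown scenario {config.scenario!r}")
        ds = synthetic_data.generate_dataset(scfg)
        return ds.graph, ds.provinces, ds.panel, ds.composition, ds.rates, \
            ds.geojson
    for name in ("geojson", "panel_csv", "composition_csv", "rates_csv"):
        if getattr(config, name) is None:
            raise ValueError(f"no scenario and no {name} input")
    geoms, provinces = geo_weights.read_region_geojson(config.geojson)
    graph = geo_weights.build_queen_adjacency(geoms)
    panel = pd.read_csv(config.panel_csv, dtype={"city_id": str,
                                                 "province_id": str})
    comp = pd.read_csv(config.composition_csv, dtype={"province_id": str})
    rates = standardize.ReferenceRates.from_csv(config.rates_csv)
    with open(config.geojson) as fh:
        fc = json.load(fh)
    return graph, provinces, panel, comp, rates, fc


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _annotated_geojson(fc: dict, fields: dict[str, dict[str, object]],
                       path: Path) -> None:
    out = json.loads(json.dumps(fc))  # deep copy
    for feat in out["features"]:
        cid = str(feat["properties"]["city_id"])
        for name, mapping in fields.items():
            feat["properties"][name] = mapping.get(cid)
    path.write_text(json.dumps(out, sort_keys=True))


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns a report dict and writes the bundle."""
    t0 = time.perf_counter()
    timings: dict[str, float] = {}
    out = Path(config.out_dir) / config.config_hash()
    out.mkdir(parents=True, exist_ok=True)

    graph, provinces, panel, comp, rates, fc = _load_inputs(config)
    years = sorted(panel["year"].unique())
    cities = list(graph.region_ids)
    timings["load"] = time.perf_counter() - t0

    # --- SIR ---------------------------------------------------------------
    t = time.perf_counter()
    sir_tab = standardize.compute_sir_panel(panel, comp, rates)
    _write_csv(sir_tab[["city_id", "year", "E", "SIR"]], out / "sir.csv")
    sir_mat = sir_tab.pivot(index="city_id", columns="year", values="SIR") \
        .loc[cities, years].to_numpy()
    o_mat = sir_tab.pivot(index="city_id", columns="year", values="cases") \
        .loc[cities, years].to_numpy()
    e_mat = sir_tab.pivot(index="city_id", columns="year", values="E") \
        .loc[cities, years].to_numpy()
    timings["sir"] = time.perf_counter() - t

    # --- autocorrelation suite ----------------------------------------------
    t = time.perf_counter()
    w_bin = geo_weights.binary_weights(graph)
    w_row = geo_weights.row_standardize(w_bin)
    geo_weights.write_edges_csv(graph, str(out / "edges.csv"))
    moran_rows = []
    lisa_fields: dict[str, dict] = {}
    gi_fields: dict[str, dict] = {}
    for j, year in enumerate(years):
        vals = sir_mat[:, j]
        mres = spatial_stats.global_morans_i(vals, w_row,
                                             n_perm=config.n_perm,
                                             seed=config.seed + j)
        moran_rows.append({"year": int(year), "moran_i": float(mres.I),
                           "expected_i": float(mres.expected_I),
                           "z": float(mres.z), "p": float(mres.p)})
        lres = spatial_stats.lisa(vals, w_row, n_perm=config.n_perm,
                                  alpha=config.alpha, seed=config.seed + j)
        gres = spatial_stats.gi_star(vals, graph)
        lisa_fields[f"lisa_{year}"] = dict(zip(cities, lres.category))
        gi_fields[f"gi_{year}"] = dict(zip(cities, gres.bin))
    _write_csv(pd.DataFrame(moran_rows), out / "moran_by_year.csv")
    _annotated_geojson(fc, lisa_fields, out / "lisa.geojson")
    _annotated_geojson(fc, gi_fields, out / "gistar.geojson")

    stw = geo_weights.build_st_weights(graph, years, scheme=config.st_scheme)
    st_res = spatial_stats.st_morans_i(sir_mat, stw, n_perm=config.n_perm,
                                       seed=config.seed)
    _write_csv(pd.DataFrame([{"moran_st": st_res.I, "z": st_res.z,
                              "p": st_res.p, "n": st_res.n, "T": st_res.T,
                              "scheme": st_res.scheme}]),
               out / "moran_st.csv")
    timings["autocorrelation"] = time.perf_counter() - t

    # --- model ladder --------------------------------------------------------
    t = time.perf_counter()
    ladder = model_ladder()
    unknown = set(config.ladder) - set(ladder)
    if unknown:
        raise ValueError(f"unknown ladder models: {sorted(unknown)}")
    fits, rows = {}, []
    for name in config.ladder:
        spec = ladder[name]
        fit = fit_mcmc(o_mat, e_mat, spec, graph, seed=config.seed,
                       **config.mcmc_kwargs())
        d, p_d = dic(fit)
        w, p_w = waic(fit)
        fits[name] = (fit, d, w)
        summ = fit.summary()
        for _, r in summ.iterrows():
            rows.append({"model": name, "parameter": r["parameter"],
                         "posterior_mean": r["mean"], "sd": r["sd"],
                         "ci_low": r["q2.5"], "ci_high": r["q97.5"],
                         "rhat": r["rhat"], "DIC": d, "WAIC": w})
    comparison = pd.DataFrame(rows)
    _write_csv(comparison, out / "model_comparison.csv")
    timings["ladder"] = time.perf_counter() - t

    # --- selection -----------------------------------------------------------
    by_dic = min(fits, key=lambda k: fits[k][1])
    by_waic = min(fits, key=lambda k: fits[k][2])
    discordant = by_dic != by_waic
    selected = by_dic
    if discordant:
        logger.warning("discordant selection: DIC prefers %s, WAIC prefers %s",
                       by_dic, by_waic)
    sel_fit = fits[selected][0]

    sel = sel_fit.summary()
    _write_csv(sel.assign(model=selected), out / "selected_model.csv")
    if "delta" in sel_fit.draws:
        dmean = sel_fit.delta_mean()
        ddf = pd.DataFrame({
            "city_id": np.repeat(cities, len(years)),
            "year": np.tile(years, len(cities)),
            "delta_mean": dmean.ravel(),
            "bin": bin_delta(dmean)})
        _write_csv(ddf, out / "delta_surface.csv")
    counts, edges = pit_histogram(sel_fit, seed=config.seed)
    _write_csv(pd.DataFrame({"bin_low": edges[:-1], "bin_high": edges[1:],
                             "count": counts}), out / "pit_histogram.csv")
    timings["selection"] = time.perf_counter() - t0

    report = {
        "out_dir": str(out),
        "selected": selected,
        "selected_by_dic": by_dic,
        "selected_by_waic": by_waic,
        "discordant": discordant,
        "dic": {k: fits[k][1] for k in fits},
        "waic": {k: fits[k][2] for k in fits},
        "converged": sel_fit.converged,
        "moran_by_year": moran_rows,
        "moran_st": st_res.I,
        "timings": timings,
    }
    (out / "report.json").write_text(json.dumps(report, indent=2,
                                                sort_keys=True))
    for stage, dt in timings.items():
        logger.info("stage %-16s %.2fs", stage, dt)
    if not sel_fit.converged:
        logger.warning("selected model %s failed convergence checks", selected)
    return report


# --- sensitivity grid --------------------------------------------------------

_PREC_AXES = ("tau_b", "tau_gamma", "tau_phi", "tau_delta")
_PREC_U = (0.5, 1.0, 2.0)
_PREC_ALPHA = (0.01, 0.05, 0.1)
_OMEGA_U = (0.3, 0.5, 0.7)
_RHO_U = (0.1, 0.2, 0.4)
_RHO_ALPHA = 0.2


def sensitivity_settings(baseline: ModelSpec | None = None
                         ) -> list[dict]:
    """Enumerate the one-axis-at-a-time prior grid (42 settings).

    Four precision parameters each get the 3x3 pc_prec(U, alpha) grid;
    the BYM2 mixing gets three thresholds at its baseline alpha; the
    AR(1) coefficient gets three pc_cor0 thresholds at alpha = 0.2.
    All other priors stay at baseline.
    """
    baseline = baseline or ModelSpec()
    rows: list[dict] = []
    for param in _PREC_AXES:
        for u in _PREC_U:
            for a in _PREC_ALPHA:
                rows.append({"param": param,
                             "prior": PriorSpec("pc_prec", (u, a))})
    base_omega_alpha = baseline.priors["omega"].params[1]
    for u in _OMEGA_U:
        rows.append({"param": "omega",
                     "prior": PriorSpec("pc_mix", (u, base_omega_alpha))})
    for u in _RHO_U:
        rows.append({"param": "rho",
                     "prior": PriorSpec("pc_cor0", (u, _RHO_ALPHA))})
    baseline_priors = baseline.priors
    for row in rows:
        base = baseline_priors.get(row["param"])
        row["is_baseline"] = base is not None and base == row["prior"]
    return rows


def sensitivity_grid(config: RunConfig,
                     baseline: ModelSpec | None = None) -> pd.DataFrame:
    """Refit the baseline model across the prior grid; failed cells are
    marked and the grid completes."""
    baseline = baseline or ModelSpec()
    graph, provinces, panel, comp, rates, fc = _load_inputs(config)
    years = sorted(panel["year"].unique())
    cities = list(graph.region_ids)
    sir_tab = standardize.compute_sir_panel(panel, comp, rates)
    o_mat = sir_tab.pivot(index="city_id", columns="year", values="cases") \
        .loc[cities, years].to_numpy()
    e_mat = sir_tab.pivot(index="city_id", columns="year", values="E") \
        .loc[cities, years].to_numpy()

    rows = []
    for setting in sensitivity_settings(baseline):
        param, prior = setting["param"], setting["prior"]
        spec = ModelSpec(spatial=baseline.spatial,
                         temporal_structured=baseline.temporal_structured,
                         temporal_iid=baseline.temporal_iid,
                         interaction=baseline.interaction,
                         priors={**dict(baseline.priors), param: prior})
        rec = {"param": param, "family": prior.family,
               "U": prior.params[0], "alpha": prior.params[1],
               "is_baseline": setting["is_baseline"], "failed": False,
               "DIC": np.nan, "WAIC": np.nan, "omega_mean": np.nan,
               "tau_delta_mean": np.nan}
        try:
            fit = fit_mcmc(o_mat, e_mat, spec, graph, seed=config.seed,
                           **config.mcmc_kwargs())
            rec["DIC"], _ = dic(fit)
            rec["WAIC"], _ = waic(fit)
            if "omega" in fit.draws:
                rec["omega_mean"] = float(fit.pooled("omega").mean())
            if "tau_delta" in fit.draws:
                rec["tau_delta_mean"] = float(
                    fit.pooled("tau_delta").mean())
        except Exception as exc:  # noqa: BLE001 - grid must complete
            logger.warning("sensitivity cell %s/%s failed: %s",
                           param, prior.params, exc)
            rec["failed"] = True
        rows.append(rec)
    grid = pd.DataFrame(rows)
    ok = grid[~grid["failed"]]
    if len(ok):
        logger.info("DIC spread across grid (max-min): %.2f",
                    ok["DIC"].max() - ok["DIC"].min())
    out = Path(config.out_dir) / config.config_hash()
    out.mkdir(parents=True, exist_ok=True)
    _write_csv(grid, out / "sensitivity_grid.csv")
    return grid
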
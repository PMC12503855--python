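"""End-to-end orchestration: census -> rates -> matrices -> SPEI -> FLM -> PVA.

All randomness flows from one root seed split per module, so a rerun
with the same configuration and seed writes identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rametdemog import census, flm, mpm, pva, reporting, synthetic, weather
from rametdemog.census import STAGES
from rametdemog.vital_rates import assemble_vital_rates

log = logging.getLogger("rametdemog")


@dataclass
class SiteConfig:
    name: str
    latitude: float
    n_plots: int = 4


@dataclass
class PipelineConfig:
    sites: list
    seed: int = 1
    outdir: str = "out"
    census_years: tuple = (1990, 2009)
    weather_years: tuple = (1950, 2009)
    reference_period: tuple = weather.REFERENCE_PERIOD
    synthetic: bool = True
    census_csv: str | None = None
    weather_csv: str | None = None
    pva_horizon: int = 50
    pva_replicates: int = 1000
    pva_n0: float = 50.0
    flm_battery: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sites = [SiteConfig(name=s["name"], latitude=s["latitude"],
                            n_plots=s.get("n_plots", 4))
                 for s in raw.pop("sites")]
        raw = {k: tuple(v) if isinstance(v, list) else v
               for k, v in raw.items()}
        return cls(sites=sites, **raw)

    def digest(self) -> str:
        payload = json.dumps(
            {k: (v if not isinstance(v, list) else [vars(s) for s in v])
             for k, v in vars(self).items()}, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def demo_truth(dry: bool = True) -> synthetic.TruthParameters:
    """Truth parameters for the bundled two-site synthetic study.

    The drier site carries lag kernels linking seedling recruitment and
    SR survival to precipitation and flowering to temperature; the
    wetter site only the recruitment kernel, echoing the asymmetry the
    method is meant to detect.
    """
    L = synthetic.TruthParameters().L
    k_rec = np.zeros(L + 1)
    k_rec[:12] = 0.30          # wet winter/spring boosts germination
    kernels = {(("rec", "Sd_rec"), "panom"): k_rec}
    if dry:
        k_surv = np.zeros(L + 1)
        k_surv[:14] = 0.12     # cumulative precipitation aids survival
        k_flow = np.zeros(L + 1)
        k_flow[12:19] = 0.15   # warm previous season promotes flowering
        kernels[(("SR", "survival"), "panom")] = k_surv
        kernels[(("SR", "flowering"), "tanom")] = k_flow
    return synthetic.TruthParameters(lag_kernels=kernels)


def battery_responses(table: census.TransitionTable,
                      lambdas: dict[int, float]) -> dict:
    """Assemble the per-site FLM response set: binomial survival and
    transition arrows, Poisson recruitment classes, Gaussian log
    lambda.  Years with zero trials/exposure are dropped per response."""
    out = {}
    counts = table.counts
    years = sorted(counts.index.get_level_values("year").unique())
    for origin in census.ORIGIN_STAGES:
        rows = {y: counts.loc[(y, origin)] for y in years
                if (y, origin) in counts.index}
        if not rows:
            continue
        yy = np.array(sorted(rows))
        totals = np.array([rows[y].sum() for y in yy])
        keep = totals > 0
        if keep.sum() < 10:
            continue
        surv = np.array([rows[y].sum() - rows[y]["DEAD"] for y in yy])
        out[f"delta_{origin}"] = {"family": "binomial", "years": yy[keep],
                                  "y": surv[keep], "trials": totals[keep]}
        for fate in census.FATE_STAGES[:-1]:
            k = np.array([rows[y][fate] for y in yy])
            if k.sum() == 0:
                continue
            out[f"{origin}_to_{fate}"] = {
                "family": "binomial", "years": yy[keep],
                "y": k[keep], "trials": totals[keep]}
    first_year = int(table.exposures["year"].min())
    rec = table.recruits
    for cls in ("Sd_rec", "SR_rec", "MR_rec", "SF_rec", "MF_rec"):
        expo_fn = table.flowering_at if cls == "Sd_rec" else table.sprout_pool_at
        yy, kk, ee = [], [], []
        for y in years:
            e = expo_fn(int(y))
            if e <= 0 or y + 1 <= first_year:
                continue
            yy.append(y)
            kk.append(int(rec.query("year == @y + 1 and rec_class == @cls")
                          ["n"].sum()))
            ee.append(e)
        if len(yy) >= 10 and sum(kk) > 0:
            out[cls] = {"family": "poisson", "years": np.array(yy),
                        "y": np.array(kk), "exposure": np.array(ee),
                        "L": flm.SEEDLING_L if cls == "Sd_rec" else flm.DEFAULT_L}
    lam_years = np.array(sorted(lambdas))
    lam = np.array([lambdas[y] for y in lam_years])
    ok = lam > 0
    if ok.sum() >= 10:
        out["log_lambda"] = {"family": "gaussian", "years": lam_years[ok],
                             "y": np.log(lam[ok])}
    return out


@dataclass
class SiteResult:
    site: str
    records: pd.DataFrame
    table: census.TransitionTable
    vital_rates: object
    matrices: dict
    lambdas: dict
    transients: dict
    ssd_mean: np.ndarray
    mean_mat: mpm.ProjectionMatrix
    spei_df: pd.DataFrame
    annual_spei: dict
    flm_table: pd.DataFrame | None = None
    flm_fits: dict | None = None
    pva_results: dict | None = None
    pva_table: pd.DataFrame | None = None
    densities: pd.DataFrame | None = None


def analyze_site(site_cfg: SiteConfig, records: pd.DataFrame,
                 weather_df: pd.DataFrame, cfg: PipelineConfig,
                 seed) -> SiteResult:
    """Run the full per-site analysis chain on resolved census records."""
    site = site_cfg.name
    log.info("[%s] resolving fates (%d raw records)", site, len(records))
    resolved = census.resolve_fates(records)
    table = census.tabulate_transitions(resolved, site)
    log.info("[%s] %d transition-years", site, len(table.counts))

    vr = assemble_vital_rates(table)
    matrices = {}
    lambdas = {}
    for y in vr.years:
        pm = mpm.build_annual_matrix(vr.year_row(int(y)), site=site, year=int(y))
        matrices[int(y)] = pm
        lambdas[int(y)] = mpm.asymptotic_lambda(pm)
    mean_mat = mpm.mean_matrix(list(matrices.values()))
    ssd_mean = mpm.stable_stage_distribution(mean_mat)

    totals = (resolved[resolved["stage"].isin(STAGES)]
              .groupby("year").size().sort_index())
    transients = {}
    for y in vr.years:
        y = int(y)
        if y in totals.index and y + 1 in totals.index and totals[y] > 0:
            transients[y] = mpm.transient_growth(totals[y], totals[y + 1])

    spei_df = weather.site_spei(weather_df, site_cfg.latitude,
                                reference=cfg.reference_period)
    annual_spei = {int(y): weather.annual_mean_spei(spei_df, int(y))
                   for y in vr.years}

    flm_table = flm_fits = None
    if cfg.flm_battery:
        monthly = weather.monthly_anomalies(weather_df, cfg.reference_period)
        monthly = monthly.merge(spei_df[["year", "month", "spei"]],
                                on=["year", "month"])
        responses = battery_responses(table, lambdas)
        flm_table, flm_fits = flm.run_flm_battery(site, responses, monthly)
        log.info("[%s] FLM battery: %d fits, %d significant", site,
                 len(flm_table), int((flm_table["p_overall"] < 0.01).sum()))

    drought, wet = pva.partition_matrices(matrices, annual_spei)
    scenarios = tuple(
        pva.ScenarioSpec(s.name, s.p_drought, horizon=cfg.pva_horizon,
                         replicates=cfg.pva_replicates, n0=cfg.pva_n0)
        for s in pva.DEFAULT_SCENARIOS)
    start = cfg.pva_n0 * ssd_mean
    pva_results, pva_table = pva.run_all_scenarios(
        drought, wet, seed, scenarios=scenarios, start=start)
    pva_table.insert(0, "site", site)

    densities = reporting.summarize_densities(resolved, site)
    return SiteResult(site=site, records=resolved, table=table, vital_rates=vr,
                      matrices=matrices, lambdas=lambdas,
                      transients=transients, ssd_mean=ssd_mean,
                      mean_mat=mean_mat, spei_df=spei_df,
                      annual_spei=annual_spei, flm_table=flm_table,
                      flm_fits=flm_fits, pva_results=pva_results,
                      pva_table=pva_table, densities=densities)


def run_full_pipeline(cfg: PipelineConfig) -> dict[str, SiteResult]:
    """Generate or load inputs, analyze every site, write the outputs."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.default_rng(cfg.seed)
    site_seeds = root.spawn(2 * len(cfg.sites) + 1)
    header = {"config_sha": cfg.digest(), "seed": cfg.seed}

    results = {}
    for i, site_cfg in enumerate(cfg.sites):
        if cfg.synthetic:
            truth = demo_truth(dry=(i == 0))
            wdf = synthetic.gen_weather(site_cfg.name, cfg.weather_years[0],
                                        cfg.weather_years[1], truth,
                                        site_seeds[2 * i])
            plots = [f"P{j + 1}" for j in range(site_cfg.n_plots)]
            records, truth_log = synthetic.gen_population(
                site_cfg.name, plots, cfg.census_years[0], cfg.census_years[1],
                truth, wdf, site_seeds[2 * i + 1])
            truth_log.to_json(outdir / f"{site_cfg.name}_truth.json")
        else:
            records = census.read_census_csv(cfg.census_csv)
            records = records[records["site"] == site_cfg.name]
            wdf = pd.read_csv(cfg.weather_csv)
            wdf = wdf[wdf["site"] == site_cfg.name]
        res = analyze_site(site_cfg, records, wdf, cfg, site_seeds[-1])
        results[site_cfg.name] = res
        _write_site_outputs(res, outdir, header)

    dens = pd.concat([r.densities for r in results.values()])
    dens.to_csv(outdir / "densities.csv", index=False)
    if len(results) == 2:
        a, b = results.values()
        rows = []
        for metric in dens["density"].unique():
            va = _plot_year_counts(a, metric)
            vb = _plot_year_counts(b, metric)
            try:
                t, p = reporting.compare_sites(va, vb)
            except reporting.ReportingError:
                t, p = np.nan, np.nan
            rows.append((metric, t, p))
        pd.DataFrame(rows, columns=["density", "t", "p"]).to_csv(
            outdir / "site_comparison.csv", index=False)
    with open(outdir / "run_info.json", "w") as fh:
        json.dump(header, fh, indent=1)
    return results


def _plot_year_counts(res: SiteResult, metric: str) -> np.ndarray:
    dens = reporting.summarize_densities(res.records, res.site)
    # recompute raw per-plot-year vectors for the t-test
    sub = res.records[res.records["stage"].isin(STAGES)]
    plots = sorted(sub["plot"].unique())
    years = sorted(sub["year"].unique())
    idx = pd.MultiIndex.from_product([years, plots], names=["year", "plot"])
    if metric == "all_ramets":
        c = sub.groupby(["year", "plot"]).size()
    elif metric == "seedlings":
        c = sub[sub["stage"] == "Sd"].groupby(["year", "plot"]).size()
    elif metric == "sprout_recruits":
        first = sub.sort_values("year").groupby(["plot", "tag_id"]).first()
        spr = first[(first["stage"] != "Sd") & (first["year"] > years[0])]
        c = spr.groupby(["year", "plot"]).size()
    else:
        c = sub[sub["stage"] == metric].groupby(["year", "plot"]).size()
    return c.reindex(idx, fill_value=0).to_numpy(dtype=float)


def _write_site_outputs(res: SiteResult, outdir: Path, header: dict) -> None:
    site = res.site
    res.records.to_csv(outdir / f"{site}_census_resolved.csv", index=False)
    res.vital_rates.table.to_csv(outdir / f"{site}_vital_rates.csv",
                                 index=False)
    rows = []
    for y, pm in res.matrices.items():
        ssd = mpm.stable_stage_distribution(pm.A + 1e-12)  # jitter reducibles
        rows.append((site, y, res.lambdas[y], res.transients.get(y, np.nan),
                     *ssd))
    pd.DataFrame(rows, columns=["site", "year", "lambda", "transient",
                                *[f"ssd_{s}" for s in STAGES]]
                 ).to_csv(outdir / f"{site}_lambda.csv", index=False)
    res.mean_mat.to_frame().to_csv(outdir / f"{site}_mean_matrix.csv")
    res.spei_df.to_csv(outdir / f"{site}_spei.csv", index=False)
    pd.DataFrame(sorted(res.annual_spei.items()),
                 columns=["year", "mean_spei"]).to_csv(
        outdir / f"{site}_annual_spei.csv", index=False)
    if res.flm_table is not None:
        res.flm_table.to_csv(outdir / f"{site}_flm.csv", index=False)
    res.pva_table.to_csv(outdir / f"{site}_pva.csv", index=False)
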
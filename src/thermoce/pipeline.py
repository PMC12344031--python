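"""End-to-end orchestration: filter -> indices -> rates -> equilibrium -> trends.

Mirrors the analysis workflow: validate and filter the monitoring tables,
compute thermal indices and site summaries, estimate per-site and per-group
colonisation/extinction rates, fit exponential-link covariate models,
predict equilibrium richness and CTI, and run the trend and equilibrium
regressions.  Every stage is importable on its own; :func:`run_full` wires
them together and writes the output bundle plus a run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import equilibrium as eq
from . import io, thermal
from .ce_model import fit_covariate_model, fit_site_rates
from .io import build_occupancy_series

log = logging.getLogger("thermoce")

COVARIATES = ("latitude", "log_abundance", "pool_size")


@dataclass
class PipelineConfig:
    """Run settings; defaults follow the monitoring-data filters."""

    observations: str | Path = ""
    sites: str | Path = ""
    sti: str | Path = ""
    output_dir: str | Path = "results/pipeline"
    min_years: int = 10
    max_start_year: int = 2005
    singleton_mode: str = "none"  # none | per_site | global
    pool_mode: str = "dataset"  # dataset-wide ranges (per-year mode not orchestrated)
    mean_sti_mode: str = "pool"  # pool | observed members
    zone_breaks: tuple[float, float] = thermal.DEFAULT_ZONE_BREAKS
    covariates: tuple[str, ...] = COVARIATES
    standardise_covariates: bool = False
    fit_group_rates: bool = True
    seed: int = 2023

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if isinstance(cfg.zone_breaks, list):
            cfg.zone_breaks = tuple(cfg.zone_breaks)
        if isinstance(cfg.covariates, list):
            cfg.covariates = tuple(cfg.covariates)
        return cfg


def load_and_filter(
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    sti: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Validate inputs and apply the site filters.

    Sites need at least ``min_years`` surveyed years and a first survey no
    later than ``max_start_year``.  Observations at unknown sites raise.
    Returns (filtered observations, retained sites, report).
    """
    io.validate_observations(observations)
    unknown = sorted(set(observations["site_id"]) - set(sites["site_id"]))
    if unknown:
        raise ValueError(f"observations reference unknown sites: {unknown}")

    obs = observations[observations["count"] > 0]
    per_site = obs.groupby("site_id")["year"].agg(["nunique", "min"])
    keep = per_site.index[
        (per_site["nunique"] >= config.min_years)
        & (per_site["min"] <= config.max_start_year)
    ]
    removed = sorted(set(sites["site_id"]) - set(keep))
    obs_f = obs[obs["site_id"].isin(keep)].sort_values(
        ["site_id", "year", "species"], ignore_index=True
    )
    sites_f = sites[sites["site_id"].isin(keep)].sort_values(
        "site_id", ignore_index=True
    )
    if config.singleton_mode in ("per_site", "global"):
        obs_f = thermal.remove_singletons(obs_f, mode=config.singleton_mode)
    report = {
        "n_sites_in": int(sites["site_id"].nunique()),
        "n_sites_kept": int(len(sites_f)),
        "removed_sites": removed,
        "n_species_kept": int(obs_f["species"].nunique()),
        "n_species_missing_sti": int(
            len(set(obs_f["species"]) - set(io.sti_series(sti).index))
        ),
    }
    log.info("filtering kept %d/%d sites", report["n_sites_kept"], report["n_sites_in"])
    return obs_f, sites_f, report


def compute_indices(obs, sites, sti, config: PipelineConfig) -> dict:
    """Thermal grouping, CTI table, species ranges, site summaries, coverage."""
    sti_s = io.sti_series(sti)
    groups, boundaries = thermal.assign_thermal_groups(sti_s)
    ranges = thermal.species_ranges(obs, sites)
    summaries = thermal.summarise_sites(obs, sites, ranges, groups)
    summaries["zone"] = thermal.assign_zone(
        summaries["latitude"].to_numpy(), config.zone_breaks
    )
    cti = thermal.cti_by_site_year(obs, sti_s).merge(
        sites[["site_id", "latitude"]], on="site_id"
    )
    coverage = thermal.coverage_by_site(obs)
    return {
        "groups": groups,
        "group_boundaries": boundaries,
        "ranges": ranges,
        "summaries": summaries,
        "cti": cti,
        "coverage": coverage,
        "sti_values": sti_s,
    }


def fit_rates_stage(obs, sites, indices, config: PipelineConfig) -> pd.DataFrame:
    """Per-site (and per site x thermal group) ML rate fits."""
    groups = indices["groups"]
    rows = []
    for site_id in sites["site_id"]:
        targets = [(None, None)]
        if config.fit_group_rates:
            targets += [
                (g, groups[groups == g].index) for g in thermal.THERMAL_GROUPS
            ]
        for gname, subset in targets:
            series = build_occupancy_series(obs, site_id, subset, group=gname)
            row = {"site_id": site_id, "group": gname or "all"}
            if series is None:
                row.update(c=np.nan, e=np.nan, nll=np.nan, n_transitions=0,
                           boundary_flag="no_data", persistence=np.nan)
            else:
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        fit = fit_site_rates(series, seed=config.seed)
                    row.update(
                        c=fit.c, e=fit.e, nll=fit.nll,
                        n_transitions=fit.n_transitions,
                        boundary_flag=fit.boundary_flag or "",
                        persistence=fit.persistence,
                    )
                except ValueError as err:
                    row.update(c=np.nan, e=np.nan, nll=np.nan,
                               n_transitions=0, boundary_flag=str(err),
                               persistence=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _covariate_values(name: str, summaries: pd.DataFrame) -> np.ndarray:
    if name == "latitude":
        return summaries["latitude"].to_numpy(dtype=float)
    if name == "log_abundance":
        return np.log(summaries["mean_abundance"].to_numpy(dtype=float))
    if name == "pool_size":
        return summaries["pool_size"].to_numpy(dtype=float)
    raise ValueError(f"unknown covariate {name!r}")


def fit_covariates_stage(obs, sites, indices, config: PipelineConfig) -> pd.DataFrame:
    """Separate exponential-link models per explanatory variable.

    One model per covariate for the whole community, plus per-thermal-group
    models (group-specific intercept and slope) on the group series.
    Reports betas and the implied persistence slope (-beta1_e).
    """
    summaries = indices["summaries"].set_index("site_id").loc[sites["site_id"]]
    groups = indices["groups"]
    rows = []
    targets = [("all", None)]
    if config.fit_group_rates:
        targets += [(g, groups[groups == g].index) for g in thermal.THERMAL_GROUPS]
    for gname, subset in targets:
        series_list, site_ids = [], []
        for site_id in sites["site_id"]:
            s = build_occupancy_series(obs, site_id, subset, group=gname)
            if s is not None:
                series_list.append(s)
                site_ids.append(site_id)
        if len(series_list) < 3:
            log.warning("group %s present at <3 sites; covariate models skipped", gname)
            continue
        sub = summaries.loc[site_ids]
        for cov_name in config.covariates:
            x = _covariate_values(cov_name, sub.reset_index())
            if config.standardise_covariates:
                x = (x - x.mean()) / x.std(ddof=0)
            try:
                model = fit_covariate_model(
                    series_list, x, covariate_name=cov_name,
                    per_group=None if gname == "all" else gname,
                    seed=config.seed,
                )
            except (ValueError, RuntimeError) as err:
                log.warning("covariate model %s/%s failed: %s", gname, cov_name, err)
                continue
            rows.append(
                {
                    "group": gname,
                    "covariate": cov_name,
                    "beta0_c": model.beta0_c,
                    "beta1_c": model.beta1_c,
                    "beta0_e": model.beta0_e,
                    "beta1_e": model.beta1_e,
                    "se_beta0_c": model.se[0],
                    "se_beta1_c": model.se[1],
                    "se_beta0_e": model.se[2],
                    "se_beta1_e": model.se[3],
                    "persistence_slope": -model.beta1_e,
                    "nll": model.nll,
                    "n_sites": len(series_list),
                }
            )
    return pd.DataFrame(rows)


def _group_mean_sti(sites, indices, config: PipelineConfig, obs=None) -> pd.DataFrame:
    """Mean STI of each thermal group at each site (pool members by default)."""
    groups = indices["groups"]
    ranges = indices["ranges"]
    rows = []
    for _, site in sites.iterrows():
        for g in thermal.THERMAL_GROUPS:
            if config.mean_sti_mode == "observed" and obs is not None:
                seen = obs.loc[
                    (obs["site_id"] == site["site_id"]) & (obs["count"] > 0), "species"
                ].unique()
                members = pd.Index(seen).intersection(groups[groups == g].index)
            else:
                members = thermal.build_species_pool(
                    site["latitude"], ranges, groups, g
                )
            sti_vals = indices["sti_values"].reindex(members).dropna()
            rows.append(
                {
                    "site_id": site["site_id"],
                    "group": g,
                    "mean_sti": float(sti_vals.mean()) if len(sti_vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)


def equilibrium_stage(obs, sites, indices, rates, config: PipelineConfig) -> dict:
    """Equilibrium richness, net rates and CTI predictions per site."""
    mean_sti = _group_mean_sti(sites, indices, config, obs)
    group_rates = rates[rates["group"] != "all"][
        ["site_id", "group", "c", "e", "boundary_flag"]
    ]
    table = eq.group_site_table(indices["summaries"], group_rates, mean_sti)
    cti_site = eq.site_cti_predictions(table)
    return {"group_table": table, "cti_site": cti_site}


def trends_stage(indices, equilibrium_out, sites) -> dict:
    from . import trends

    cti = indices["cti"]
    trend = trends.fit_cti_trend(cti)
    slopes = trends.site_cti_slopes(cti)
    df = equilibrium_out["cti_site"].merge(
        sites[["site_id", "latitude"]], on="site_id"
    )
    reg = trends.equilibrium_regression(
        df["cti_obs_group"], df["cti_pred"], df["latitude"]
    )
    return {"trend": trend, "site_slopes": slopes, "equilibrium_regression": reg}


def singleton_sensitivity(obs, sites, sti, config: PipelineConfig) -> dict:
    """Refit site rates with singletons removed; correlate with the full fit.

    Returns Pearson correlations between the with/without-singleton rate
    vectors, the robustness check used to justify keeping singletons.
    """
    indices = None
    out = {}
    for label, mode in (("with_singletons", "none"), ("without_singletons", "per_site")):
        cfg = PipelineConfig(**{**asdict(config), "singleton_mode": mode,
                                "fit_group_rates": False})
        obs_f, sites_f, _ = load_and_filter(obs, sites, sti, cfg)
        idx = compute_indices(obs_f, sites_f, sti, cfg)
        out[label] = fit_rates_stage(obs_f, sites_f, idx, cfg)
    merged = out["with_singletons"].merge(
        out["without_singletons"], on=["site_id", "group"], suffixes=("_w", "_wo")
    ).dropna(subset=["c_w", "c_wo", "e_w", "e_wo"])
    return {
        "r_colonisation": float(np.corrcoef(merged["c_w"], merged["c_wo"])[0, 1]),
        "r_extinction": float(np.corrcoef(merged["e_w"], merged["e_wo"])[0, 1]),
        "n_sites": int(len(merged)),
        "rates": merged,
    }


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()[:16]


def run_full(config: PipelineConfig) -> dict:
    """Execute the whole pipeline and write the output bundle.

    Writes rates, covariate-model, site-summary, CTI, coverage, group
    assignment, equilibrium and regression CSVs plus a JSON manifest under
    ``config.output_dir``.  Raises on stage failure (the CLI maps this to
    exit codes); the manifest records per-stage status either way.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in asdict(config).items()},
        "inputs": {
            name: _checksum(getattr(config, name))
            for name in ("observations", "sites", "sti")
            if getattr(config, name)
        },
        "stages": {},
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))

    outputs: dict = {}
    try:
        observations = io.read_observations(config.observations)
        sites = io.read_sites(config.sites)
        sti = io.read_sti(config.sti)
        obs, sites_f, report = load_and_filter(observations, sites, sti, config)
        manifest["stages"]["filter"] = "ok"
        outputs["filter_report"] = report

        indices = compute_indices(obs, sites_f, sti, config)
        manifest["stages"]["indices"] = "ok"
        io.write_csv(indices["cti"], outdir / "cti_site_year.csv")
        io.write_csv(indices["summaries"], outdir / "site_summary.csv")
        io.write_csv(indices["coverage"], outdir / "coverage.csv")
        io.write_csv(
            indices["groups"].rename("group").rename_axis("species").reset_index(),
            outdir / "thermal_groups.csv",
        )

        rates = fit_rates_stage(obs, sites_f, indices, config)
        manifest["stages"]["rates"] = "ok"
        io.write_csv(rates, outdir / "rates.csv")

        cov_models = fit_covariates_stage(obs, sites_f, indices, config)
        manifest["stages"]["covariates"] = "ok"
        io.write_csv(cov_models, outdir / "covariate_models.csv")

        eq_out = equilibrium_stage(obs, sites_f, indices, rates, config)
        manifest["stages"]["equilibrium"] = "ok"
        io.write_csv(eq_out["group_table"], outdir / "equilibrium_group_site.csv")
        io.write_csv(eq_out["cti_site"], outdir / "cti_predictions.csv")

        tr = trends_stage(indices, eq_out, sites_f)
        manifest["stages"]["trends"] = "ok"
        io.write_csv(tr["trend"].wald.assign(
            **{"re_var": tr["trend"].re_var}), outdir / "trend_tests.csv")
        io.write_csv(tr["site_slopes"], outdir / "site_cti_slopes.csv")
        reg = tr["equilibrium_regression"]
        io.write_csv(
            pd.DataFrame([{
                "slope": reg.slope, "intercept": reg.intercept,
                "slope_se": reg.slope_se,
                "f_slope_vs_1": reg.f_slope_vs_1, "p_slope_vs_1": reg.p_slope_vs_1,
                "f_interaction": reg.f_interaction, "p_interaction": reg.p_interaction,
                "n_sites": reg.n_sites,
            }]),
            outdir / "equilibrium_regression.csv",
        )

        outputs.update(indices=indices, rates=rates, covariate_models=cov_models,
                       equilibrium=eq_out, trends=tr)
    except Exception as err:
        manifest["stages"]["error"] = repr(err)
        manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
        raise
    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    outputs["manifest"] = manifest
    return outputs
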
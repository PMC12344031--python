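"""Synthetic community-monitoring generator with known ground truth.

Emulates a national light-trap style monitoring scheme: sites strung along
a latitudinal gradient, surveyed annually for three decades with occasional
missing years; several hundred species with thermal affinities (STIs);
northern range limits that shrink with increasing STI; occupancy dynamics
following the two-state colonisation-extinction model with rates linked to
a site covariate through an exponential function; and abundances, given
presence, declining with latitude.  Every generated table passes the
pipeline's input validators unchanged, and the generating truth (rates,
link coefficients, ranges, equilibrium richness) is returned for recovery
tests.

One global seed drives a per-stream RNG hierarchy (species pool, occupancy,
missingness, abundance) so each stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate_species_pool",
           "simulate_dataset", "simulate_cti_table"]


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions.

    Rates follow c_j = exp(beta0_c + beta1_c * z_j) (likewise e) with z the
    standardised site latitude.  ``group_betas`` optionally replaces the
    shared coefficients with per-thermal-group ones.  With
    ``range_model="sti"`` each species' northern limit declines with its
    STI; ``"none"`` makes every species available everywhere.
    """

    n_sites: int = 60
    latitude_range: tuple[float, float] = (59.8, 69.8)
    survey_years: tuple[int, int] = (1993, 2022)
    missing_survey_prob: float = 0.05
    n_species: int = 300
    sti_mean: float = 8.0  # degC, centre of the STI distribution
    sti_sd: float = 2.5
    range_model: str = "sti"
    northern_limit_at_mean: float = 70.5  # degN for a species of mean STI
    northern_limit_slope: float = -1.2  # degN per degC of STI
    northern_limit_sd: float = 1.5
    southern_limit_mean: float = 55.0  # mostly below the gradient
    southern_limit_sd: float = 2.5
    beta0_c: float = -1.0
    beta1_c: float = -0.4
    beta0_e: float = -0.8
    beta1_e: float = 0.6
    group_betas: dict | None = None
    log_abundance_at_ref: float = 3.4  # ln individuals/species/year at 60 degN
    abundance_lat_slope: float = -0.12  # per degN, on the log scale
    abundance_sd: float = 0.8  # log-normal dispersion
    rate_heterogeneity_sd: float = 0.0  # per-species log-rate spread (stress test)
    seed: int = 2023

    def validate(self) -> None:
        if not 0.0 <= self.missing_survey_prob < 1.0:
            raise ValueError("missing_survey_prob must be in [0, 1)")
        if self.survey_years[1] <= self.survey_years[0]:
            raise ValueError("survey years must be ordered")
        if self.n_species < 4:
            raise ValueError("need at least 4 species")
        if self.sti_sd <= 0:
            raise ValueError("STI sd must be positive")
        if self.range_model not in ("sti", "none"):
            raise ValueError("range_model must be 'sti' or 'none'")


@dataclass
class SimulatedDataset:
    """Synthetic monitoring tables plus the generating truth."""

    observations: pd.DataFrame  # site_id, year, species, count
    sites: pd.DataFrame  # site_id, latitude, longitude
    sti: pd.DataFrame  # species, sti_degC
    truth: dict


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _species_ids(n: int) -> list[str]:
    return [f"sp{i:04d}" for i in range(1, n + 1)]


def _site_table(config: SimulationConfig) -> pd.DataFrame:
    lat = np.linspace(*config.latitude_range, config.n_sites)
    return pd.DataFrame(
        {
            "site_id": [f"site{i:03d}" for i in range(1, config.n_sites + 1)],
            "latitude": np.round(lat, 4),
            "longitude": np.round(25.0 + 3.0 * np.sin(np.arange(config.n_sites)), 4),
        }
    )


def simulate_species_pool(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw STIs and latitudinal range limits for the species list.

    Northern limits decline with STI (plus noise); southern limits sit
    mostly below the study gradient so that most species could occur at
    the southernmost sites.
    """
    config.validate()
    if rng is None:
        rng = _streams(config.seed, 4)[0]
    species = _species_ids(config.n_species)
    sti = rng.normal(config.sti_mean, config.sti_sd, config.n_species)
    if config.range_model == "none":
        lo = np.full(config.n_species, -90.0)
        hi = np.full(config.n_species, 90.0)
    else:
        hi = (
            config.northern_limit_at_mean
            + config.northern_limit_slope * (sti - config.sti_mean)
            + rng.normal(0.0, config.northern_limit_sd, config.n_species)
        )
        lo = rng.normal(
            config.southern_limit_mean, config.southern_limit_sd, config.n_species
        )
        lo = np.minimum(lo, hi - 1.0)
    sti_df = pd.DataFrame({"species": species, "sti_degC": np.round(sti, 4)})
    ranges = pd.DataFrame(
        {
            "species": species,
            "min_latitude": np.round(lo, 4),
            "max_latitude": np.round(hi, 4),
        }
    )
    return sti_df, ranges


def _species_group_codes(sti: np.ndarray) -> np.ndarray:
    """Quartile group index (0 coldest .. 3 warmest), ties to the colder group."""
    cuts = np.percentile(sti, [25, 50, 75])
    return np.searchsorted(cuts, sti, side="left")


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a full synthetic monitoring dataset.

    Per in-range site x species pair a two-state Markov chain runs over the
    survey span with the site's (or the species' group's) rates; the
    initial state is drawn from the stationary occupancy c/(c+e).  Survey
    years are dropped site-wise with ``missing_survey_prob`` (at least two
    always retained), and counts given presence are log-normal with a
    latitude-declining mean, rounded with a floor of one individual.
    """
    config = config or SimulationConfig()
    config.validate()
    rng_pool, rng_occ, rng_miss, rng_abund = _streams(config.seed, 4)

    sti_df, ranges = simulate_species_pool(config, rng_pool)
    sites = _site_table(config)
    years = np.arange(config.survey_years[0], config.survey_years[1] + 1)
    n_years = years.size
    lat = sites["latitude"].to_numpy()
    lat_sd = lat.std(ddof=0)
    z = (lat - lat.mean()) / lat_sd if lat_sd > 0 else np.zeros_like(lat)

    sti_vals = sti_df["sti_degC"].to_numpy()
    group_codes = _species_group_codes(sti_vals)
    if config.group_betas is not None:
        from .thermal import THERMAL_GROUPS

        betas = np.array([config.group_betas[g] for g in THERMAL_GROUPS])
        b_sp = betas[group_codes]  # (n_species, 4)
        c_mat = np.exp(b_sp[:, 0][None, :] + z[:, None] * b_sp[:, 1][None, :])
        e_mat = np.exp(b_sp[:, 2][None, :] + z[:, None] * b_sp[:, 3][None, :])
    else:
        c_site = np.exp(config.beta0_c + config.beta1_c * z)
        e_site = np.exp(config.beta0_e + config.beta1_e * z)
        c_mat = np.repeat(c_site[:, None], config.n_species, axis=1)
        e_mat = np.repeat(e_site[:, None], config.n_species, axis=1)
    if config.rate_heterogeneity_sd > 0:
        c_mat = c_mat * np.exp(
            rng_occ.normal(0, config.rate_heterogeneity_sd, c_mat.shape)
        )
        e_mat = e_mat * np.exp(
            rng_occ.normal(0, config.rate_heterogeneity_sd, e_mat.shape)
        )

    in_range = (ranges["min_latitude"].to_numpy()[None, :] <= lat[:, None]) & (
        lat[:, None] <= ranges["max_latitude"].to_numpy()[None, :]
    )
    if not in_range.any(axis=1).all():
        raise ValueError("a site has an empty species pool; widen the range model")

    s = c_mat + e_mat
    E = np.exp(-s)  # annual step
    p01 = c_mat / s * (1.0 - E)
    p11 = (c_mat + e_mat * E) / s
    occ = np.empty((config.n_sites, config.n_species, n_years), dtype=bool)
    state = rng_occ.random((config.n_sites, config.n_species)) < c_mat / s
    occ[:, :, 0] = state
    for t in range(1, n_years):
        p = np.where(state, p11, p01)
        state = rng_occ.random(state.shape) < p
        occ[:, :, t] = state
    occ &= in_range[:, :, None]

    surveyed = rng_miss.random((config.n_sites, n_years)) >= config.missing_survey_prob
    for j in range(config.n_sites):  # guarantee a usable series
        while surveyed[j].sum() < 2:
            surveyed[j] = rng_miss.random(n_years) >= config.missing_survey_prob

    mu = config.log_abundance_at_ref + config.abundance_lat_slope * (lat - 60.0)
    counts = np.exp(
        mu[:, None, None]
        + rng_abund.normal(0.0, config.abundance_sd, occ.shape)
    )
    counts = np.maximum(np.rint(counts), 1.0)
    counts = np.where(occ & surveyed[:, None, :], counts, 0.0)

    site_idx, sp_idx, yr_idx = np.nonzero(counts)
    obs = pd.DataFrame(
        {
            "site_id": sites["site_id"].to_numpy()[site_idx],
            "year": years[yr_idx],
            "species": np.array(sti_df["species"])[sp_idx],
            "count": counts[site_idx, sp_idx, yr_idx].astype(int),
        }
    ).sort_values(["site_id", "year", "species"], ignore_index=True)

    pool_size = in_range.sum(axis=1)
    if config.group_betas is None:
        c_site_vec = c_mat[:, 0]
        e_site_vec = e_mat[:, 0]
    else:
        c_site_vec = np.full(config.n_sites, np.nan)
        e_site_vec = np.full(config.n_sites, np.nan)
    truth = {
        "betas": {
            "beta0_c": config.beta0_c,
            "beta1_c": config.beta1_c,
            "beta0_e": config.beta0_e,
            "beta1_e": config.beta1_e,
        },
        "group_betas": config.group_betas,
        "covariate": z,
        "c_site": c_site_vec,
        "e_site": e_site_vec,
        "ranges": ranges,
        "group_codes": group_codes,
        "pool_size": pool_size,
        "equilibrium_richness": pool_size * c_site_vec / (c_site_vec + e_site_vec)
        if config.group_betas is None
        else None,
        "seed": config.seed,
        "config": config,
    }
    return SimulatedDataset(observations=obs, sites=sites, sti=sti_df, truth=truth)


def simulate_cti_table(
    n_sites: int = 60,
    years: tuple[int, int] = (1993, 2022),
    latitude_range: tuple[float, float] = (59.8, 69.8),
    slope_south: float = 0.02,
    slope_north: float = 0.03,
    slope_ref_lats: tuple[float, float] = (60.0, 70.0),
    base_cti: float = 10.0,
    base_lat_slope: float = -0.3,
    site_sd: float = 0.3,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Direct site-year CTI generator for trend-model checks.

    The per-site trend interpolates linearly from ``slope_south`` degC/yr
    at ``slope_ref_lats[0]`` to ``slope_north`` at ``slope_ref_lats[1]``;
    sites get Gaussian random intercepts and iid yearly noise.  Returns the
    table and the generating truth (including the year x latitude
    interaction coefficient).
    """
    rng = np.random.default_rng(seed)
    lats = np.linspace(*latitude_range, n_sites)
    yrs = np.arange(years[0], years[1] + 1)
    interaction = (slope_north - slope_south) / (slope_ref_lats[1] - slope_ref_lats[0])
    site_int = rng.normal(0.0, site_sd, n_sites)
    rows = []
    for j, lat in enumerate(lats):
        slope = slope_south + interaction * (lat - slope_ref_lats[0])
        level = base_cti + base_lat_slope * (lat - slope_ref_lats[0]) + site_int[j]
        cti = level + slope * (yrs - yrs.mean()) + rng.normal(0.0, noise_sd, yrs.size)
        for y, v in zip(yrs, cti):
            rows.append(
                {"site_id": f"site{j + 1:03d}", "year": int(y), "latitude": lat, "cti": v}
            )
    truth = {
        "interaction": interaction,
        "slope_south": slope_south,
        "slope_north": slope_north,
        "site_sd": site_sd,
        "noise_sd": noise_sd,
    }
    return pd.DataFrame(rows), truth
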
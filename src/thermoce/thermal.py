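"""Species and community thermal indices, grouping, pools and summaries.

STI (species temperature index) is the mean temperature across a species'
range; CTI (community temperature index) is the abundance-weighted mean STI
of a community.  Species are partitioned into four thermal-affinity groups
by STI quartiles.  A site's species pool is the set of species whose
latitudinal occurrence range (taken from the whole dataset) overlaps the
site's latitude.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "THERMAL_GROUPS",
    "compute_cti",
    "cti_by_site_year",
    "assign_thermal_groups",
    "species_ranges",
    "build_species_pool",
    "summarise_site",
    "summarise_sites",
    "sample_coverage",
    "remove_singletons",
    "assign_zone",
]

#: Group labels from coldest to warmest STI quartile.
THERMAL_GROUPS = ("cold-adapted", "cold-tolerant", "warm-tolerant", "warm-adapted")

#: Default bioclimatic-zone latitude breakpoints (degN): South < 63 <= Middle < 66 <= North.
DEFAULT_ZONE_BREAKS = (63.0, 66.0)


def compute_cti(abundances: pd.Series, sti: pd.Series) -> float:
    """Abundance-weighted mean STI over species with both STI and abundance.

    ``abundances`` maps species -> individual counts, ``sti`` maps
    species -> STI (degC).  Species without an STI are dropped from both
    numerator and denominator.  Returns NaN (with a warning) when no
    STI-bearing species has positive abundance.
    """
    common = abundances.index.intersection(sti.index)
    a = abundances.loc[common].astype(float)
    w = a[a > 0]
    if w.empty or w.sum() <= 0:
        warnings.warn("no STI-bearing species with positive abundance; CTI undefined")
        return float("nan")
    return float(np.average(sti.loc[w.index], weights=w))


def cti_by_site_year(observations: pd.DataFrame, sti: pd.Series) -> pd.DataFrame:
    """Per site and year CTI from long-format observations.

    ``observations`` has columns site_id, year, species, count.  Returns a
    frame with columns site_id, year, cti.
    """
    obs = observations[observations["count"] > 0]
    obs = obs[obs["species"].isin(sti.index)].copy()
    obs["w_sti"] = obs["count"] * sti.loc[obs["species"]].to_numpy()
    g = obs.groupby(["site_id", "year"], sort=True)
    out = (g["w_sti"].sum() / g["count"].sum()).rename("cti").reset_index()
    return out


def assign_thermal_groups(sti: pd.Series) -> tuple[pd.Series, np.ndarray]:
    """Partition STI-bearing species into quartile thermal-affinity groups.

    Cut points are the empirical 25/50/75 percentiles (linear
    interpolation).  A species whose STI falls exactly on a cut point is
    assigned to the colder group.  Returns (species -> group label,
    boundaries).
    """
    sti = sti.dropna()
    if sti.size < 4:
        raise ValueError("need at least 4 species with STI to form quartiles")
    boundaries = np.percentile(sti.to_numpy(), [25, 50, 75])
    # side="left": a value equal to a cut point stays in the colder group.
    idx = np.searchsorted(boundaries, sti.to_numpy(), side="left")
    groups = pd.Series(
        pd.Categorical.from_codes(idx, categories=list(THERMAL_GROUPS)),
        index=sti.index,
        name="group",
    )
    return groups, boundaries


def species_ranges(observations: pd.DataFrame, sites: pd.DataFrame) -> pd.DataFrame:
    """Min/max latitude of occurrence per species across the whole dataset."""
    obs = observations[observations["count"] > 0]
    lat = sites.set_index("site_id")["latitude"]
    unknown = set(obs["site_id"]) - set(lat.index)
    if unknown:
        raise ValueError(f"observations reference unknown sites: {sorted(unknown)}")
    df = obs.assign(latitude=lat.loc[obs["site_id"]].to_numpy())
    out = df.groupby("species")["latitude"].agg(min_latitude="min", max_latitude="max")
    return out.reset_index()


def build_species_pool(
    site_latitude: float,
    ranges: pd.DataFrame,
    groups: pd.Series | None = None,
    group: str | None = None,
) -> pd.Index:
    """Species whose latitudinal range overlaps the site (boundaries inclusive).

    Optionally restricted to one thermal group; an empty pool is valid
    (e.g. warm-adapted species in the far north).
    """
    if ranges.empty:
        raise ValueError("ranges table is empty")
    mask = (ranges["min_latitude"] <= site_latitude) & (
        site_latitude <= ranges["max_latitude"]
    )
    pool = pd.Index(ranges.loc[mask, "species"])
    if group is not None:
        if groups is None:
            raise ValueError("group filter requires a group assignment")
        in_group = groups[groups == group].index
        pool = pool.intersection(in_group)
    return pool


def assign_zone(latitude, breaks=DEFAULT_ZONE_BREAKS):
    """Bioclimatic zone from latitude: South < breaks[0] <= Middle < breaks[1] <= North."""
    lat = np.asarray(latitude, dtype=float)
    zones = np.where(lat < breaks[0], "South", np.where(lat < breaks[1], "Middle", "North"))
    return zones if lat.ndim else str(zones)


def summarise_site(
    observations: pd.DataFrame,
    site_row: pd.Series,
    ranges: pd.DataFrame,
    groups: pd.Series | None = None,
) -> dict:
    """Abundance, richness and pool summaries for one site.

    mean_abundance is the total number of individuals per surveyed year
    averaged over surveyed years; S is the mean yearly number of distinct
    species detected; Sp the size of the range-overlap species pool.
    Per-group richness decompositions (only for STI-bearing, grouped
    species) are included when ``groups`` is given.
    """
    site_id = site_row["site_id"]
    obs = observations[(observations["site_id"] == site_id) & (observations["count"] > 0)]
    if obs.empty:
        raise ValueError(f"site {site_id!r} has no surveyed years")
    yearly = obs.groupby("year").agg(
        abundance=("count", "sum"), richness=("species", "nunique")
    )
    pool = build_species_pool(site_row["latitude"], ranges)
    out = {
        "site_id": site_id,
        "latitude": float(site_row["latitude"]),
        "n_years": int(len(yearly)),
        "first_year": int(yearly.index.min()),
        "mean_abundance": float(yearly["abundance"].mean()),
        "mean_richness": float(yearly["richness"].mean()),
        "pool_size": int(pool.size),
    }
    if groups is not None:
        grouped = obs[obs["species"].isin(groups.index)].copy()
        grouped["group"] = groups.loc[grouped["species"]].to_numpy()
        for g in THERMAL_GROUPS:
            sub = grouped[grouped["group"] == g]
            rich = sub.groupby("year")["species"].nunique()
            # average over *surveyed* years, counting zero-richness years
            s_mean = float(rich.reindex(yearly.index, fill_value=0).mean())
            gpool = build_species_pool(site_row["latitude"], ranges, groups, g)
            out[f"S_{g}"] = s_mean
            out[f"Sp_{g}"] = int(gpool.size)
    return out


def summarise_sites(
    observations: pd.DataFrame,
    sites: pd.DataFrame,
    ranges: pd.DataFrame,
    groups: pd.Series | None = None,
) -> pd.DataFrame:
    """Table of :func:`summarise_site` over all sites, with zones attached."""
    rows = [
        summarise_site(observations, row, ranges, groups)
        for _, row in sites.iterrows()
    ]
    df = pd.DataFrame(rows)
    df["zone"] = assign_zone(df["latitude"].to_numpy())
    return df


def sample_coverage(abundance_vector) -> float:
    """Abundance-based sample coverage from singleton/doubleton frequencies.

    ``Chat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2)`` where f1 and f2
    are the numbers of species observed as exactly one or two individuals
    and n the total count.  Equals 1 when there are no singletons.
    """
    a = np.asarray(abundance_vector, dtype=float)
    a = a[a > 0]
    n = a.sum()
    if a.size == 0 or n <= 0:
        raise ValueError("abundance vector is empty")
    f1 = float(np.sum(a == 1))
    f2 = float(np.sum(a == 2))
    if f1 == 0:
        return 1.0
    denom = (n - 1) * f1 + 2 * f2
    if denom == 0:
        return 1.0
    return float(1.0 - (f1 / n) * ((n - 1) * f1 / denom))


def coverage_by_site(observations: pd.DataFrame) -> pd.DataFrame:
    """Sample coverage per site from species totals pooled over years."""
    totals = observations.groupby(["site_id", "species"])["count"].sum()
    rows = [
        {"site_id": site, "coverage": sample_coverage(grp.to_numpy())}
        for site, grp in totals.groupby(level="site_id")
    ]
    return pd.DataFrame(rows)


def remove_singletons(observations: pd.DataFrame, mode: str = "per_site") -> pd.DataFrame:
    """Drop species represented by a single individual.

    ``per_site`` (default): drop a (site, species) pair whose summed count
    across the series is exactly 1 — occupancy series are per site, so the
    singleton notion is applied per site.  ``global``: drop species whose
    dataset-wide total is 1.  Idempotent in both modes.
    """
    if mode == "per_site":
        totals = observations.groupby(["site_id", "species"])["count"].transform("sum")
        return observations[totals != 1].reset_index(drop=True)
    if mode == "global":
        totals = observations.groupby("species")["count"].transform("sum")
        return observations[totals != 1].reset_index(drop=True)
    raise ValueError(f"unknown singleton mode {mode!r}")
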
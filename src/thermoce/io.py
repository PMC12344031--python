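"""Readers, validators and writers for the pipeline's CSV dialects.

Long-format observations (site_id, year, species, count), site metadata
(site_id, latitude, longitude[, zone]) and a species thermal table
(species, sti_degC).  Presence is defined as count >= 1; a site's surveyed
years are the years for which it has any record.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ce_model import OccupancySeries

OBS_COLUMNS = ["site_id", "year", "species", "count"]
SITE_COLUMNS = ["site_id", "latitude", "longitude"]
STI_COLUMNS = ["species", "sti_degC"]


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing columns {missing}")


def read_observations(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_observations(df)
    return df


def validate_observations(df: pd.DataFrame) -> None:
    _check_columns(df, OBS_COLUMNS, "observations table")
    bad = df.index[
        df["year"].isna()
        | df["count"].isna()
        | (df["count"] < 0)
        | (df["count"] != df["count"].astype(int))
    ]
    if len(bad):
        lines = (bad + 2).tolist()[:10]  # 1-based incl. header
        raise ValueError(f"malformed observation rows at lines {lines}")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, SITE_COLUMNS, "site table")
    if df["site_id"].duplicated().any():
        raise ValueError("duplicate site ids in site table")
    return df


def read_sti(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _check_columns(df, STI_COLUMNS, "STI table")
    if df["species"].duplicated().any():
        raise ValueError("duplicate species in STI table")
    return df


def sti_series(sti: pd.DataFrame) -> pd.Series:
    return sti.dropna(subset=["sti_degC"]).set_index("species")["sti_degC"]


def surveyed_years(observations: pd.DataFrame, site_id: str) -> np.ndarray:
    years = np.sort(
        observations.loc[observations["site_id"] == site_id, "year"].unique()
    )
    return years.astype(float)


def build_occupancy_series(
    observations: pd.DataFrame,
    site_id: str,
    species_subset=None,
    group: str | None = None,
    species_universe=None,
) -> OccupancySeries | None:
    """Presence/absence series for one site from long-format observations.

    The species universe defaults to the species observed at least once at
    the site (optionally intersected with ``species_subset``, e.g. one
    thermal group's members); pass ``species_universe`` to force a fixed
    species list including all-absent rows.  A year with any record at the
    site counts as surveyed, and absences in surveyed years become zeros.
    Returns None when fewer than 2 surveyed years or no qualifying species
    remain.
    """
    sub = observations[
        (observations["site_id"] == site_id) & (observations["count"] > 0)
    ]
    years = np.sort(sub["year"].unique())
    if years.size < 2:
        return None
    if species_subset is not None:
        sub = sub[sub["species"].isin(species_subset)]
    species = (
        sorted(species_universe) if species_universe is not None
        else sorted(sub["species"].unique())
    )
    if not species:
        return None
    mat = (
        sub.assign(present=1)
        .pivot_table(
            index="species", columns="year", values="present", aggfunc="max", fill_value=0
        )
        .reindex(index=species, columns=years, fill_value=0)
    )
    return OccupancySeries(
        site_id=site_id,
        survey_times=years.astype(float),
        states=mat.to_numpy(dtype=np.int8),
        species=species,
        group=group,
    )


def write_csv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
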
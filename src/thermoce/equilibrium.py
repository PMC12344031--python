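"""Equilibrium species richness, group-based CTI and net turnover rates.

A community is at equilibrium when yearly colonisations balance yearly
extinctions, c (Sp - S) = e S, giving the equilibrium richness
S* = Sp c / (c + e).  Weighting each thermal group's mean STI by its
(estimated or observed) richness yields a predicted or observed group-based
CTI for a site; comparing the two locates the community relative to thermal
equilibrium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NetRates", "equilibrium_richness", "group_cti", "net_rates"]


@dataclass
class NetRates:
    """Expected yearly species gains and losses for one site x group."""

    net_extinctions: float  # e * S, species lost per year
    net_colonisations: float  # c * (Sp - S), species gained per year
    potential_colonists: float  # Sp - S, species


def equilibrium_richness(sp: float, c: float, e: float) -> float:
    """Equilibrium richness S* = Sp * c / (c + e); lies in [0, Sp]."""
    if sp < 0:
        raise ValueError("species pool size must be non-negative")
    if c + e <= 0:
        raise ValueError("c + e must be positive")
    return sp * c / (c + e)


def group_cti(richness_by_group, mean_sti_by_group) -> float:
    """Richness-weighted mean of group mean STIs.

    Used with equilibrium richness this gives the predicted CTI of a site;
    with recorded group richness it gives the observed group-based CTI.
    Groups with zero richness (e.g. no pool members at the site) contribute
    zero weight.  Returns NaN with a warning when total richness is zero.
    """
    r = np.asarray(richness_by_group, dtype=float)
    s = np.asarray(mean_sti_by_group, dtype=float)
    if r.shape != s.shape:
        raise ValueError("richness and STI vectors must align")
    valid = (r > 0) & np.isfinite(s)
    if not valid.any() or r[valid].sum() <= 0:
        warnings.warn("total richness is zero; group CTI undefined")
        return float("nan")
    return float(np.average(s[valid], weights=r[valid]))


def net_rates(sp: float, s: float, c: float, e: float) -> NetRates:
    """Net extinctions e*S and net colonisations c*(Sp - S) for a summary.

    Under the per-year pool mode S can exceed Sp; the count of potential
    colonists is then clamped to zero with a warning.
    """
    potential = sp - s
    if potential < 0:
        warnings.warn("observed richness exceeds pool size; clamping Sp - S to 0")
        potential = 0.0
    return NetRates(
        net_extinctions=float(e * s),
        net_colonisations=float(c * potential),
        potential_colonists=float(potential),
    )


def group_site_table(
    summaries: pd.DataFrame,
    rates: pd.DataFrame,
    mean_sti: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the per site x group table feeding the CTI predictions.

    Parameters
    ----------
    summaries
        Output of :func:`thermoce.thermal.summarise_sites` with per-group
        ``S_<group>`` and ``Sp_<group>`` columns.
    rates
        Columns site_id, group, c, e, boundary_flag.
    mean_sti
        Columns site_id, group, mean_sti (degC), pool-member mean by default.

    Returns a frame with S_equilibrium, net_extinctions, net_colonisations
    and potential_colonists per site x group.
    """
    from .thermal import THERMAL_GROUPS

    long_rows = []
    for _, row in summaries.iterrows():
        for g in THERMAL_GROUPS:
            long_rows.append(
                {
                    "site_id": row["site_id"],
                    "group": g,
                    "Sp": row.get(f"Sp_{g}", np.nan),
                    "S": row.get(f"S_{g}", np.nan),
                }
            )
    df = pd.DataFrame(long_rows)
    df = df.merge(rates, on=["site_id", "group"], how="left")
    df = df.merge(mean_sti, on=["site_id", "group"], how="left")

    s_eq, ne, nc, pot = [], [], [], []
    for _, r in df.iterrows():
        if r["Sp"] > 0 and np.isfinite(r.get("c", np.nan)) and np.isfinite(r.get("e", np.nan)):
            s_eq.append(equilibrium_richness(r["Sp"], r["c"], r["e"]))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nr = net_rates(r["Sp"], r["S"], r["c"], r["e"])
            ne.append(nr.net_extinctions)
            nc.append(nr.net_colonisations)
            pot.append(nr.potential_colonists)
        else:
            s_eq.append(0.0 if r["Sp"] == 0 else np.nan)
            ne.append(np.nan)
            nc.append(np.nan)
            pot.append(max(r["Sp"] - r["S"], 0.0) if np.isfinite(r["Sp"]) else np.nan)
    df["S_equilibrium"] = s_eq
    df["net_extinctions"] = ne
    df["net_colonisations"] = nc
    df["potential_colonists"] = pot
    return df


def site_cti_predictions(group_table: pd.DataFrame) -> pd.DataFrame:
    """Predicted (equilibrium) and observed group-based CTI per site.

    Groups absent from a site's pool carry zero weight; a site with no
    usable group yields NaN.
    """
    rows = []
    for site, sub in group_table.groupby("site_id", sort=True):
        w_pred = sub["S_equilibrium"].fillna(0.0).to_numpy()
        w_obs = sub["S"].fillna(0.0).to_numpy()
        sti = sub["mean_sti"].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "site_id": site,
                    "cti_pred": group_cti(w_pred, sti),
                    "cti_obs_group": group_cti(w_obs, sti),
                }
            )
    return pd.DataFrame(rows)
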
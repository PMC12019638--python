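"""Macrosimulation of care demand and costs.

Three parts: (1) decompose the projected 65+ population into cells by
age band, gender, functional difficulty and depression severity;
(2) apply predicted care-mode probabilities and weekly hours to each
cell to get users and annualized hours (52.14 weeks/year); (3) attach
unit costs (GBP/hour, 2022 prices, with a real growth path) to the
annual hours.  Cost tables cover people with depressive symptoms
(mild/moderate/severe); the symptom-free can be included for
completeness analyses.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .care import CareModeFit, HoursFit, predict_care_probs, predict_hours
from .config import AGE_BANDS, CostParameters, FUNCTIONAL, GENDERS, STATES
from .projection import StateDistribution
from .synthetic import generate_unit_cost_path

SEVERITIES = ("mild", "moderate", "severe")
CARE_TYPES = ("unpaid", "home")


def band_label(lo: int, hi: int) -> str:
    return f"{lo}+" if hi >= 150 else f"{lo}-{hi}"


def band_midpoint(lo: int, hi: int) -> float:
    """Age used when predicting for a banded cell (92.5 for 90+)."""
    return 92.5 if hi >= 150 else (lo + hi) / 2.0


def decompose_population(state: StateDistribution,
                         functional_conditional: np.ndarray,
                         bands: Sequence[tuple] = AGE_BANDS) -> pd.DataFrame:
    """Split 65+ state counts into (age band, gender, functional,
    depression) cells; cell count = state count x conditional share."""
    fc = np.asarray(functional_conditional, dtype=float)
    if fc.shape != (4, 4):
        raise ValueError("functional conditional must be 4x4")
    if not np.allclose(fc.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("functional conditional rows must sum to 1")
    rows = []
    for lo, hi in bands:
        sel = (state.ages >= lo) & (state.ages <= hi)
        for g, gender in enumerate(GENDERS):
            by_state = state.counts[sel, g, :].sum(axis=0)
            for s, dep in enumerate(STATES):
                for f, func in enumerate(FUNCTIONAL):
                    rows.append((state.year, band_label(lo, hi),
                                 band_midpoint(lo, hi), gender, func, dep,
                                 by_state[s] * fc[s, f]))
    return pd.DataFrame(rows, columns=["year", "age_band", "age", "gender",
                                       "functional", "depression", "count"])


def attach_care_predictions(cells: pd.DataFrame, care_fit: CareModeFit,
                            hours_fit: HoursFit) -> pd.DataFrame:
    """Add mode probabilities and predicted weekly hours to each cell."""
    out = cells.copy()
    keys = ["age", "gender", "functional", "depression"]
    uniq = out[keys].drop_duplicates()
    pcols = ["p_none", "p_unpaid_only", "p_home_only", "p_both"]
    recs = []
    for _, r in uniq.iterrows():
        cell = {"age": r["age"], "gender": r["gender"],
                "functional": r["functional"], "depression": r["depression"]}
        p = predict_care_probs(care_fit, cell)
        recs.append((*r[keys], *p,
                     predict_hours(hours_fit, cell, "unpaid"),
                     predict_hours(hours_fit, cell, "home")))
    pred = pd.DataFrame(recs, columns=keys + pcols
                        + ["unpaid_hours_week", "home_hours_week"])
    return out.merge(pred, on=keys, how="left")


def compute_care_users(cells: pd.DataFrame) -> pd.DataFrame:
    """Users by severity and care type: unpaid users count the
    unpaid-only and both modes, home users the home-only and both."""
    c = cells.copy()
    c["unpaid_users"] = c["count"] * (c["p_unpaid_only"] + c["p_both"])
    c["home_users"] = c["count"] * (c["p_home_only"] + c["p_both"])
    return (c.groupby("depression", sort=False, observed=True)
            [["count", "unpaid_users", "home_users"]].sum().reset_index())


def compute_annual_hours(users: float, weekly_hours: float,
                         weeks_per_year: float = 52.14) -> float:
    """Annual hours = users x weekly hours x weeks per year."""
    if users < 0 or weekly_hours < 0 or weeks_per_year < 0:
        raise ValueError("inputs must be nonnegative")
    return users * weekly_hours * weeks_per_year


def unit_cost_paths(params: CostParameters, start: int,
                    horizon: int) -> dict[str, pd.Series]:
    """Real unit-cost paths for home and unpaid care over the horizon."""
    return {
        "home": generate_unit_cost_path(
            params.unit_cost_home, params.growth_rate, params.uplift_2024,
            start=start, horizon=horizon),
        "unpaid": generate_unit_cost_path(
            params.unit_cost_unpaid, params.growth_rate, params.uplift_2024,
            start=start, horizon=horizon),
    }


def compute_costs(annual_hours: float, params: CostParameters, year: int,
                  care_type: str,
                  paths: Optional[Mapping[str, pd.Series]] = None) -> float:
    """Cost in GBP (2022 prices x real growth) of a year's care hours."""
    if care_type not in CARE_TYPES:
        raise ValueError("care_type must be 'unpaid' or 'home'")
    if annual_hours < 0:
        raise ValueError("hours must be nonnegative")
    if paths is None:
        paths = unit_cost_paths(params, params.base_year, max(year, 2042))
    if year not in paths[care_type].index:
        raise ValueError(f"year {year} outside the unit-cost path")
    return annual_hours * float(paths[care_type].loc[year])


@dataclass
class CostTable:
    """Users, annual hours and costs by year x severity x care type."""
    table: pd.DataFrame    # year, severity, care_type, users, hours, cost
    people: pd.DataFrame   # year, severity, count

    def totals(self) -> pd.DataFrame:
        """Totals over severities per year and care type (pre-rounding)."""
        return (self.table.groupby(["year", "care_type"], observed=True)
                [["users", "annual_hours", "cost"]].sum().reset_index())

    def presentation(self) -> pd.DataFrame:
        """Rounded display table: users in thousands, costs in GBP bn."""
        t = self.table.copy()
        t["users_thousand"] = (t["users"] / 1e3).round(0)
        t["cost_bn"] = (t["cost"] / 1e9).round(1)
        return t[["year", "severity", "care_type", "users_thousand", "cost_bn"]]


def project_costs(trajectory: Sequence[StateDistribution],
                  care_fit: CareModeFit, hours_fit: HoursFit,
                  functional_conditional: np.ndarray,
                  params: CostParameters,
                  include_no_symptoms: bool = False,
                  years: Optional[Sequence[int]] = None) -> CostTable:
    """Run the three-part macrosimulation over a projected trajectory.

    Cell-level care predictions depend only on covariates, so they are
    computed once and reused across years; only cell counts change.
    """
    first, last = trajectory[0].year, trajectory[-1].year
    paths = unit_cost_paths(params, first, last)
    proto = attach_care_predictions(
        decompose_population(trajectory[0], functional_conditional),
        care_fit, hours_fit).drop(columns=["year", "count"])
    keys = ["age_band", "age", "gender", "functional", "depression"]

    severities = list(STATES) if include_no_symptoms else list(SEVERITIES)
    rows, people = [], []
    for state in trajectory:
        if years is not None and state.year not in years:
            continue
        cells = decompose_population(state, functional_conditional)
        cells = cells.merge(proto, on=keys, how="left")
        cells = cells[cells["depression"].isin(severities)]
        g = compute_care_users(cells)
        hours = cells.assign(
            unpaid_h=lambda d: (d["count"] * (d["p_unpaid_only"] + d["p_both"])
                                * d["unpaid_hours_week"] * params.weeks_per_year),
            home_h=lambda d: (d["count"] * (d["p_home_only"] + d["p_both"])
                              * d["home_hours_week"] * params.weeks_per_year),
        ).groupby("depression", sort=False, observed=True)[
            ["unpaid_h", "home_h"]].sum()
        for sev in severities:
            urow = g[g["depression"] == sev]
            users_u = float(urow["unpaid_users"].iloc[0])
            users_h = float(urow["home_users"].iloc[0])
            people.append((state.year, sev, float(urow["count"].iloc[0])))
            for ct, users, h in (("unpaid", users_u, hours.loc[sev, "unpaid_h"]),
                                 ("home", users_h, hours.loc[sev, "home_h"])):
                cost = h * float(paths[ct].loc[state.year])
                rows.append((state.year, sev, ct, users, float(h), cost))
    return CostTable(
        table=pd.DataFrame(rows, columns=["year", "severity", "care_type",
                                          "users", "annual_hours", "cost"]),
        people=pd.DataFrame(people, columns=["year", "severity", "count"]))
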
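"""Care-utilization models: mode choice and weekly hours.

A cross-sectional multinomial logit (base outcome: no care) links care
mode (unpaid only, home only, both) to depressive-symptom severity,
age, gender and functional difficulty among people aged 65+.  Weekly
hours of each care type are modelled by OLS on recipients of that type
(a two-part structure: participation times conditional hours).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    CARE_AGE_MIN,
    CARE_INTERCEPTS,
    CARE_MODES,
    CARE_PREDICTORS,
    CARE_RRR,
    CARE_RRR_SE,
    FUNCTIONAL,
    GENDERS,
    HOURS_COEF,
    HOURS_INTERCEPTS,
    HOURS_SE,
    STATES,
)

_MODES = ("unpaid_only", "home_only", "both")  # non-base, CARE_MODES order


@dataclass
class CareModeFit:
    """Multinomial care-mode fit on the log relative-risk scale."""
    params: pd.DataFrame  # index: intercept + CARE_PREDICTORS; cols: _MODES
    bse: pd.DataFrame
    n_used: int

    def __post_init__(self):
        if list(self.params.columns) != list(_MODES):
            raise ValueError(f"mode columns must be {_MODES}")
        if not (self.bse.values >= 0).all():
            raise ValueError("standard errors must be nonnegative")

    @property
    def rrr(self) -> pd.DataFrame:
        return np.exp(self.params.drop(index="intercept"))

    @classmethod
    def from_published(cls) -> "CareModeFit":
        idx = ["intercept"] + list(CARE_PREDICTORS)
        params = pd.DataFrame(0.0, index=idx, columns=list(_MODES))
        bse = pd.DataFrame(0.0, index=idx, columns=list(_MODES))
        for mode in _MODES:
            params.loc["intercept", mode] = CARE_INTERCEPTS[mode]
            for pred, rrr in CARE_RRR[mode].items():
                params.loc[pred, mode] = math.log(rrr)
                bse.loc[pred, mode] = CARE_RRR_SE[mode][pred] / rrr
        return cls(params, bse, n_used=0)


@dataclass
class HoursFit:
    """OLS weekly-hours models fitted on recipients of each care type."""
    params: pd.DataFrame  # index: intercept + CARE_PREDICTORS; cols: home, unpaid
    bse: pd.DataFrame
    resid_sd: dict
    n_used: dict

    @classmethod
    def from_published(cls) -> "HoursFit":
        idx = ["intercept"] + list(CARE_PREDICTORS)
        params = pd.DataFrame(0.0, index=idx, columns=["home", "unpaid"])
        bse = pd.DataFrame(0.0, index=idx, columns=["home", "unpaid"])
        for ct in ("home", "unpaid"):
            params.loc["intercept", ct] = HOURS_INTERCEPTS[ct]
            for pred, coef in HOURS_COEF[ct].items():
                params.loc[pred, ct] = coef
                bse.loc[pred, ct] = HOURS_SE[ct][pred]
        return cls(params, bse, resid_sd={"home": 0.0, "unpaid": 0.0},
                   n_used={"home": 0, "unpaid": 0})


def _care_design_frame(df: pd.DataFrame) -> np.ndarray:
    bad = set(df["functional"].unique()) - set(FUNCTIONAL)
    if bad:
        raise ValueError(f"unknown functional categories: {bad}")
    return np.column_stack([
        np.ones(len(df)),
        (df["depression_state"] == "mild").to_numpy(float),
        (df["depression_state"] == "moderate").to_numpy(float),
        (df["depression_state"] == "severe").to_numpy(float),
        df["age"].to_numpy(float),
        (df["gender"] == "female").to_numpy(float),
        (df["functional"] == "iadl_only").to_numpy(float),
        (df["functional"] == "adl_1_2").to_numpy(float),
        (df["functional"] == "adl_3plus").to_numpy(float),
    ])


def fit_care_mode_model(cross_section: pd.DataFrame,
                        age_min: float = CARE_AGE_MIN) -> CareModeFit:
    """ML fit of the care-mode multinomial on the 65+ cross-section."""
    df = cross_section[cross_section["age"] >= age_min].copy()
    counts = df["care_mode"].value_counts()
    empty = [m for m in CARE_MODES if counts.get(m, 0) == 0]
    if empty:
        raise ValueError(f"care modes with no observations: {empty}")
    codes = df["care_mode"].map({m: i for i, m in enumerate(CARE_MODES)})
    x = _care_design_frame(df)
    res = sm.MNLogit(codes.to_numpy(), x).fit(method="newton", maxiter=200,
                                              disp=0)
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("care-mode fit did not converge")
    idx = ["intercept"] + list(CARE_PREDICTORS)
    params = pd.DataFrame(np.asarray(res.params), index=idx,
                          columns=list(_MODES))
    bse = pd.DataFrame(np.asarray(res.bse), index=idx, columns=list(_MODES))
    return CareModeFit(params, bse, n_used=len(df))


def fit_hours_models(cross_section: pd.DataFrame,
                     age_min: float = CARE_AGE_MIN) -> HoursFit:
    """Least-squares weekly-hours models on care recipients (65+)."""
    df = cross_section[cross_section["age"] >= age_min]
    idx = ["intercept"] + list(CARE_PREDICTORS)
    params = pd.DataFrame(index=idx, columns=["home", "unpaid"], dtype=float)
    bse = pd.DataFrame(index=idx, columns=["home", "unpaid"], dtype=float)
    resid_sd, n_used = {}, {}
    for ct, flag, col in (("home", "home_care", "home_hours_week"),
                          ("unpaid", "unpaid_care", "unpaid_hours_week")):
        rec = df[df[flag].astype(bool)]
        x = _care_design_frame(rec)
        if len(rec) <= x.shape[1]:
            raise ValueError(f"too few {ct}-care recipients to fit hours model")
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(f"rank-deficient design for {ct} hours model")
        res = sm.OLS(rec[col].to_numpy(float), x).fit()
        params[ct] = res.params
        bse[ct] = res.bse
        resid_sd[ct] = float(np.sqrt(res.scale))
        n_used[ct] = len(rec)
    return HoursFit(params, bse, resid_sd, n_used)


def _cell_vector(cell: Mapping) -> np.ndarray:
    state = cell["depression"]
    if state not in STATES:
        raise ValueError(f"unknown depression state {state!r}")
    func = cell.get("functional", "none")
    if func not in FUNCTIONAL:
        raise ValueError(f"unknown functional category {func!r}")
    gender = cell["gender"]
    if gender not in GENDERS:
        raise ValueError(f"unknown gender {gender!r}")
    return np.array([
        1.0,
        float(state == "mild"), float(state == "moderate"),
        float(state == "severe"),
        float(cell["age"]), float(gender == "female"),
        float(func == "iadl_only"), float(func == "adl_1_2"),
        float(func == "adl_3plus"),
    ])


def predict_care_probs(fit: CareModeFit, cell: Mapping) -> np.ndarray:
    """Care-mode probabilities (none, unpaid only, home only, both) for
    one population cell; softmax of the fitted linear predictors."""
    xv = _cell_vector(cell)
    lp = xv @ fit.params.to_numpy()
    full = np.concatenate([[0.0], lp])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def user_probabilities(p_modes: np.ndarray) -> dict:
    """Marginal user probabilities: unpaid = unpaid-only + both,
    home = home-only + both."""
    return {"unpaid": float(p_modes[1] + p_modes[3]),
            "home": float(p_modes[2] + p_modes[3])}


def predict_hours(fit: HoursFit, cell: Mapping, care_type: str) -> float:
    """Predicted weekly hours of a care type for a cell, floored at 0."""
    if care_type not in ("home", "unpaid"):
        raise ValueError("care_type must be 'home' or 'unpaid'")
    xv = _cell_vector(cell)
    return float(max(0.0, xv @ fit.params[care_type].to_numpy()))


def functional_conditional_from_panel(analysis: pd.DataFrame,
                                      age_min: float = CARE_AGE_MIN
                                      ) -> np.ndarray:
    """P(functional category | depression state) estimated from the
    base-wave 65+ cross-section, shape (4 states, 4 categories)."""
    w1 = analysis[(analysis["wave"] == analysis["wave"].min())
                  & (analysis["age"] >= age_min)]
    table = np.zeros((4, 4))
    for s, state in enumerate(STATES):
        sub = w1[w1["depression_state"] == state]
        if len(sub) == 0:
            table[s] = np.array([1.0, 0.0, 0.0, 0.0])
            continue
        shares = (sub["functional"].value_counts(normalize=True)
                  .reindex(list(FUNCTIONAL)).fillna(0.0))
        table[s] = shares.to_numpy()
    return table
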
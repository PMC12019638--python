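"""Derivation of analysis variables from raw person-wave records.

Depressive symptoms are measured with the 8-item CES-D battery (six
negative statements, two positive statements).  The symptom score is the
number of symptom-consistent answers: "yes" to a negative statement or
"no" to a positive one, giving a 0-8 count.  Severity bands: 0 = no
symptoms, 1-2 = mild, 3-5 = moderate, 6-8 = severe.
"""
from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .config import CARE_MODES, FUNCTIONAL, STATES

N_CESD_ITEMS = 8
N_NEGATIVE_ITEMS = 6   # items 0-5 are negative statements
MAX_HOUSING_PROBLEMS = 12

# score-band edges: none=0, mild=1-2, moderate=3-5, severe=6-8
CESD_BAND_UPPER = (0, 2, 5, 8)


def score_cesd(items: Sequence, n_negative: int = N_NEGATIVE_ITEMS) -> Optional[int]:
    """Sum the 8 binary CES-D items into a 0-8 symptom score.

    ``items`` holds the raw yes(1)/no(0) answers, negative statements
    first.  Positive statements are reverse-coded, so the score counts
    yes-to-negative plus no-to-positive.  Returns ``None`` when any item
    is missing (NaN/None): a part-missing battery yields no score and the
    record is excluded downstream rather than silently scored 0.
    """
    items = list(items)
    if len(items) != N_CESD_ITEMS:
        raise ValueError(f"expected {N_CESD_ITEMS} CES-D items, got {len(items)}")
    vals = []
    for x in items:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        if x not in (0, 1, True, False):
            raise ValueError(f"CES-D item must be binary, got {x!r}")
        vals.append(int(x))
    negative = sum(vals[:n_negative])
    positive = sum(1 - v for v in vals[n_negative:])
    return negative + positive


def classify_depression(score: int) -> str:
    """Map a 0-8 CES-D score onto the four severity states."""
    if not float(score).is_integer() or not 0 <= score <= 8:
        raise ValueError(f"CES-D score must be an integer in [0, 8], got {score!r}")
    score = int(score)
    for state, upper in zip(STATES, CESD_BAND_UPPER):
        if score <= upper:
            return state
    raise AssertionError("unreachable")


def classify_functional(adl_count: int, iadl_count: int) -> str:
    """Four-level functional-difficulty category from ADL/IADL counts.

    No difficulties; IADL difficulties only; one or two ADL
    difficulties; three or more ADL difficulties.
    """
    if adl_count < 0 or iadl_count < 0:
        raise ValueError("difficulty counts must be nonnegative")
    if adl_count == 0:
        return "none" if iadl_count == 0 else "iadl_only"
    return "adl_1_2" if adl_count <= 2 else "adl_3plus"


def derive_care_mode(unpaid: bool, home: bool) -> str:
    """Care-utilization category from the two receipt flags."""
    if unpaid and home:
        return "both"
    if unpaid:
        return "unpaid_only"
    if home:
        return "home_only"
    return "none"


def total_weekly_hours(task_hours: Iterable[float]) -> float:
    """Total weekly care hours across ADL/IADL tasks."""
    total = 0.0
    for h in task_hours:
        if h < 0:
            raise ValueError("task hours must be nonnegative")
        total += float(h)
    return total


def equivalise_income(household_income: float, adults_14plus: int,
                      children_under14: int = 0) -> float:
    """Equivalised weekly income: household income over the household
    weight (1.0 first adult, 0.5 each further person aged 14+, 0.3 each
    child under 14)."""
    if adults_14plus < 1:
        raise ValueError("household must contain at least one adult")
    if household_income < 0:
        raise ValueError("income must be nonnegative")
    if children_under14 < 0:
        raise ValueError("children count must be nonnegative")
    weight = 1.0 + 0.5 * (adults_14plus - 1) + 0.3 * children_under14
    return household_income / weight


def build_analysis_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Turn a raw panel (one row per person-wave) into the analysis table.

    Adds ``cesd_score``, ``depression_state``, ``functional`` and
    ``care_mode``; drops records of dead individuals and person-waves
    with incomplete CES-D batteries; validates housing-problem counts.
    """
    item_cols = [f"cesd_{i + 1}" for i in range(N_CESD_ITEMS)]
    missing = [c for c in item_cols if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing CES-D item columns: {missing}")
    if (panel["housing_problems"] > MAX_HOUSING_PROBLEMS).any() or \
            (panel["housing_problems"] < 0).any():
        raise ValueError(
            f"housing_problems must be in [0, {MAX_HOUSING_PROBLEMS}]")

    df = panel.copy()
    if "alive" in df.columns:
        df = df[df["alive"].astype(bool)]
    items = df[item_cols]
    complete = items.notna().all(axis=1)
    df = df[complete].copy()
    items = df[item_cols].astype(int)

    negative = items.iloc[:, :N_NEGATIVE_ITEMS].sum(axis=1)
    positive = (1 - items.iloc[:, N_NEGATIVE_ITEMS:]).sum(axis=1)
    df["cesd_score"] = (negative + positive).astype(int)
    df["depression_state"] = pd.Categorical(
        np.select(
            [df["cesd_score"] == 0, df["cesd_score"] <= 2, df["cesd_score"] <= 5],
            ["none", "mild", "moderate"], default="severe"),
        categories=list(STATES), ordered=True)
    df["functional"] = pd.Categorical(
        [classify_functional(a, i)
         for a, i in zip(df["adl_count"], df["iadl_count"])],
        categories=list(FUNCTIONAL), ordered=True)
    df["care_mode"] = pd.Categorical(
        [derive_care_mode(u, h)
         for u, h in zip(df["unpaid_care"].astype(bool),
                         df["home_care"].astype(bool))],
        categories=list(CARE_MODES))
    return df
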
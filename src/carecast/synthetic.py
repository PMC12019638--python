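"""Seeded synthetic panel and demographic inputs.

The generator emulates the statistical structure the downstream analysis
assumes: a biennial longitudinal survey of adults aged 50+, with an
8-item CES-D depression battery, housing-problem counts, functional
difficulties, and receipt and weekly hours of unpaid and formal home
care.  Wave-to-wave depression states follow the lagged multinomial-
logit data-generating process with configurable coefficients; care
receipt follows a cross-sectional multinomial with hours drawn from
linear models on recipients.  Mortality is Gompertz, attrition is
missing-at-random.  All randomness flows from one seeded generator.
"""
from __future__ import annotations

from typing import Optional, Union

import numpy as np
import pandas as pd

from .config import (
    CARE_MODES,
    GENDERS,
    EDUCATION,
    GeneratorConfig,
    GompertzMortality,
    STATES,
    TRANSITION_PREDICTORS,
    CARE_PREDICTORS,
)
from .preprocessing import MAX_HOUSING_PROBLEMS, N_CESD_ITEMS, N_NEGATIVE_ITEMS

# CES-D score bounds per state band
_BAND_LO = np.array([0, 1, 3, 6])
_BAND_HI = np.array([0, 2, 5, 8])

PANEL_COLUMNS = (
    ["person_id", "wave", "age", "gender", "tenure", "education", "income",
     "housing_problems"]
    + [f"cesd_{i + 1}" for i in range(N_CESD_ITEMS)]
    + ["adl_count", "iadl_count", "unpaid_care", "home_care",
       "unpaid_hours_week", "home_hours_week", "alive"]
)


def _coef_matrix(coeffs: dict, predictors, outcomes) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-outcome coefficient dicts into (intercepts, beta matrix)."""
    beta = np.zeros((len(outcomes), len(predictors)))
    alpha = np.zeros(len(outcomes))
    for i, out in enumerate(outcomes):
        c = coeffs[out]
        alpha[i] = c.get("intercept", 0.0)
        for j, p in enumerate(predictors):
            beta[i, j] = c.get(p, 0.0)
    return alpha, beta


def _softmax_with_base(lp: np.ndarray) -> np.ndarray:
    """Probabilities over (base, outcome_1..k) from k linear predictors."""
    full = np.concatenate([np.zeros((*lp.shape[:-1], 1)), lp], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def _sample_categorical(rng: np.random.Generator, probs: np.ndarray) -> np.ndarray:
    """Row-wise categorical draw from an (n, k) probability matrix."""
    cum = probs.cumsum(axis=1)
    u = rng.random((probs.shape[0], 1))
    return (u > cum[:, :-1]).sum(axis=1)


def _draw_cesd_items(rng: np.random.Generator, states: np.ndarray) -> np.ndarray:
    """Item responses consistent with each person's severity band.

    A score is drawn uniformly within the band, then that many of the 8
    items are made symptom-consistent (yes to a negative statement, no
    to a positive one) at random positions.
    """
    n = states.shape[0]
    score = rng.integers(_BAND_LO[states], _BAND_HI[states] + 1)
    rank = np.argsort(rng.random((n, N_CESD_ITEMS)), axis=1).argsort(axis=1)
    symptomatic = rank < score[:, None]
    items = np.empty((n, N_CESD_ITEMS), dtype=int)
    items[:, :N_NEGATIVE_ITEMS] = symptomatic[:, :N_NEGATIVE_ITEMS]
    items[:, N_NEGATIVE_ITEMS:] = 1 - symptomatic[:, N_NEGATIVE_ITEMS:]
    return items


def _functional_counts(rng: np.random.Generator, category: np.ndarray):
    """ADL/IADL difficulty counts consistent with a functional category."""
    n = category.shape[0]
    adl = np.zeros(n, dtype=int)
    iadl = np.zeros(n, dtype=int)
    m = category == 1  # IADLs only
    iadl[m] = rng.integers(1, 4, size=m.sum())
    m = category == 2  # 1-2 ADLs
    adl[m] = rng.integers(1, 3, size=m.sum())
    iadl[m] = rng.integers(0, 3, size=m.sum())
    m = category == 3  # 3+ ADLs
    adl[m] = rng.integers(3, 7, size=m.sum())
    iadl[m] = rng.integers(0, 4, size=m.sum())
    return adl, iadl


def _transition_design(age, female, rented, edu, income, housing, state):
    """Design matrix in TRANSITION_PREDICTORS order for current state."""
    n = age.shape[0]
    x = np.zeros((n, len(TRANSITION_PREDICTORS)))
    x[:, 0] = housing
    for s in (1, 2, 3):
        x[:, s] = state == s
    x[:, 4] = age
    x[:, 5] = female
    x[:, 6] = rented
    x[:, 7] = edu == 1
    x[:, 8] = edu == 2
    x[:, 9] = income
    return x


def _care_design(age, female, state, functional):
    x = np.zeros((age.shape[0], len(CARE_PREDICTORS)))
    for s in (1, 2, 3):
        x[:, s - 1] = state == s
    x[:, 3] = age
    x[:, 4] = female
    for f in (1, 2, 3):
        x[:, 4 + f] = functional == f
    return x


def _gompertz_q(mort: GompertzMortality, age: np.ndarray,
                female: np.ndarray) -> np.ndarray:
    a = np.where(female, mort.a_female, mort.a_male)
    b = np.where(female, mort.b_female, mort.b_male)
    return np.minimum(1.0, a * np.exp(b * age))


def generate_panel(config: GeneratorConfig) -> pd.DataFrame:
    """Generate the synthetic person-wave panel.

    Returns one row per surviving, non-attrited person-wave with the
    columns of :data:`PANEL_COLUMNS`.  Waves are two years apart; death
    and dropout truncate a person's record.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals

    # fixed individual covariates
    a, b = config.age_beta
    age0 = config.age_min + config.age_range * rng.beta(a, b, size=n)
    female = rng.random(n) < config.female_share
    rented = rng.random(n) < config.rented_share
    edu = _sample_categorical(rng, np.tile(config.education_shares, (n, 1)))
    income = np.exp(rng.normal(config.income_log_mean, config.income_log_sd, n))
    # housing problems: band then count; held fixed across waves
    band = _sample_categorical(rng, np.tile(config.housing_distribution, (n, 1)))
    housing = band.copy()
    m3 = band == 3
    housing[m3] = np.minimum(
        3 + rng.geometric(0.6, size=m3.sum()) - 1, MAX_HOUSING_PROBLEMS)

    state = _sample_categorical(
        rng, np.tile(config.baseline_prevalence, (n, 1)))

    alpha_t, beta_t = _coef_matrix(
        config.transition_coefficients, TRANSITION_PREDICTORS,
        ("mild", "moderate", "severe"))
    # care modes in CARE_MODES order (base = none)
    alpha_c, beta_c = _coef_matrix(
        config.care_coefficients, CARE_PREDICTORS,
        ("unpaid_only", "home_only", "both"))
    hours_keys = ["intercept"] + list(CARE_PREDICTORS)
    hb = {ct: np.array([config.hours_coefficients[ct].get(k, 0.0)
                        for k in hours_keys])
          for ct in ("home", "unpaid")}

    active = np.ones(n, dtype=bool)
    person_id = np.arange(n)
    frames = []
    for wave in range(1, config.n_waves + 1):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        age = age0[idx] + 2.0 * (wave - 1)
        st = state[idx]
        items = _draw_cesd_items(rng, st)
        fcat = _sample_categorical(rng, config.functional_given_state[st])
        adl, iadl = _functional_counts(rng, fcat)

        xc = _care_design(age, female[idx].astype(float), st, fcat)
        cp = _softmax_with_base(alpha_c + xc @ beta_c.T)
        cmode = _sample_categorical(rng, cp)  # CARE_MODES order
        unpaid = (cmode == 1) | (cmode == 3)
        home = (cmode == 2) | (cmode == 3)
        xh = np.column_stack([np.ones(idx.size), xc])
        unpaid_hours = np.zeros(idx.size)
        home_hours = np.zeros(idx.size)
        mu = xh @ hb["unpaid"]
        unpaid_hours[unpaid] = np.maximum(
            0.5, mu[unpaid] + rng.normal(
                0, config.hours_resid_sd["unpaid"], unpaid.sum()))
        mh = xh @ hb["home"]
        home_hours[home] = np.maximum(
            0.5, mh[home] + rng.normal(
                0, config.hours_resid_sd["home"], home.sum()))

        frames.append(pd.DataFrame({
            "person_id": person_id[idx], "wave": wave, "age": age,
            "gender": np.where(female[idx], "female", "male"),
            "tenure": np.where(rented[idx], "rented", "owner"),
            "education": np.asarray(EDUCATION, dtype=object)[edu[idx]],
            "income": income[idx], "housing_problems": housing[idx],
            **{f"cesd_{i + 1}": items[:, i] for i in range(N_CESD_ITEMS)},
            "adl_count": adl, "iadl_count": iadl,
            "unpaid_care": unpaid, "home_care": home,
            "unpaid_hours_week": unpaid_hours, "home_hours_week": home_hours,
            "alive": True,
        }))

        if wave == config.n_waves:
            break
        # transition to the next wave: new state from the lagged model
        xt = _transition_design(age, female[idx].astype(float),
                                rented[idx].astype(float), edu[idx],
                                income[idx], housing[idx], st)
        tp = _softmax_with_base(alpha_t + xt @ beta_t.T)
        state[idx] = _sample_categorical(rng, tp)
        # two-year death probability from annual Gompertz rates
        q1a = _gompertz_q(config.mortality, age, female[idx])
        q1b = _gompertz_q(config.mortality, age + 1, female[idx])
        q2 = 1.0 - (1.0 - q1a) * (1.0 - q1b)
        died = rng.random(idx.size) < q2
        dropped = rng.random(idx.size) < config.attrition_rate
        active[idx[died | dropped]] = False

    return pd.concat(frames, ignore_index=True)[list(PANEL_COLUMNS)]


# England-like single-age population anchors (both genders combined)
_POP_ANCHORS = ((45, 740_000.0), (55, 780_000.0), (65, 620_000.0),
                (75, 560_000.0), (85, 300_000.0), (95, 60_000.0),
                (100, 8_000.0))


def generate_population_table(per_cell: Optional[float] = None,
                              age_min: int = 45, age_max: int = 100,
                              scale: float = 1.0) -> pd.DataFrame:
    """Base-year population counts by single year of age and gender.

    The default profile is a smooth England-like age pyramid (about 10.5
    million aged 65+); ``per_cell`` replaces it with a flat profile.
    The table is deterministic.
    """
    if per_cell is not None and per_cell < 0:
        raise ValueError("per_cell must be nonnegative")
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    ages = np.arange(age_min, age_max + 1)
    if per_cell is not None:
        counts = {g: np.full(ages.size, float(per_cell)) for g in GENDERS}
    else:
        xs = [a for a, _ in _POP_ANCHORS]
        ys = [c for _, c in _POP_ANCHORS]
        total = np.interp(ages, xs, ys)
        fem_share = np.clip(0.50 + 0.0025 * (ages - 45), 0.50, 0.65)
        counts = {"male": total * (1 - fem_share), "female": total * fem_share}
    rows = [pd.DataFrame({"age": ages, "gender": g, "count": counts[g] * scale})
            for g in GENDERS]
    out = pd.concat(rows, ignore_index=True)
    if (out["count"] < 0).any():
        raise ValueError("population counts must be nonnegative")
    return out


def generate_mortality_schedule(mortality: GompertzMortality = None,
                                age_min: int = 45,
                                age_max: int = 100) -> pd.DataFrame:
    """Annual death probability by single age and gender (Gompertz)."""
    mortality = mortality or GompertzMortality()
    ages = np.arange(age_min, age_max + 1)
    rows = []
    for g in GENDERS:
        female = np.full(ages.size, g == "female")
        q = _gompertz_q(mortality, ages.astype(float), female)
        rows.append(pd.DataFrame({"age": ages, "gender": g, "q": q}))
    return pd.concat(rows, ignore_index=True)


def generate_unit_cost_path(base_cost: float,
                            growth: Union[float, dict] = 0.0,
                            uplift_2024: float = 1.0,
                            start: int = 2022,
                            horizon: int = 2042) -> pd.Series:
    """Real unit-cost path (GBP/hour) from the base year to the horizon.

    Costs grow by ``growth`` (a scalar rate or a {year: rate} mapping,
    applied over [year, year+1)) with a one-off uplift factor in 2024
    for the planned rise in the national living wage.
    """
    if base_cost < 0:
        raise ValueError("base cost must be nonnegative")
    if horizon < start:
        raise ValueError("horizon must not precede the base year")
    years = np.arange(start, horizon + 1)
    path = np.empty(years.size)
    path[0] = base_cost
    for i, y in enumerate(years[:-1]):
        g = growth.get(y, 0.0) if isinstance(growth, dict) else growth
        path[i + 1] = path[i] * (1.0 + g)
        if y + 1 == 2024:
            path[i + 1] *= uplift_2024
    return pd.Series(path, index=years, name="unit_cost")
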
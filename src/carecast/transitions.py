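"""Lagged multinomial transition model and annual transition matrices.

The transition model regresses depressive-symptom severity at wave T+1
(none/mild/moderate/severe, base outcome none) on covariates at wave T:
housing-problem count, current severity, age, gender, tenure, education
and equivalised income.  Predicted two-year transition probabilities are
converted to annual ones under a constant-hazard assumption,

    p1 = 1 - (1 - p2)**0.5,

applied per destination with the diagonal restored, and mixed over a
stratum-level housing-problem distribution to give one 5-state annual
matrix (four living states plus absorbing death) per age and gender.
Housing-intervention scenarios cap the housing distribution at 2, 1 or
0 problems before mixing.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import (
    EDUCATION,
    GENDERS,
    STATES,
    STATES_DEAD,
    STATE_MORTALITY_MULTIPLIERS,
    TRANSITION_INTERCEPTS,
    TRANSITION_PREDICTORS,
    TRANSITION_RRR,
    TRANSITION_RRR_SE,
)
from .preprocessing import MAX_HOUSING_PROBLEMS

_OUTCOMES = ("mild", "moderate", "severe")
N_HOUSING = MAX_HOUSING_PROBLEMS + 1  # housing-problem counts 0..12


@dataclass
class TransitionModelFit:
    """Fitted lagged multinomial model on the log relative-risk scale.

    ``params`` and ``bse`` are indexed by ``["intercept", *predictors]``
    with one column per non-base outcome; the base outcome (no
    symptoms) carries implicit zeros.
    """
    params: pd.DataFrame
    bse: pd.DataFrame
    n_used: int

    def __post_init__(self):
        if list(self.params.columns) != list(_OUTCOMES):
            raise ValueError(f"outcome columns must be {_OUTCOMES}")
        if not (self.bse.values >= 0).all():
            raise ValueError("standard errors must be nonnegative")

    @property
    def rrr(self) -> pd.DataFrame:
        """Relative risk ratios (exponentiated coefficients)."""
        return np.exp(self.params.drop(index="intercept"))

    def to_table(self) -> pd.DataFrame:
        """Long coefficient table (outcome, predictor, coef, se)."""
        rows = []
        for out in _OUTCOMES:
            for pred in self.params.index:
                rows.append((out, pred, self.params.loc[pred, out],
                             self.bse.loc[pred, out]))
        return pd.DataFrame(rows, columns=["outcome", "predictor", "coef", "se"])

    @classmethod
    def from_table(cls, table: pd.DataFrame, n_used: int = 0) -> "TransitionModelFit":
        params = table.pivot(index="predictor", columns="outcome", values="coef")
        bse = table.pivot(index="predictor", columns="outcome", values="se")
        idx = ["intercept"] + [p for p in TRANSITION_PREDICTORS]
        return cls(params.reindex(idx)[list(_OUTCOMES)],
                   bse.reindex(idx)[list(_OUTCOMES)], n_used)

    @classmethod
    def from_published(cls) -> "TransitionModelFit":
        """Fit object assembled from the published relative risk ratios
        (with calibrated intercepts), usable without refitting."""
        idx = ["intercept"] + list(TRANSITION_PREDICTORS)
        params = pd.DataFrame(0.0, index=idx, columns=list(_OUTCOMES))
        bse = pd.DataFrame(0.0, index=idx, columns=list(_OUTCOMES))
        for out in _OUTCOMES:
            params.loc["intercept", out] = TRANSITION_INTERCEPTS[out]
            for pred, rrr in TRANSITION_RRR[out].items():
                params.loc[pred, out] = math.log(rrr)
                # delta method: se(log RRR) ~= se(RRR) / RRR
                bse.loc[pred, out] = TRANSITION_RRR_SE[out][pred] / rrr
        return cls(params, bse, n_used=0)


def make_lagged_pairs(analysis: pd.DataFrame) -> pd.DataFrame:
    """Pool consecutive person-wave pairs (T, T+1) into one table with
    wave-T covariates and the wave-T+1 outcome ``next_state``."""
    df = analysis.sort_values(["person_id", "wave"])
    nxt = df.groupby("person_id")["depression_state"].shift(-1)
    wave_gap = df.groupby("person_id")["wave"].shift(-1) - df["wave"]
    pairs = df[(wave_gap == 1) & nxt.notna()].copy()
    pairs["next_state"] = pd.Categorical(
        nxt[pairs.index], categories=list(STATES), ordered=True)
    return pairs


def _design(df: pd.DataFrame) -> np.ndarray:
    """Design matrix with columns [const, *TRANSITION_PREDICTORS]."""
    bad_edu = set(df["education"].unique()) - set(EDUCATION)
    if bad_edu:
        raise ValueError(f"unknown education levels: {bad_edu}")
    bad_ten = set(df["tenure"].unique()) - {"owner", "rented"}
    if bad_ten:
        raise ValueError(f"unknown tenure levels: {bad_ten}")
    x = np.column_stack([
        np.ones(len(df)),
        df["housing_problems"].to_numpy(float),
        (df["depression_state"] == "mild").to_numpy(float),
        (df["depression_state"] == "moderate").to_numpy(float),
        (df["depression_state"] == "severe").to_numpy(float),
        df["age"].to_numpy(float),
        (df["gender"] == "female").to_numpy(float),
        (df["tenure"] == "rented").to_numpy(float),
        (df["education"] == "nvq_gce_cse").to_numpy(float),
        (df["education"] == "degree_or_below").to_numpy(float),
        df["income"].to_numpy(float),
    ])
    return x


def fit_transition_model(analysis: pd.DataFrame) -> TransitionModelFit:
    """Maximum-likelihood fit of the lagged multinomial transition model.

    ``analysis`` is the analysis-ready panel (see
    :func:`carecast.preprocessing.build_analysis_table`); consecutive
    wave pairs are pooled.  Raises if any outcome category is absent or
    the optimizer fails (e.g. separation).
    """
    pairs = make_lagged_pairs(analysis)
    need = ["housing_problems", "age", "gender", "tenure", "education",
            "income", "depression_state", "next_state"]
    pairs = pairs.dropna(subset=need)
    counts = pairs["next_state"].value_counts()
    empty = [s for s in STATES if counts.get(s, 0) == 0]
    if empty:
        raise ValueError(f"outcome categories with no observations: {empty}")
    y = pairs["next_state"].cat.codes.to_numpy()
    x = _design(pairs)
    model = sm.MNLogit(y, x)
    try:
        res = model.fit(method="newton", maxiter=200, disp=0)
    except Exception as exc:  # pragma: no cover - statsmodels failure modes
        raise RuntimeError(f"multinomial fit failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise RuntimeError("multinomial fit did not converge "
                           "(possible separation or collinearity)")
    idx = ["intercept"] + list(TRANSITION_PREDICTORS)
    params = pd.DataFrame(np.asarray(res.params), index=idx,
                          columns=list(_OUTCOMES))
    bse = pd.DataFrame(np.asarray(res.bse), index=idx, columns=list(_OUTCOMES))
    return TransitionModelFit(params, bse, n_used=len(pairs))


def _profile_vector(fit: TransitionModelFit, profile: Mapping) -> np.ndarray:
    state = profile["current_state"]
    if state not in STATES:
        raise ValueError(f"unknown depression state {state!r}")
    gender = profile["gender"]
    if gender not in GENDERS:
        raise ValueError(f"unknown gender {gender!r}")
    edu = profile.get("education", "none")
    if edu not in EDUCATION:
        raise ValueError(f"unknown education level {edu!r}")
    tenure = profile.get("tenure", "owner")
    if tenure not in ("owner", "rented"):
        raise ValueError(f"unknown tenure {tenure!r}")
    vals = {
        "housing_problems": float(profile["housing_problems"]),
        "state_mild": float(state == "mild"),
        "state_moderate": float(state == "moderate"),
        "state_severe": float(state == "severe"),
        "age": float(profile["age"]),
        "female": float(gender == "female"),
        "rented": float(tenure == "rented"),
        "edu_nvq_gce_cse": float(edu == "nvq_gce_cse"),
        "edu_degree_or_below": float(edu == "degree_or_below"),
        "income": float(profile.get("income", 0.0)),
    }
    return np.array([1.0] + [vals[p] for p in TRANSITION_PREDICTORS])


def predict_two_year_probs(fit: TransitionModelFit,
                           profile: Mapping) -> np.ndarray:
    """Predicted two-year probabilities over the four living states for
    one covariate profile (softmax of the fitted linear predictors)."""
    xv = _profile_vector(fit, profile)
    lp = xv @ fit.params.to_numpy()          # (3,)
    full = np.concatenate([[0.0], lp])
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def annualize_probability(p2: float) -> float:
    """Annual transition probability from a two-year one under a
    constant instantaneous rate: p1 = 1 - (1 - p2)**(1/2)."""
    if not 0.0 <= p2 <= 1.0:
        raise ValueError(f"probability must be in [0, 1], got {p2}")
    return 1.0 - math.sqrt(1.0 - p2)


def annualize_row(p2_row: Sequence[float], origin: int) -> np.ndarray:
    """Annualize one two-year transition row per destination.

    Off-diagonal entries are converted with the constant-hazard formula;
    the stay probability is restored as the complement.  If the
    annualized moves exceed 1 the moves are rescaled proportionally (the
    per-destination conversion is an approximation; exact only in the
    two-state case).
    """
    row = np.asarray(p2_row, dtype=float)
    if row.min() < -1e-12 or row.max() > 1 + 1e-12:
        raise ValueError("row entries must be probabilities")
    if not math.isclose(row.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("two-year row must sum to 1")
    out = 1.0 - np.sqrt(np.clip(1.0 - row, 0.0, 1.0))
    out[origin] = 0.0
    moves = out.sum()
    if moves > 1.0:
        out /= moves
        moves = 1.0
    out[origin] = 1.0 - moves
    return out


def uniform_housing_expansion(band_probs: Sequence[float],
                              tail_ratio: float = 0.4) -> np.ndarray:
    """Expand mass on bands {0,1,2,3+} to counts 0..12, spreading the 3+
    band geometrically."""
    band_probs = np.asarray(band_probs, dtype=float)
    full = np.zeros(N_HOUSING)
    full[:3] = band_probs[:3]
    tail = tail_ratio ** np.arange(N_HOUSING - 3)
    full[3:] = band_probs[3] * tail / tail.sum()
    return full


def apply_housing_scenario(dist: Sequence[float], cap: float) -> np.ndarray:
    """Cap the housing-problem distribution: all mass above ``cap`` is
    relocated onto ``cap``.  ``cap=inf`` is the no-intervention identity."""
    dist = np.asarray(dist, dtype=float)
    if (dist < 0).any() or not math.isclose(dist.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("housing distribution must be a probability vector")
    if cap < 0:
        raise ValueError("cap must be nonnegative")
    if math.isinf(cap):
        return dist.copy()
    cap = int(cap)
    out = dist.copy()
    if cap < dist.size - 1:
        out[cap] += out[cap + 1:].sum()
        out[cap + 1:] = 0.0
    return out


def default_covariate_means(config=None) -> dict:
    """Stratum-mean values for the covariates held fixed when
    materializing matrices (tenure, education, income)."""
    from .config import GeneratorConfig
    config = config or GeneratorConfig()
    return {
        "rented": config.rented_share,
        "edu_nvq_gce_cse": config.education_shares[1],
        "edu_degree_or_below": config.education_shares[2],
        "income": float(np.exp(config.income_log_mean
                               + config.income_log_sd ** 2 / 2)),
    }


def covariate_means_from_panel(analysis: pd.DataFrame) -> dict:
    """Observed stratum means of tenure, education and income."""
    return {
        "rented": float((analysis["tenure"] == "rented").mean()),
        "edu_nvq_gce_cse": float((analysis["education"] == "nvq_gce_cse").mean()),
        "edu_degree_or_below": float(
            (analysis["education"] == "degree_or_below").mean()),
        "income": float(analysis["income"].mean()),
    }


def _annual_rows_by_housing(fit: TransitionModelFit, ages: np.ndarray,
                            female: bool, covariate_means: Mapping) -> np.ndarray:
    """Annualized predicted rows, shape (n_ages, 4 origins, 13 housing
    levels, 4 destinations)."""
    beta = fit.params.to_numpy()  # (11, 3) rows: intercept + predictors
    b = {name: beta[i + 1] for i, name in enumerate(TRANSITION_PREDICTORS)}
    fixed = (beta[0]
             + b["female"] * float(female)
             + b["rented"] * covariate_means["rented"]
             + b["edu_nvq_gce_cse"] * covariate_means["edu_nvq_gce_cse"]
             + b["edu_degree_or_below"] * covariate_means["edu_degree_or_below"]
             + b["income"] * covariate_means["income"])
    state_term = np.stack([np.zeros(3), b["state_mild"],
                           b["state_moderate"], b["state_severe"]])  # (4,3)
    h = np.arange(N_HOUSING)
    lp = (fixed[None, None, None, :]
          + np.asarray(ages, float)[:, None, None, None] * b["age"]
          + state_term[None, :, None, :]
          + h[None, None, :, None] * b["housing_problems"])
    full = np.concatenate([np.zeros((*lp.shape[:-1], 1)), lp], axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    p2 = e / e.sum(axis=-1, keepdims=True)  # (A, 4, 13, 4)

    p1 = 1.0 - np.sqrt(np.clip(1.0 - p2, 0.0, 1.0))
    origins = np.arange(4)
    p1[:, origins, :, origins] = 0.0
    moves = p1.sum(axis=-1, keepdims=True)
    scale = np.where(moves > 1.0, 1.0 / np.maximum(moves, 1e-300), 1.0)
    p1 *= scale
    stay = 1.0 - p1.sum(axis=-1)
    p1[:, origins, :, origins] = stay[:, origins, :].transpose(1, 0, 2)
    return p1


def build_transition_matrix(fit: TransitionModelFit, age: float, gender: str,
                            dist: Sequence[float], mortality_rate: float,
                            state_mortality_multipliers: Sequence[float]
                            = STATE_MORTALITY_MULTIPLIERS,
                            covariate_means: Optional[Mapping] = None,
                            state_shares: Sequence[float] = None) -> np.ndarray:
    """One 5x5 annual transition matrix for an (age, gender) stratum.

    Death is resolved first: the death probability from living state s is
    ``mortality_rate * m_s / sum_k w_k m_k`` with multipliers ``m`` and
    stratum state shares ``w`` (so the share-weighted death probability
    equals the marginal rate).  Surviving mass moves between living
    states according to the housing-distribution mixture of annualized
    predicted rows.
    """
    if not 0.0 <= mortality_rate <= 1.0:
        raise ValueError("mortality_rate must be in [0, 1]")
    mult = np.asarray(state_mortality_multipliers, dtype=float)
    if (mult <= 0).any():
        raise ValueError("mortality multipliers must be positive")
    dist = np.asarray(dist, dtype=float)
    if dist.size != N_HOUSING:
        dist = uniform_housing_expansion(dist) if dist.size == 4 else dist
    if dist.size != N_HOUSING:
        raise ValueError(f"housing distribution must have {N_HOUSING} entries")
    covariate_means = covariate_means or default_covariate_means()
    if state_shares is None:
        from .config import GeneratorConfig
        state_shares = GeneratorConfig().baseline_prevalence
    w = np.asarray(state_shares, dtype=float)
    w = w / w.sum()

    rows = _annual_rows_by_housing(
        fit, np.array([age]), gender == "female", covariate_means)[0]
    living = np.einsum("h,shd->sd", dist, rows)  # (4, 4)
    if np.any(~np.isfinite(living)) or np.any(living.sum(axis=1) <= 0):
        raise ValueError("degenerate living transition row")
    death = np.clip(mortality_rate * mult / (w @ mult), 0.0, 1.0)

    m = np.zeros((5, 5))
    m[:4, :4] = living * (1.0 - death)[:, None]
    m[:4, 4] = death
    m[4, 4] = 1.0
    return m


@dataclass
class TransitionMatrixSet:
    """Annual 5-state matrices for every (single age, gender) stratum.

    ``matrices`` has shape (n_ages, 2, 5, 5) with genders in
    :data:`carecast.config.GENDERS` order.
    """
    ages: np.ndarray
    matrices: np.ndarray

    def __post_init__(self):
        if self.matrices.shape != (self.ages.size, 2, 5, 5):
            raise ValueError("matrix array shape mismatch")

    def matrix(self, age: float, gender: str) -> np.ndarray:
        i = int(np.searchsorted(self.ages, age))
        return self.matrices[i, GENDERS.index(gender)]

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for g, gender in enumerate(GENDERS):
                for s, origin in enumerate(STATES_DEAD):
                    for d, dest in enumerate(STATES_DEAD):
                        rows.append((int(a), gender, origin, dest,
                                     self.matrices[i, g, s, d]))
        return pd.DataFrame(
            rows, columns=["age", "gender", "origin", "destination",
                           "probability"])


def build_matrix_set(fit: TransitionModelFit, mortality: pd.DataFrame,
                     dist: Sequence[float],
                     covariate_means: Optional[Mapping] = None,
                     state_mortality_multipliers: Sequence[float]
                     = STATE_MORTALITY_MULTIPLIERS,
                     state_shares: Sequence[float] = None) -> TransitionMatrixSet:
    """Materialize annual matrices for all ages and genders at once.

    ``mortality`` is the (age, gender, q) schedule; ``dist`` a housing
    distribution over counts 0..12 (or 4 bands, expanded).
    """
    dist = np.asarray(dist, dtype=float)
    if dist.size == 4:
        dist = uniform_housing_expansion(dist)
    covariate_means = covariate_means or default_covariate_means()
    if state_shares is None:
        from .config import GeneratorConfig
        state_shares = GeneratorConfig().baseline_prevalence
    w = np.asarray(state_shares, dtype=float)
    w = w / w.sum()
    mult = np.asarray(state_mortality_multipliers, dtype=float)

    ages = np.sort(mortality["age"].unique())
    mats = np.zeros((ages.size, 2, 5, 5))
    qtab = mortality.set_index(["gender", "age"])["q"]
    for g, gender in enumerate(GENDERS):
        rows = _annual_rows_by_housing(fit, ages, gender == "female",
                                       covariate_means)
        living = np.einsum("h,ashd->asd", dist, rows)  # (A, 4, 4)
        q = qtab.loc[gender].reindex(ages).to_numpy()
        death = np.clip(q[:, None] * mult[None, :] / (w @ mult), 0.0, 1.0)
        mats[:, g, :4, :4] = living * (1.0 - death)[:, :, None]
        mats[:, g, :4, 4] = death
        mats[:, g, 4, 4] = 1.0
    return TransitionMatrixSet(ages=ages, matrices=mats)
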
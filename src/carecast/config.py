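"""Configuration objects and published default parameters.

The default regression coefficients bundled here are the published
estimates from the ELSA-based study of housing quality and late-life
depressive symptoms: relative risk ratios of a lagged multinomial
transition model (depressive-symptom state at wave T+1 on covariates at
wave T) and of a cross-sectional care-utilization model, plus OLS
coefficients for weekly hours of care among recipients.  They serve two
roles: as ground truth for the synthetic-cohort generator, and as an
importable coefficient set so projections can run without refitting.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

# canonical category orders used throughout the package
STATES = ("none", "mild", "moderate", "severe")  # living depression states
STATES_DEAD = STATES + ("dead",)
FUNCTIONAL = ("none", "iadl_only", "adl_1_2", "adl_3plus")
CARE_MODES = ("none", "unpaid_only", "home_only", "both")
GENDERS = ("male", "female")
EDUCATION = ("none", "nvq_gce_cse", "degree_or_below")

AGE_MIN, AGE_MAX = 45, 100  # projection age range; AGE_MAX is open-ended
CARE_AGE_MIN = 65           # care models and cost tables cover 65+
AGE_BANDS = ((65, 69), (70, 74), (75, 79), (80, 84), (85, 89), (90, 150))

BASE_YEAR = 2022
HORIZON_YEAR = 2042
WEEKS_PER_YEAR = 52.14

# predictors of the transition model, in design-matrix order
TRANSITION_PREDICTORS = (
    "housing_problems",
    "state_mild", "state_moderate", "state_severe",
    "age", "female", "rented",
    "edu_nvq_gce_cse", "edu_degree_or_below",
    "income",
)
# predictors of the care-mode and hours models
CARE_PREDICTORS = (
    "state_mild", "state_moderate", "state_severe",
    "age", "female",
    "func_iadl_only", "func_adl_1_2", "func_adl_3plus",
)


def _log(rrrs):
    return {k: math.log(v) for k, v in rrrs.items()}


# Published relative risk ratios of the lagged transition model
# (outcome: symptom severity at T+1; base outcome: no symptoms).
TRANSITION_RRR = {
    "mild": {
        "housing_problems": 1.12, "state_mild": 3.73, "state_moderate": 5.54,
        "state_severe": 4.58, "age": 1.02, "female": 1.36, "rented": 1.22,
        "edu_nvq_gce_cse": 0.94, "edu_degree_or_below": 0.86, "income": 0.99,
    },
    "moderate": {
        "housing_problems": 1.24, "state_mild": 5.89, "state_moderate": 29.96,
        "state_severe": 46.91, "age": 1.03, "female": 1.48, "rented": 1.70,
        "edu_nvq_gce_cse": 0.82, "edu_degree_or_below": 0.70, "income": 0.99,
    },
    "severe": {
        "housing_problems": 1.28, "state_mild": 6.24, "state_moderate": 52.06,
        "state_severe": 267.68, "age": 1.02, "female": 1.85, "rented": 2.20,
        "edu_nvq_gce_cse": 0.96, "edu_degree_or_below": 0.97, "income": 0.99,
    },
}
# Standard errors as printed (on the RRR scale); converted to the log
# scale by the delta method where a log-scale SE is needed.
TRANSITION_RRR_SE = {
    "mild": {
        "housing_problems": 0.02, "state_mild": 0.13, "state_moderate": 0.36,
        "state_severe": 0.64, "age": 0.002, "female": 0.05, "rented": 0.07,
        "edu_nvq_gce_cse": 0.04, "edu_degree_or_below": 0.04, "income": 0.0001,
    },
    "moderate": {
        "housing_problems": 0.03, "state_mild": 0.37, "state_moderate": 2.35,
        "state_severe": 6.4, "age": 0.003, "female": 0.07, "rented": 0.11,
        "edu_nvq_gce_cse": 0.05, "edu_degree_or_below": 0.05, "income": 0.0001,
    },
    "severe": {
        "housing_problems": 0.05, "state_mild": 0.84, "state_moderate": 7.11,
        "state_severe": 45.4, "age": 0.004, "female": 0.15, "rented": 0.21,
        "edu_nvq_gce_cse": 0.09, "edu_degree_or_below": 0.1, "income": 0.0002,
    },
}

# Intercepts are not published.  The values below were calibrated once so
# that, with the default covariate marginals, the generator's wave-to-wave
# state distribution stays in the neighbourhood of the observed wave-6/7
# marginals (about 45/36/14/5 percent).
TRANSITION_INTERCEPTS = {"mild": 1.3249, "moderate": -1.0047, "severe": -2.2843}

# Published care-mode relative risk ratios (base outcome: no care) for
# people aged 65+, and OLS coefficients for weekly hours among recipients.
CARE_RRR = {
    "home_only": {
        "state_mild": 1.80, "state_moderate": 2.44, "state_severe": 2.43,
        "age": 1.06, "female": 1.78,
        "func_iadl_only": 43.83, "func_adl_1_2": 13.89, "func_adl_3plus": 49.91,
    },
    "unpaid_only": {
        "state_mild": 1.56, "state_moderate": 2.43, "state_severe": 2.43,
        "age": 1.15, "female": 2.11,
        "func_iadl_only": 8.11, "func_adl_1_2": 4.81, "func_adl_3plus": 22.1,
    },
    "both": {
        "state_mild": 1.86, "state_moderate": 3.00, "state_severe": 2.76,
        "age": 1.15, "female": 2.27,
        "func_iadl_only": 39.59, "func_adl_1_2": 18.11, "func_adl_3plus": 147.75,
    },
}
CARE_RRR_SE = {
    "home_only": {
        "state_mild": 0.11, "state_moderate": 0.18, "state_severe": 0.25,
        "age": 0.004, "female": 0.09,
        "func_iadl_only": 4.51, "func_adl_1_2": 0.77, "func_adl_3plus": 5.1,
    },
    "unpaid_only": {
        "state_mild": 0.18, "state_moderate": 0.31, "state_severe": 0.43,
        "age": 0.01, "female": 0.2,
        "func_iadl_only": 1.53, "func_adl_1_2": 0.5, "func_adl_3plus": 3.44,
    },
    "both": {
        "state_mild": 0.23, "state_moderate": 0.38, "state_severe": 0.47,
        "age": 0.01, "female": 0.19,
        "func_iadl_only": 6.36, "func_adl_1_2": 1.98, "func_adl_3plus": 20.77,
    },
}
# Care-mode intercepts are unpublished; calibrated once so the 65+
# synthetic population under the default marginals uses unpaid care at
# ~12.5% and home care at ~6.5%.
CARE_INTERCEPTS = {"home_only": -9.9787, "unpaid_only": -14.2962,
                   "both": -17.1733}

HOURS_COEF = {
    "home": {
        "state_mild": 1.51, "state_moderate": -1.17, "state_severe": 0.40,
        "age": 0.04, "female": 0.20,
        "func_iadl_only": 5.18, "func_adl_1_2": 4.69, "func_adl_3plus": 11.15,
    },
    "unpaid": {
        "state_mild": 3.18, "state_moderate": 8.11, "state_severe": 6.97,
        "age": 0.21, "female": -4.99,
        "func_iadl_only": 4.46, "func_adl_1_2": 7.94, "func_adl_3plus": 26.25,
    },
}
HOURS_SE = {
    "home": {
        "state_mild": 2.96, "state_moderate": 2.85, "state_severe": 3.5,
        "age": 0.12, "female": 1.76,
        "func_iadl_only": 4.02, "func_adl_1_2": 3.15, "func_adl_3plus": 3.18,
    },
    "unpaid": {
        "state_mild": 1.33, "state_moderate": 1.45, "state_severe": 2.01,
        "age": 0.06, "female": 0.97,
        "func_iadl_only": 1.54, "func_adl_1_2": 1.2, "func_adl_3plus": 1.44,
    },
}
# Hours intercepts (unpublished): chosen so reference predictions are
# positive with headroom (a 75-year-old man with no symptoms or
# difficulties receives ~8 h/week of home care or ~15 h/week of unpaid
# care when he receives that care at all).
HOURS_INTERCEPTS = {"home": 5.0, "unpaid": -0.75}
HOURS_RESID_SD = {"home": 4.0, "unpaid": 5.0}

# Functional-difficulty distribution conditional on depression severity,
# rows = depression states, columns = FUNCTIONAL categories.  The study
# establishes the association but no generative law; these defaults give
# a plausible monotone gradient.
FUNCTIONAL_GIVEN_STATE = np.array([
    [0.80, 0.08, 0.09, 0.03],
    [0.70, 0.10, 0.13, 0.07],
    [0.55, 0.13, 0.19, 0.13],
    [0.45, 0.14, 0.22, 0.19],
])

# Differential mortality by depression state, normalized inside the
# matrix builder so the stratum's marginal rate is preserved.
STATE_MORTALITY_MULTIPLIERS = (1.0, 1.1, 1.3, 1.6)


def _check_simplex(p, name, n=None):
    p = np.asarray(p, dtype=float)
    if n is not None and p.shape[-1] != n:
        raise ValueError(f"{name} must have length {n}, got {p.shape[-1]}")
    if (p < 0).any():
        raise ValueError(f"{name} must be nonnegative")
    if not np.allclose(p.sum(axis=-1), 1.0, atol=1e-9):
        raise ValueError(f"{name} must sum to 1 (got {p.sum(axis=-1)})")
    return p


@dataclass
class GompertzMortality:
    """Annual death probability q(age) = a * exp(b * age), clipped at 1."""
    a_male: float = 2.3e-5
    b_male: float = 0.095
    a_female: float = 1.35e-5
    b_female: float = 0.097

    def __post_init__(self):
        for f in ("a_male", "a_female"):
            if getattr(self, f) < 0:
                raise ValueError("Gompertz level parameter must be >= 0")
        for f in ("b_male", "b_female"):
            if getattr(self, f) < 0:
                raise ValueError("Gompertz slope parameter must be >= 0")


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic longitudinal cohort generator.

    Defaults emulate the wave-6 marginals of the English Longitudinal
    Study of Ageing sample and use the published regression estimates as
    the data-generating truth.
    """
    n_individuals: int = 10_000
    n_waves: int = 4
    seed: int = 0
    # per-outcome log-RRR vectors over TRANSITION_PREDICTORS + intercept
    transition_coefficients: dict = field(
        default_factory=lambda: {
            out: {**_log(TRANSITION_RRR[out]),
                  "intercept": TRANSITION_INTERCEPTS[out]}
            for out in ("mild", "moderate", "severe")
        })
    care_coefficients: dict = field(
        default_factory=lambda: {
            mode: {**_log(CARE_RRR[mode]), "intercept": CARE_INTERCEPTS[mode]}
            for mode in ("home_only", "unpaid_only", "both")
        })
    hours_coefficients: dict = field(
        default_factory=lambda: {
            ct: {**HOURS_COEF[ct], "intercept": HOURS_INTERCEPTS[ct]}
            for ct in ("home", "unpaid")
        })
    hours_resid_sd: dict = field(default_factory=lambda: dict(HOURS_RESID_SD))
    # mass on {0, 1, 2, 3+} housing problems
    housing_distribution: tuple = (0.717, 0.182, 0.063, 0.038)
    # mass on the 4 living depression states at wave 1
    baseline_prevalence: tuple = (0.480, 0.319, 0.143, 0.058)
    attrition_rate: float = 0.12
    mortality: GompertzMortality = field(default_factory=GompertzMortality)
    functional_given_state: np.ndarray = field(
        default_factory=lambda: FUNCTIONAL_GIVEN_STATE.copy())
    # covariate marginals
    female_share: float = 0.552
    rented_share: float = 0.160
    education_shares: tuple = (0.378, 0.309, 0.313)
    income_log_mean: float = 5.82   # mean income ~ GBP 392/week
    income_log_sd: float = 0.55
    age_min: float = 50.0
    age_range: float = 40.0
    age_beta: tuple = (1.7, 2.3)    # Beta shape of the age profile

    def __post_init__(self):
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.n_waves < 2:
            raise ValueError("n_waves must be >= 2")
        if not 0 <= self.attrition_rate < 1:
            raise ValueError("attrition_rate must be in [0, 1)")
        if not 0 <= self.female_share <= 1:
            raise ValueError("female_share must be in [0, 1]")
        if not 0 <= self.rented_share <= 1:
            raise ValueError("rented_share must be in [0, 1]")
        if self.income_log_sd < 0:
            raise ValueError("income_log_sd must be >= 0")
        _check_simplex(self.housing_distribution, "housing_distribution", 4)
        _check_simplex(self.baseline_prevalence, "baseline_prevalence", 4)
        _check_simplex(self.education_shares, "education_shares", 3)
        fg = np.asarray(self.functional_given_state, dtype=float)
        if fg.shape != (4, 4):
            raise ValueError("functional_given_state must be 4x4")
        _check_simplex(fg, "functional_given_state rows")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass
class CostParameters:
    """Unit costs and annualization constants (2022 prices)."""
    unit_cost_home: float = 23.0        # GBP per hour of formal home care
    unit_cost_unpaid: float = 23.0      # replacement-cost default
    weeks_per_year: float = WEEKS_PER_YEAR
    base_year: int = BASE_YEAR
    growth_rate: float = 0.012          # real unit-cost growth per year
    uplift_2024: float = 1.05           # one-off living-wage uplift
    costing_approach: str = "replacement"

    OPPORTUNITY_COST_UNPAID = 14.8      # GBP per hour, 2022 prices

    def __post_init__(self):
        if self.unit_cost_home <= 0 or self.unit_cost_unpaid <= 0:
            raise ValueError("unit costs must be positive")
        if self.weeks_per_year <= 0:
            raise ValueError("weeks_per_year must be positive")
        if self.costing_approach not in ("replacement", "opportunity"):
            raise ValueError("costing_approach must be replacement|opportunity")
        if self.costing_approach == "opportunity":
            self.unit_cost_unpaid = self.OPPORTUNITY_COST_UNPAID


@dataclass(frozen=True)
class ScenarioSpec:
    """One run of the pipeline: a housing cap plus sensitivity switches."""
    name: str = "base"
    housing_cap: float = math.inf       # inf (no intervention), 2, 1 or 0
    progression_perturbation: str = "none"   # none|accelerated|delayed
    effectiveness_scale: float = 1.0
    costing_approach: str = "replacement"

    def __post_init__(self):
        if self.housing_cap < 0:
            raise ValueError("housing_cap must be >= 0")
        if self.progression_perturbation not in ("none", "accelerated", "delayed"):
            raise ValueError("unknown progression_perturbation")


DEFAULT_SCENARIOS = (
    ScenarioSpec("base", math.inf),
    ScenarioSpec("cap2", 2),
    ScenarioSpec("cap1", 1),
    ScenarioSpec("cap0", 0),
)
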
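"""Scenario orchestration and sensitivity analyses.

Housing scenarios cap the housing-problem distribution (no cap, at
most 2, 1 or 0 problems) before the transition matrices are built.
Sensitivity switches: +/-5% accelerated or delayed symptom progression
(multiplicative scaling of annual worsening/improving probabilities),
+/-5% intervention effectiveness (linear interpolation between base and
scenario matrices), the opportunity-cost valuation of unpaid care, and
a Monte Carlo over regression coefficients giving 95% credible
intervals (2.5th-97.5th percentiles across draws).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .care import CareModeFit, HoursFit
from .config import (
    BASE_YEAR,
    CostParameters,
    DEFAULT_SCENARIOS,
    GENDERS,
    HORIZON_YEAR,
    ScenarioSpec,
    STATES,
)
from .costs import CostTable, project_costs
from .projection import (
    StateDistribution,
    aggregate_prevalence,
    entrant_schedule_from_initial,
    initialize_state,
    run_projection,
)
from .transitions import (
    TransitionMatrixSet,
    TransitionModelFit,
    apply_housing_scenario,
    build_matrix_set,
    uniform_housing_expansion,
)

logger = logging.getLogger(__name__)

_WORSEN = [(s, d) for s in range(4) for d in range(4) if d > s]
_IMPROVE = [(s, d) for s in range(4) for d in range(4) if d < s]


@dataclass
class FittedModels:
    """The three fitted regression components of the pipeline."""
    transition: TransitionModelFit
    care: CareModeFit
    hours: HoursFit

    @classmethod
    def from_published(cls) -> "FittedModels":
        return cls(TransitionModelFit.from_published(),
                   CareModeFit.from_published(), HoursFit.from_published())


@dataclass
class ProjectionInputs:
    """Demographic and parameter inputs of a projection run."""
    population: pd.DataFrame        # age, gender, count (base year)
    mortality: pd.DataFrame         # age, gender, q
    prevalence: pd.DataFrame        # age, gender, state, share (base year)
    housing_distribution: np.ndarray  # mass on counts 0..12 (or 4 bands)
    functional_conditional: np.ndarray
    covariate_means: Mapping
    base_year: int = BASE_YEAR
    horizon_year: int = HORIZON_YEAR
    state_shares: Sequence[float] = (0.480, 0.319, 0.143, 0.058)

    def __post_init__(self):
        hd = np.asarray(self.housing_distribution, dtype=float)
        if hd.size == 4:
            hd = uniform_housing_expansion(hd)
        self.housing_distribution = hd
        if self.horizon_year < self.base_year:
            raise ValueError("horizon must not precede the base year")


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    trajectory: list
    costs: CostTable
    prevalence: pd.DataFrame

    def people_with_symptoms(self, year: int) -> float:
        p = self.costs.people
        return float(p.loc[p["year"] == year, "count"].sum())

    def total_cost(self, year: int, care_type: str) -> float:
        t = self.costs.table
        sel = (t["year"] == year) & (t["care_type"] == care_type)
        return float(t.loc[sel, "cost"].sum())


def _restore_diagonal(m: np.ndarray) -> int:
    """Reset each living diagonal so rows sum to 1, keeping the death
    column; if off-diagonal mass exceeds the survivors' budget the
    moves are rescaled.  Returns the number of rescaled rows."""
    clipped = 0
    for s in range(4):
        budget = 1.0 - m[s, 4]
        off = sum(m[s, d] for d in range(4) if d != s)
        if off > budget + 1e-15:
            scale = budget / off if off > 0 else 0.0
            for d in range(4):
                if d != s:
                    m[s, d] *= scale
            off = budget
            clipped += 1
        m[s, s] = budget - off
    return clipped


def perturb_transitions(matrix: np.ndarray, direction: str,
                        magnitude: float = 0.05) -> np.ndarray:
    """Accelerated/delayed progression perturbation of one 5x5 matrix.

    Accelerated: worsening (toward more severe) living entries are
    scaled by (1 + magnitude) and improving entries by (1 - magnitude);
    delayed is the reverse.  The diagonal is reset to restore row sums
    and the death column is untouched.
    """
    if direction not in ("accelerated", "delayed"):
        raise ValueError("direction must be 'accelerated' or 'delayed'")
    if magnitude < 0:
        raise ValueError("magnitude must be nonnegative")
    up = 1.0 + magnitude if direction == "accelerated" else 1.0 - magnitude
    down = 2.0 - up
    m = np.array(matrix, dtype=float)
    for s, d in _WORSEN:
        m[s, d] *= up
    for s, d in _IMPROVE:
        m[s, d] *= down
    m[:4] = np.clip(m[:4], 0.0, None)
    n = _restore_diagonal(m)
    if n:
        logger.warning("perturbation rescaled %d row(s)", n)
    return m


def scale_intervention_effect(base_matrix: np.ndarray,
                              scenario_matrix: np.ndarray,
                              factor: float) -> np.ndarray:
    """Scale the intervention effect: base + factor x (scenario - base)
    entrywise on the off-diagonal entries, diagonal restored, clipped."""
    if base_matrix.shape != scenario_matrix.shape:
        raise ValueError("matrices must share shape")
    m = base_matrix + factor * (scenario_matrix - base_matrix)
    m = np.clip(m, 0.0, 1.0)
    m[4] = scenario_matrix[4]
    n = _restore_diagonal(m)
    if n:
        logger.warning("effect scaling rescaled %d row(s)", n)
    return m


def _transform_set(mset: TransitionMatrixSet, fn) -> TransitionMatrixSet:
    out = np.empty_like(mset.matrices)
    for i in range(mset.ages.size):
        for g in range(2):
            out[i, g] = fn(mset.matrices[i, g])
    return TransitionMatrixSet(ages=mset.ages.copy(), matrices=out)


def build_scenario_matrices(spec: ScenarioSpec, fit: TransitionModelFit,
                            inputs: ProjectionInputs) -> TransitionMatrixSet:
    """Matrices for one scenario: cap the housing distribution, apply
    effectiveness scaling against the base, then any progression
    perturbation (perturbations act on annual probabilities)."""
    dist = apply_housing_scenario(inputs.housing_distribution,
                                  spec.housing_cap)
    mset = build_matrix_set(fit, inputs.mortality, dist,
                            covariate_means=inputs.covariate_means,
                            state_shares=inputs.state_shares)
    if spec.effectiveness_scale != 1.0 and np.isfinite(spec.housing_cap):
        base = build_matrix_set(fit, inputs.mortality,
                                inputs.housing_distribution,
                                covariate_means=inputs.covariate_means,
                                state_shares=inputs.state_shares)
        f = spec.effectiveness_scale
        out = np.empty_like(mset.matrices)
        for i in range(mset.ages.size):
            for g in range(2):
                out[i, g] = scale_intervention_effect(
                    base.matrices[i, g], mset.matrices[i, g], f)
        mset = TransitionMatrixSet(ages=mset.ages, matrices=out)
    if spec.progression_perturbation != "none":
        mset = _transform_set(
            mset, lambda m: perturb_transitions(
                m, spec.progression_perturbation))
    return mset


def run_scenario(spec: ScenarioSpec, models: FittedModels,
                 inputs: ProjectionInputs,
                 params: Optional[CostParameters] = None,
                 cost_years: Optional[Sequence[int]] = None) -> ScenarioResult:
    """Deterministic composition of one scenario: matrices -> Markov
    trajectory -> macrosimulation -> cost table."""
    if params is None:
        params = CostParameters(costing_approach=spec.costing_approach)
    mset = build_scenario_matrices(spec, models.transition, inputs)
    initial = initialize_state(inputs.population, inputs.prevalence,
                               year=inputs.base_year)
    horizon = inputs.horizon_year - inputs.base_year
    years = range(inputs.base_year + 1, inputs.horizon_year + 1)
    entrants = entrant_schedule_from_initial(initial, years)
    mix = initial.counts[0] / initial.counts[0].sum(axis=-1, keepdims=True)
    traj = run_projection(initial, mset, horizon, entrants, mix)
    costs = project_costs(traj, models.care, models.hours,
                          inputs.functional_conditional, params,
                          years=cost_years)
    prev = pd.concat([aggregate_prevalence(s) for s in traj],
                     ignore_index=True)
    return ScenarioResult(spec, traj, costs, prev)


def run_scenarios(models: FittedModels, inputs: ProjectionInputs,
                  specs: Sequence[ScenarioSpec] = DEFAULT_SCENARIOS,
                  **kwargs) -> dict[str, ScenarioResult]:
    return {spec.name: run_scenario(spec, models, inputs, **kwargs)
            for spec in specs}


def sample_params(params: pd.DataFrame, bse: pd.DataFrame,
                  rng: np.random.Generator) -> pd.DataFrame:
    """One independent-normal draw of a coefficient table on its
    estimation scale (log-RRR for multinomial fits, linear for OLS)."""
    draw = rng.normal(params.to_numpy(float), bse.to_numpy(float))
    return pd.DataFrame(draw, index=params.index, columns=params.columns)


def draw_models(models: FittedModels,
                rng: np.random.Generator) -> FittedModels:
    """Perturb every regression coefficient of all three fits."""
    t = replace(models.transition,
                params=sample_params(models.transition.params,
                                     models.transition.bse, rng))
    c = replace(models.care,
                params=sample_params(models.care.params, models.care.bse, rng))
    h = replace(models.hours,
                params=sample_params(models.hours.params, models.hours.bse,
                                     rng))
    return FittedModels(t, c, h)


def monte_carlo(specs: Sequence[ScenarioSpec], models: FittedModels,
                inputs: ProjectionInputs, n_draws: int = 1000,
                seed: int = 0,
                years: Sequence[int] = (BASE_YEAR, HORIZON_YEAR),
                params: Optional[CostParameters] = None) -> pd.DataFrame:
    """Monte Carlo credible intervals for care costs and symptom counts.

    Every draw samples all regression coefficients independently from
    normals on their estimation scale (each draw uses the deterministic
    substream ``default_rng([seed, draw])``), reruns the full pipeline,
    and records the measures; the 2.5th/97.5th percentiles across draws
    frame the point estimate computed without perturbation.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    years = list(years)
    measures = (["cost_unpaid", "cost_home", "people_with_symptoms"])
    point = {spec.name: run_scenario(spec, models, inputs, params=params,
                                     cost_years=years)
             for spec in specs}
    samples = {(spec.name, y, m): np.empty(n_draws)
               for spec in specs for y in years for m in measures}
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        drawn = draw_models(models, rng)
        for spec in specs:
            res = run_scenario(spec, drawn, inputs, params=params,
                               cost_years=years)
            for y in years:
                samples[(spec.name, y, "cost_unpaid")][i] = \
                    res.total_cost(y, "unpaid")
                samples[(spec.name, y, "cost_home")][i] = \
                    res.total_cost(y, "home")
                samples[(spec.name, y, "people_with_symptoms")][i] = \
                    res.people_with_symptoms(y)
    rows = []
    for spec in specs:
        for y in years:
            for m in measures:
                s = samples[(spec.name, y, m)]
                if m == "cost_unpaid":
                    pt = point[spec.name].total_cost(y, "unpaid")
                elif m == "cost_home":
                    pt = point[spec.name].total_cost(y, "home")
                else:
                    pt = point[spec.name].people_with_symptoms(y)
                lo, hi = np.percentile(s, [2.5, 97.5])
                if hi < lo:  # pragma: no cover
                    lo, hi = hi, lo
                rows.append((spec.name, y, m, pt, lo, hi, n_draws))
    return pd.DataFrame(rows, columns=["scenario", "year", "measure",
                                       "point", "lower", "upper", "n_draws"])
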
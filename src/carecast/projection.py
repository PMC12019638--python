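"""Annual Markov cohort projection over age, gender and symptom state.

The projection starts from base-year population counts by single year
of age (45 to 100+) and gender, split across the four living depression
states, and applies the stratum-specific annual transition matrices
year by year: death is absorbing, survivors advance one year of age,
the open 100+ group pools its survivors, and new 45-year-old entrants
are injected each year.  Transition probabilities are held constant
over time (homogeneous chain).  Counts are expected values (real
numbers), not simulated agents.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AGE_BANDS, GENDERS, STATES
from .transitions import TransitionMatrixSet


@dataclass
class StateDistribution:
    """Population counts by age x gender x living state for one year.

    ``counts`` has shape (n_ages, 2, 4); ``cumulative_deaths`` and
    ``cumulative_entrants`` track flows since the base year.
    """
    year: int
    ages: np.ndarray
    counts: np.ndarray
    cumulative_deaths: float = 0.0
    cumulative_entrants: float = 0.0

    def __post_init__(self):
        if self.counts.shape != (self.ages.size, 2, 4):
            raise ValueError("counts must have shape (n_ages, 2, 4)")
        if (self.counts < -1e-9).any():
            raise ValueError("counts must be nonnegative")

    @property
    def living_total(self) -> float:
        return float(self.counts.sum())

    def totals_by_state(self, age_min: float = 65) -> pd.Series:
        sel = self.ages >= age_min
        return pd.Series(self.counts[sel].sum(axis=(0, 1)),
                         index=list(STATES))

    def to_table(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.ages):
            for g, gender in enumerate(GENDERS):
                for s, state in enumerate(STATES):
                    rows.append((self.year, int(a), gender, state,
                                 self.counts[i, g, s]))
        return pd.DataFrame(
            rows, columns=["year", "age", "gender", "state", "count"])


def baseline_prevalence_table(shares_by_age_gender: pd.DataFrame) -> pd.DataFrame:
    """Validate a long (age, gender, state, share) prevalence table."""
    tot = shares_by_age_gender.groupby(["age", "gender"])["share"].sum()
    if not np.allclose(tot, 1.0, atol=1e-9):
        raise ValueError("prevalence shares must sum to 1 per age-gender cell")
    return shares_by_age_gender


def prevalence_from_panel(analysis: pd.DataFrame, ages: Sequence[int],
                          band_width: int = 5) -> pd.DataFrame:
    """Estimate baseline state prevalence by age and gender from the
    wave-1 cross-section, pooled in ``band_width``-year bands (single
    ages inside a band share the band's estimate; sparse cells fall
    back to the gender's overall distribution)."""
    w1 = analysis[analysis["wave"] == analysis["wave"].min()]
    rows = []
    for gender in GENDERS:
        sub = w1[w1["gender"] == gender]
        overall = (sub["depression_state"].value_counts(normalize=True)
                   .reindex(list(STATES)).fillna(0.0))
        for age in ages:
            lo = age - (age % band_width)
            band = sub[(sub["age"] >= lo) & (sub["age"] < lo + band_width)]
            if len(band) >= 30:
                shares = (band["depression_state"]
                          .value_counts(normalize=True)
                          .reindex(list(STATES)).fillna(0.0))
            else:
                shares = overall
            for state in STATES:
                rows.append((int(age), gender, state, float(shares[state])))
    return pd.DataFrame(rows, columns=["age", "gender", "state", "share"])


def initialize_state(population: pd.DataFrame, prevalence: pd.DataFrame,
                     year: int = 2022) -> StateDistribution:
    """Split base-year population counts across depression states.

    ``population`` is a long (age, gender, count) table; ``prevalence``
    a long (age, gender, state, share) table whose shares sum to one in
    every age-gender cell present in the population.
    """
    baseline_prevalence_table(prevalence)
    ages = np.sort(population["age"].unique())
    pop = population.set_index(["age", "gender"])["count"]
    prev = prevalence.set_index(["age", "gender", "state"])["share"]
    counts = np.zeros((ages.size, 2, 4))
    for i, a in enumerate(ages):
        for g, gender in enumerate(GENDERS):
            try:
                p = pop.loc[(a, gender)]
            except KeyError:
                raise ValueError(f"population missing cell ({a}, {gender})")
            for s, state in enumerate(STATES):
                try:
                    share = prev.loc[(a, gender, state)]
                except KeyError:
                    raise ValueError(
                        f"prevalence missing cell ({a}, {gender}, {state})")
                counts[i, g, s] = p * share
    return StateDistribution(year=year, ages=ages, counts=counts)


def project_one_year(state: StateDistribution, matrices: TransitionMatrixSet,
                     entrant_counts: Mapping[str, float] | None = None,
                     entrant_mix: Optional[np.ndarray] = None) -> StateDistribution:
    """Advance the population one calendar year.

    Each (age, gender) state vector is multiplied by its 5-state
    matrix; survivors move up one year of age (the top age group pools
    its survivors); deaths accumulate; entrants are injected at the
    youngest modelled age with ``entrant_mix`` over living states.
    """
    if not np.array_equal(state.ages, matrices.ages):
        raise ValueError("matrix set and state cover different ages")
    n_ages = state.ages.size
    survivors = np.zeros_like(state.counts)
    deaths = 0.0
    for g in range(2):
        v = state.counts[:, g, :]                       # (A, 4)
        m = matrices.matrices[:, g, :4, :4]             # (A, 4, 4)
        moved = np.einsum("as,asd->ad", v, m)
        deaths += float((v * matrices.matrices[:, g, :4, 4]).sum())
        survivors[:, g, :] = moved
    # age everyone by one year; top group retains its survivors
    aged = np.zeros_like(survivors)
    aged[1:] = survivors[:-1]
    aged[-1] += survivors[-1]
    # entrants at the youngest modelled age
    entrants_total = 0.0
    if entrant_counts:
        if entrant_mix is None:
            raise ValueError("entrant_mix required with entrant_counts")
        mix = np.asarray(entrant_mix, dtype=float)
        if mix.ndim == 1:
            mix = np.tile(mix, (2, 1))
        if not np.allclose(mix.sum(axis=-1), 1.0, atol=1e-9):
            raise ValueError("entrant mix must sum to 1")
        for g, gender in enumerate(GENDERS):
            c = float(entrant_counts.get(gender, 0.0))
            aged[0, g, :] += c * mix[g]
            entrants_total += c
    return StateDistribution(
        year=state.year + 1, ages=state.ages, counts=aged,
        cumulative_deaths=state.cumulative_deaths + deaths,
        cumulative_entrants=state.cumulative_entrants + entrants_total)


def run_projection(initial: StateDistribution, matrices: TransitionMatrixSet,
                   horizon_years: int,
                   entrants_by_year: Optional[Mapping[int, Mapping[str, float]]]
                   = None,
                   entrant_mix: Optional[np.ndarray] = None
                   ) -> list[StateDistribution]:
    """Repeatedly apply :func:`project_one_year` under time-constant
    matrices; returns the trajectory including the initial year."""
    if horizon_years < 0:
        raise ValueError("horizon must be nonnegative")
    traj = [initial]
    state = initial
    for _ in range(horizon_years):
        year = state.year + 1
        entr = entrants_by_year.get(year) if entrants_by_year else None
        state = project_one_year(state, matrices, entr, entrant_mix)
        traj.append(state)
    return traj


def aggregate_prevalence(state: StateDistribution,
                         bands: Sequence[tuple] = AGE_BANDS) -> pd.DataFrame:
    """State shares by gender and age band (long table).

    Bands are (lo, hi) inclusive; the last band is open-ended.  An empty
    band yields NaN shares and is flagged in the ``empty`` column.
    """
    rows = []
    for g, gender in enumerate(GENDERS):
        for lo, hi in bands:
            sel = (state.ages >= lo) & (state.ages <= hi)
            cell = state.counts[sel, g, :].sum(axis=0)
            total = cell.sum()
            label = f"{lo}+" if hi >= 150 else f"{lo}-{hi}"
            for s, st in enumerate(STATES):
                share = cell[s] / total if total > 0 else np.nan
                rows.append((state.year, gender, label, st, share, total == 0))
    return pd.DataFrame(rows, columns=["year", "gender", "age_band", "state",
                                       "share", "empty"])


def entrant_schedule_from_initial(initial: StateDistribution,
                                  years: Sequence[int]) -> dict:
    """Constant entrant flow equal to the base-year count at the
    youngest modelled age, per gender."""
    return {int(y): {g: float(initial.counts[0, gi, :].sum())
                     for gi, g in enumerate(GENDERS)}
            for y in years}
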
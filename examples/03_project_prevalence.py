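"""Project depressive-symptom prevalence for the 65+ population to 2042.

Annual 5-state transition matrices (four living severity states plus
absorbing death) are built per single year of age and gender, then a
cohort model advances the base-year population 20 years with aging,
death and 45-year-old entrants.
"""
import numpy as np

from carecast import (
    GeneratorConfig,
    ScenarioSpec,
    build_analysis_table,
    generate_mortality_schedule,
    generate_panel,
    generate_population_table,
)
from carecast.care import functional_conditional_from_panel
from carecast.projection import prevalence_from_panel
from carecast.scenarios import FittedModels, ProjectionInputs, run_scenario
from carecast.transitions import covariate_means_from_panel
from carecast import fit_care_mode_model, fit_hours_models, fit_transition_model

analysis = build_analysis_table(
    generate_panel(GeneratorConfig(n_individuals=10_000, seed=1)))
models = FittedModels(fit_transition_model(analysis),
                      fit_care_mode_model(analysis),
                      fit_hours_models(analysis))
population = generate_population_table()
ages = sorted(population["age"].unique())
inputs = ProjectionInputs(
    population=population,
    mortality=generate_mortality_schedule(),
    prevalence=prevalence_from_panel(analysis, ages),
    housing_distribution=GeneratorConfig().housing_distribution,
    functional_conditional=functional_conditional_from_panel(analysis),
    covariate_means=covariate_means_from_panel(analysis))

result = run_scenario(ScenarioSpec(), models, inputs, cost_years=[2022, 2042])
for year in (2022, 2032, 2042):
    state = result.trajectory[year - 2022]
    totals = state.totals_by_state(age_min=65)
    share = totals / totals.sum()
    print(f"{year}: 65+ living population {totals.sum() / 1e6:.2f}M, "
          f"state shares none/mild/moderate/severe = "
          f"{'/'.join(f'{v:.3f}' for v in share)}")
sym22 = result.people_with_symptoms(2022) / 1e6
sym42 = result.people_with_symptoms(2042) / 1e6
print(f"\n65+ people with any depressive symptoms: {sym22:.2f}M (2022) -> "
      f"{sym42:.2f}M (2042), +{100 * (sym42 / sym22 - 1):.1f}%")
# Growth is driven by population aging: matrices are constant over time
# (homogeneous chain), so only the age structure and entrants change.
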
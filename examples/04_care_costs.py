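"""Macrosimulation: from projected symptom states to annual care costs.

The 65+ population with symptoms is decomposed into cells by age band,
gender, functional difficulty and severity; each cell gets predicted
care-mode probabilities and weekly hours; annual hours (52.14 weeks)
are costed at GBP 23/hour (2022 prices) with a real growth path.
"""
from carecast import (
    CostParameters,
    GeneratorConfig,
    ScenarioSpec,
    build_analysis_table,
    fit_care_mode_model,
    fit_hours_models,
    fit_transition_model,
    generate_mortality_schedule,
    generate_panel,
    generate_population_table,
)
from carecast.care import functional_conditional_from_panel
from carecast.projection import prevalence_from_panel
from carecast.scenarios import FittedModels, ProjectionInputs, run_scenario
from carecast.transitions import covariate_means_from_panel

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

result = run_scenario(ScenarioSpec(), models, inputs,
                      cost_years=[2022, 2042])
table = result.costs.table
print("base case, people with symptoms aged 65+:")
for year in (2022, 2042):
    t = table[table["year"] == year]
    for ct in ("unpaid", "home"):
        sub = t[t["care_type"] == ct]
        print(f"  {year} {ct:>6} care: {sub['users'].sum() / 1e3:7.0f}k users, "
              f"GBP {sub['cost'].sum() / 1e9:5.1f}bn")

# opportunity-cost valuation of unpaid care (GBP 14.8/hour vs 23)
opp = run_scenario(ScenarioSpec(costing_approach="opportunity"), models,
                   inputs, params=CostParameters(
                       costing_approach="opportunity"),
                   cost_years=[2042])
r = opp.total_cost(2042, "unpaid") / result.total_cost(2042, "unpaid")
print(f"\nopportunity vs replacement unpaid cost ratio: {r:.4f} "
      f"({100 * (1 - r):.0f}% lower)")
# Unpaid-care costs dominate home-care costs because far more people
# receive unpaid care and for more hours per week.
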
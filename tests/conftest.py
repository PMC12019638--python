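import numpy as np
import pandas as pd
import pytest

from carecast import (
    FittedModels,
    GeneratorConfig,
    ProjectionInputs,
    build_analysis_table,
    generate_mortality_schedule,
    generate_panel,
    generate_population_table,
)
from carecast.config import GENDERS, STATES
from carecast.transitions import default_covariate_means


def flat_prevalence(ages, shares=(0.480, 0.319, 0.143, 0.058)) -> pd.DataFrame:
    rows = [(int(a), g, s, sh)
            for a in ages for g in GENDERS
            for s, sh in zip(STATES, shares)]
    return pd.DataFrame(rows, columns=["age", "gender", "state", "share"])


@pytest.fixture(scope="session")
def published_models() -> FittedModels:
    return FittedModels.from_published()


@pytest.fixture(scope="session")
def panel_small() -> pd.DataFrame:
    return generate_panel(GeneratorConfig(n_individuals=4000, seed=11))


@pytest.fixture(scope="session")
def analysis_small(panel_small) -> pd.DataFrame:
    return build_analysis_table(panel_small)


@pytest.fixture(scope="session")
def small_inputs() -> ProjectionInputs:
    population = generate_population_table(per_cell=100.0)
    mortality = generate_mortality_schedule()
    ages = np.sort(population["age"].unique())
    return ProjectionInputs(
        population=population,
        mortality=mortality,
        prevalence=flat_prevalence(ages),
        housing_distribution=GeneratorConfig().housing_distribution,
        functional_conditional=GeneratorConfig().functional_given_state,
        covariate_means=default_covariate_means(),
    )
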
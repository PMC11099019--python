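import numpy as np
import pandas as pd
import pytest

from siblock import (
    BetaMatrix,
    ClockDefinition,
    CohortSpec,
    generate_beta_matrix,
    generate_cohort,
    make_toy_clocks,
)


@pytest.fixture(scope="session")
def toy_clocks():
    return make_toy_clocks(seed=0)


@pytest.fixture(scope="session")
def small_cohort():
    """20-mother sibling-pair cohort plus its generating truth."""
    return generate_cohort(CohortSpec(n_mothers=20, seed=11))


@pytest.fixture(scope="session")
def scored_cohort(small_cohort, toy_clocks):
    """Sheet, ages and a noise-free beta matrix for the toy clocks."""
    sheet, _ = small_cohort
    beta = generate_beta_matrix(sheet, toy_clocks, noise_sd=0.0, seed=7)
    ages = pd.Series(sheet["age_years"].to_numpy(), index=sheet["child_id"])
    return sheet, ages, beta


@pytest.fixture
def two_cpg_clock():
    return ClockDefinition(
        name="toy",
        intercept=2.0,
        weights={"cg1": 3.0, "cg2": -1.0},
        reference_medians={"cg1": 0.5, "cg2": 0.5},
    )


def beta_from_dict(data: dict[str, dict[str, float]]) -> BetaMatrix:
    """Build a BetaMatrix from {sample: {cpg: beta}} with NaN for gaps."""
    return BetaMatrix(pd.DataFrame(data).astype(float))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
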
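import numpy as np
import pytest

from mctpref.design import PriorSpec, generate_design, pilot_priors
from mctpref.schema import Attribute, AttributeSchema
from mctpref.simulate import TrueParameters, generate_respondents, simulate_choices


@pytest.fixture(scope="session")
def canonical_schema():
    return AttributeSchema.canonical_mct()


@pytest.fixture(scope="session")
def small_schema():
    """Three-attribute system with 2*2*4 = 16 profiles for brute-force oracles."""
    return AttributeSchema(
        [
            Attribute("accuracy", levels=(50, 90), reference_level=90, monotone="increasing"),
            Attribute("early", levels=("no", "yes"), reference_level="no", monotone="increasing"),
            Attribute("form", levels=("blood", "faecal", "urine", "breath"), reference_level="blood"),
        ]
    )


@pytest.fixture(scope="session")
def small_design(canonical_schema):
    """A lightly optimised canonical design reused across simulation and
    estimation tests."""
    return generate_design(
        canonical_schema, pilot_priors(canonical_schema), n_tasks=24, n_blocks=2,
        seed=11, n_sweeps=3,
    )


@pytest.fixture(scope="session")
def small_pooled_data(small_design):
    """Moderate pooled GP + public sample from the no-heterogeneity truth."""
    truth = TrueParameters.recovery_fixture()
    respondents = generate_respondents(120, 480, truth=truth, seed=21)
    dataset = simulate_choices(small_design, respondents, truth, seed=22)
    return truth, respondents, dataset
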
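"""Shared fixtures: schemas, a blocked design, and simulated datasets.

Session-scoped fixtures keep the expensive artifacts (design search,
mid-sized simulations) shared across test modules.
"""

import numpy as np
import pytest
from hypothesis import settings as hyp_settings

hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
hyp_settings.load_profile("deterministic")

from vaxchoice.design import block_and_add_repeat, optimize_design
from vaxchoice.population import PopulationParams, default_population_params
from vaxchoice.schema import Attribute, AttributeSchema, LevelConstraint, default_schema
from vaxchoice.simulate import simulate_choices, simulate_respondents

ATTENTIVE_MIX = {
    "attentive": 1.0,
    "comprehension_fail": 0.0,
    "straight_liner": 0.0,
    "inconsistent": 0.0,
}


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def tiny_schema():
    """Two binary attributes, no constraints."""
    return AttributeSchema(
        attributes=(
            Attribute("speed", (0, 1)),
            Attribute("price", (0, 1)),
        )
    )


@pytest.fixture(scope="session")
def blocked_design(schema):
    d = optimize_design(schema, n_sets=30, n_blocks=3, seed=11, n_iterations=300)
    return block_and_add_repeat(d, n_blocks=3, seed=12)


@pytest.fixture(scope="session")
def params():
    return default_population_params()


def make_dataset(design, n, seed, behavior_mix=None, params=None, sd_scale=1.0):
    params = params or default_population_params()
    if sd_scale != 1.0:
        params = PopulationParams(
            mean=dict(params.mean),
            sd={k: v * sd_scale for k, v in params.sd.items()},
            asc_optout=(params.asc_optout[0], params.asc_optout[1] * sd_scale),
        )
    roster = simulate_respondents(
        n, params=params, behavior_mix=behavior_mix or ATTENTIVE_MIX, seed=seed
    )
    return simulate_choices(design, roster, params, seed=seed + 1000)


@pytest.fixture(scope="session")
def small_attentive_dataset(blocked_design):
    """150 attentive respondents from the default population."""
    return make_dataset(blocked_design, 150, seed=21)


@pytest.fixture(scope="session")
def homogeneous_dataset(blocked_design):
    """200 respondents with zero heterogeneity (conditional-logit world)."""
    return make_dataset(blocked_design, 200, seed=31, sd_scale=0.0)


@pytest.fixture(scope="session")
def mixed_behavior_dataset(blocked_design):
    """300 respondents at the default behavior mix, ground truth retained."""
    return make_dataset(
        blocked_design,
        300,
        seed=41,
        behavior_mix={
            "attentive": 0.70,
            "comprehension_fail": 0.07,
            "straight_liner": 0.03,
            "inconsistent": 0.20,
        },
    )
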
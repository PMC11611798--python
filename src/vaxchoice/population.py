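"""Default population parameters for the synthetic survey.

The simulator draws each respondent's preference coefficients from normal
distributions around the population means below, which reproduce the
preference structure estimated in a national stated-preference study of
vaccine prioritization for China's National Immunization Program:
effectiveness and coverage dominate, higher-priced vaccines are (mildly)
preferred for public funding, preschoolers are the favored target group, and
the negative opt-out constant reflects a general demand for adding vaccines.
Coefficients are in utility units per dummy-coded level (reference levels:
incidence 10, mortality 0, effectiveness 20%, cost 100 CNY, preschoolers,
coverage 1%). Heterogeneity SDs are stored as published (some signed); the
simulator uses their absolute values, since the sign of a normal mixing SD is
not identified.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PopulationParams",
    "default_population_params",
    "DEFAULT_UNFORCED_MEANS",
    "DEFAULT_UNFORCED_SDS",
    "DEFAULT_OPTOUT_ASC",
    "DEFAULT_QUOTA_TABLE",
    "DEFAULT_BEHAVIOR_MIX",
]

# Unforced-choice population estimates (utility units, dummy coding).
DEFAULT_UNFORCED_MEANS: dict[str, float] = {
    "incidence=500": 0.053,
    "incidence=1000": 0.206,
    "mortality=50": 0.198,
    "mortality=100": 0.244,
    "effectiveness=50": 0.533,
    "effectiveness=90": 1.095,
    "cost=1000": 0.091,
    "cost=2000": 0.210,
    "group=school_age": -0.187,
    "group=adults": -0.414,
    "group=older_adults": -0.405,
    "coverage=30": 0.594,
    "coverage=60": 1.030,
}

DEFAULT_UNFORCED_SDS: dict[str, float] = {
    "incidence=500": 0.016,
    "incidence=1000": 0.977,
    "mortality=50": 0.674,
    "mortality=100": 1.288,
    "effectiveness=50": 0.037,
    "effectiveness=90": 1.141,
    "cost=1000": -0.586,
    "cost=2000": -1.028,
    "group=school_age": -0.014,
    "group=adults": 0.750,
    "group=older_adults": 0.806,
    "coverage=30": -0.033,
    "coverage=60": 1.093,
}

# Opt-out alternative-specific constant (mean, SD).
DEFAULT_OPTOUT_ASC: tuple[float, float] = (-0.953, 2.316)

# Census-aligned quota margins for respondent demographics.
DEFAULT_QUOTA_TABLE: dict[str, dict[str, float]] = {
    "gender": {"male": 0.5080, "female": 0.4920},
    "age_group": {"18-29": 0.2023, "30-44": 0.3125, "45-59": 0.3193, "60+": 0.1659},
    "region": {"eastern": 0.4693, "central": 0.2591, "western": 0.2716},
    "education": {
        "junior_or_below": 0.0170,
        "senior_high": 0.1182,
        "college": 0.7920,
        "master_or_above": 0.0727,
    },
    "income": {
        "<3000": 0.0875,
        "3000-5999": 0.2432,
        "6000-9999": 0.4011,
        ">=10000": 0.2682,
    },
    "health": {
        "very_good": 0.2011,
        "good": 0.5648,
        "fair": 0.2125,
        "poor": 0.0182,
        "very_poor": 0.0034,
    },
    "youngest_child": {"0-5": 0.2432, "6-17": 0.3739, ">=18": 0.2068, "none": 0.1761},
}

# Share of respondents exhibiting each response behavior. The non-attentive
# shares echo the attrition observed in large online vaccine-preference
# surveys (roughly 7% comprehension failures, 3% straight-liners, 20%
# inconsistent on the repeated task).
DEFAULT_BEHAVIOR_MIX: dict[str, float] = {
    "attentive": 0.70,
    "comprehension_fail": 0.07,
    "straight_liner": 0.03,
    "inconsistent": 0.20,
}


@dataclass(frozen=True)
class PopulationParams:
    """Means and heterogeneity SDs of the random utility coefficients.

    ``mean``/``sd`` are keyed by dummy-coded column name
    (``"<attribute>=<level>"``); ``asc_optout`` is the (mean, sd) of the
    opt-out alternative-specific constant. Optional ``interactions`` maps
    ``(covariate, column)`` pairs to fixed interaction coefficients used when
    simulating covariate-dependent preferences.
    """

    mean: dict[str, float]
    sd: dict[str, float]
    asc_optout: tuple[float, float] = DEFAULT_OPTOUT_ASC
    interactions: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self):
        if set(self.mean) != set(self.sd):
            raise ValueError("mean and sd must cover the same columns")
        for v in list(self.mean.values()) + list(self.sd.values()):
            if not np.isfinite(v):
                raise ValueError("population parameters must be finite")

    @property
    def columns(self) -> list[str]:
        return list(self.mean)

    def mean_vector(self) -> np.ndarray:
        return np.array([self.mean[c] for c in self.columns])

    def sd_vector(self) -> np.ndarray:
        """Simulation-side SDs: absolute values (SD sign is unidentified)."""
        return np.abs(np.array([self.sd[c] for c in self.columns]))


def default_population_params() -> PopulationParams:
    return PopulationParams(
        mean=dict(DEFAULT_UNFORCED_MEANS),
        sd=dict(DEFAULT_UNFORCED_SDS),
        asc_optout=DEFAULT_OPTOUT_ASC,
    )
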
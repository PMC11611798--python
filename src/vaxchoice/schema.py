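"""Attribute schemas for vaccine discrete choice experiments.

An :class:`AttributeSchema` describes the attribute space of the hypothetical
vaccines shown to respondents: each :class:`Attribute` has an ordered list of
levels (numeric where the attribute is a rate, percentage or price;
categorical for the vaccinated group), a reference level used for dummy
coding, and optional cross-attribute constraints such as "mortality must be
lower than incidence" that rule out epidemiologically implausible profiles.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

__all__ = [
    "Attribute",
    "LevelConstraint",
    "AttributeSchema",
    "Profile",
    "SchemaError",
    "ConstraintError",
    "default_schema",
]


class SchemaError(ValueError):
    """Raised for structurally invalid schemas or profiles."""


class ConstraintError(ValueError):
    """Raised when a constraint references attributes it cannot compare."""


@dataclass(frozen=True)
class Attribute:
    """One vaccine attribute with its levels.

    Parameters
    ----------
    name
        Identifier, e.g. ``"effectiveness"``.
    levels
        Ordered level values. Numeric for rates/percentages/prices,
        strings for categorical attributes.
    reference_level
        Index into ``levels`` of the dummy-coding reference.
    coding
        ``"dummy"`` (default) or ``"continuous"``.
    unit
        Human-readable unit, carried through to serialized artifacts.
    """

    name: str
    levels: tuple
    reference_level: int = 0
    coding: str = "dummy"
    unit: str = ""

    def __post_init__(self):
        if len(self.levels) < 2:
            raise SchemaError(f"attribute {self.name!r} needs >=2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"attribute {self.name!r} has duplicate levels")
        if not 0 <= self.reference_level < len(self.levels):
            raise SchemaError(f"attribute {self.name!r}: bad reference index")
        if self.coding not in ("dummy", "continuous"):
            raise SchemaError(f"attribute {self.name!r}: unknown coding {self.coding!r}")
        if self.coding == "continuous" and not self.is_numeric:
            raise SchemaError(f"attribute {self.name!r}: continuous coding needs numeric levels")
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def is_numeric(self) -> bool:
        return all(isinstance(v, (int, float)) for v in self.levels)

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def non_reference_indices(self) -> list[int]:
        return [i for i in range(self.n_levels) if i != self.reference_level]


@dataclass(frozen=True)
class LevelConstraint:
    """Pairwise strict inequality on numeric level values.

    ``value(left) < value(right)`` must hold in every admissible profile.
    """

    left: str
    right: str

    def validate(self, schema: "AttributeSchema") -> None:
        for name in (self.left, self.right):
            if name not in schema.names:
                raise ConstraintError(f"constraint references unknown attribute {name!r}")
            if not schema[name].is_numeric:
                raise ConstraintError(f"constraint references categorical attribute {name!r}")

    def holds(self, profile: "Profile", schema: "AttributeSchema") -> bool:
        lv = schema[self.left].levels[profile.level_of(schema, self.left)]
        rv = schema[self.right].levels[profile.level_of(schema, self.right)]
        return lv < rv


@dataclass(frozen=True)
class Profile:
    """A hypothetical vaccine: one level index per schema attribute."""

    levels: tuple  # level index per attribute, in schema order

    def level_of(self, schema: "AttributeSchema", name: str) -> int:
        return self.levels[schema.index_of(name)]

    def values(self, schema: "AttributeSchema") -> dict:
        return {
            a.name: a.levels[i] for a, i in zip(schema.attributes, self.levels)
        }


@dataclass(frozen=True)
class AttributeSchema:
    attributes: tuple[Attribute, ...]
    constraints: tuple[LevelConstraint, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "attributes", tuple(self.attributes))
        object.__setattr__(self, "constraints", tuple(self.constraints))
        if not self.attributes:
            raise SchemaError("schema has no attributes")
        names = [a.name for a in self.attributes]
        if len(set(names)) != len(names):
            raise SchemaError("duplicate attribute names")
        for c in self.constraints:
            c.validate(self)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.attributes]

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def __getitem__(self, name: str) -> Attribute:
        return self.attributes[self.index_of(name)]

    @property
    def n_dummy_columns(self) -> int:
        """Width of the dummy-coded design matrix (no ASC column)."""
        return sum(a.n_levels - 1 for a in self.attributes)

    def dummy_column_names(self) -> list[str]:
        cols = []
        for a in self.attributes:
            for i in a.non_reference_indices():
                cols.append(f"{a.name}={a.levels[i]}")
        return cols

    def satisfies(self, profile: Profile) -> bool:
        return all(c.holds(profile, self) for c in self.constraints)


def build_full_factorial(schema: AttributeSchema) -> list[Profile]:
    """All level-index combinations, lexicographic, unfiltered.

    The first attribute varies slowest; no constraint filtering is applied
    (see :func:`apply_constraints`).
    """
    ranges = [range(a.n_levels) for a in schema.attributes]
    return [Profile(levels=combo) for combo in itertools.product(*ranges)]


def apply_constraints(profiles: list[Profile], schema: AttributeSchema) -> list[Profile]:
    """Keep only profiles satisfying every pairwise constraint; order preserved.

    Idempotent: filtering an already-filtered list is a no-op.
    """
    for c in schema.constraints:
        c.validate(schema)
    return [p for p in profiles if schema.satisfies(p)]


def default_schema() -> AttributeSchema:
    """The six-attribute vaccine schema used throughout this package.

    Incidence and mortality of the vaccine-preventable disease (cases per
    100,000), vaccine effectiveness (%), total vaccine cost (CNY), the
    vaccinated group, and current vaccine coverage (%). Reference levels are
    the least favorable level of each attribute except the vaccinated group,
    whose reference is preschoolers. Mortality must be strictly lower than
    incidence in every admissible profile.
    """
    attrs = (
        Attribute("incidence", (10, 500, 1000), unit="per 100,000"),
        Attribute("mortality", (0, 50, 100), unit="per 100,000"),
        Attribute("effectiveness", (20, 50, 90), unit="%"),
        Attribute("cost", (100, 1000, 2000), unit="CNY"),
        Attribute(
            "group",
            ("preschoolers", "school_age", "adults", "older_adults"),
            unit="category",
        ),
        Attribute("coverage", (1, 30, 60), unit="%"),
    )
    constraints = (LevelConstraint(left="mortality", right="incidence"),)
    return AttributeSchema(attributes=attrs, constraints=constraints)
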
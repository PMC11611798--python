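"""D-efficient choice-design generation.

Builds the blocked set of pairwise hypothetical-vaccine tasks shown to
respondents. A design is scored by its D-error, ``det(Omega)^(1/K)`` where
``Omega`` is the asymptotic covariance of the multinomial-logit estimator at
prior coefficients and ``K`` the number of dummy-coded parameters; lower is
better. The search is a seeded random-swap (coordinate-exchange) descent over
the constraint-admissible profile pool. After the search the sets are
randomly partitioned into blocks and each block's second task is duplicated
at position 11 as a consistency probe; estimation excludes those repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .schema import (
    AttributeSchema,
    Profile,
    SchemaError,
    apply_constraints,
    build_full_factorial,
)

__all__ = [
    "DesignRow",
    "ChoiceDesign",
    "SingularDesignError",
    "InfeasibleDesignError",
    "BlockingError",
    "dummy_code",
    "compute_d_error",
    "d_error_from_information",
    "optimize_design",
    "block_and_add_repeat",
    "min_sample_size",
]


class SingularDesignError(ValueError):
    """Information matrix is singular; carries the deficient column names."""

    def __init__(self, message, deficient_columns=()):
        super().__init__(message)
        self.deficient_columns = tuple(deficient_columns)


class InfeasibleDesignError(ValueError):
    pass


class BlockingError(ValueError):
    pass


@dataclass(frozen=True)
class DesignRow:
    set_id: int
    alternative: str  # "A" or "B"
    profile: Profile
    block_id: int | None = None
    position: int | None = None  # 1-based position within block
    is_repeat: bool = False


@dataclass(frozen=True)
class ChoiceDesign:
    schema: AttributeSchema
    rows: tuple[DesignRow, ...]
    n_blocks: int = 1
    repeat_task: tuple[int, int] | None = None  # (source position, insert position)

    def __post_init__(self):
        object.__setattr__(self, "rows", tuple(self.rows))

    @property
    def set_ids(self) -> list[int]:
        seen: dict[int, None] = {}
        for r in self.rows:
            if not r.is_repeat:
                seen.setdefault(r.set_id, None)
        return list(seen)

    @property
    def n_sets(self) -> int:
        return len(self.set_ids)

    def alternatives_of(self, set_id: int) -> dict[str, Profile]:
        return {
            r.alternative: r.profile
            for r in self.rows
            if r.set_id == set_id and not r.is_repeat
        }

    def tasks_in_block(self, block_id: int) -> list[tuple[int, bool]]:
        """(position-ordered) list of (set_id, is_repeat) for one block."""
        tasks: dict[int, tuple[int, bool]] = {}
        for r in self.rows:
            if r.block_id == block_id:
                tasks[r.position] = (r.set_id, r.is_repeat)
        return [tasks[p] for p in sorted(tasks)]


def dummy_code(profile: Profile, schema: AttributeSchema) -> np.ndarray:
    """Dummy-coded row for one profile (reference levels drop out)."""
    out = np.zeros(schema.n_dummy_columns)
    j = 0
    for attr, lvl in zip(schema.attributes, profile.levels):
        for i in attr.non_reference_indices():
            if lvl == i:
                out[j] = 1.0
            j += 1
    return out


def _set_information(design: ChoiceDesign, beta: np.ndarray) -> np.ndarray:
    """Fisher information of the MNL estimator summed over choice sets."""
    K = design.schema.n_dummy_columns
    info = np.zeros((K, K))
    for set_id in design.set_ids:
        alts = design.alternatives_of(set_id)
        X = np.stack([dummy_code(alts[a], design.schema) for a in sorted(alts)])
        v = X @ beta
        v -= v.max()
        p = np.exp(v)
        p /= p.sum()
        xbar = p @ X
        Xc = X - xbar
        info += (Xc * p[:, None]).T @ Xc
    return info


def d_error_from_information(info: np.ndarray) -> float:
    """det(info^-1)^(1/K); raises on a singular information matrix."""
    K = info.shape[0]
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0 or not np.isfinite(logdet):
        # name the columns spanning the (numerical) null space
        _, s, vt = np.linalg.svd(info)
        tol = s.max() * K * np.finfo(float).eps if s.size and s.max() > 0 else 0.0
        null = vt[s <= tol] if s.size else vt
        deficient = sorted({int(i) for row in null for i in np.nonzero(np.abs(row) > 1e-8)[0]})
        raise SingularDesignError(
            "singular information matrix", deficient_columns=deficient
        )
    return float(np.exp(-logdet / K))


def compute_d_error(design: ChoiceDesign, priors: np.ndarray) -> float:
    """D-error of a pairwise design at prior coefficients ``priors``."""
    priors = np.asarray(priors, dtype=float)
    K = design.schema.n_dummy_columns
    if priors.shape != (K,):
        raise ValueError(f"priors must have length {K}, got {priors.shape}")
    if not np.all(np.isfinite(priors)):
        raise ValueError("priors must be finite")
    return d_error_from_information(_set_information(design, priors))


def _d_error_or_inf(design: ChoiceDesign, priors: np.ndarray) -> float:
    try:
        return compute_d_error(design, priors)
    except SingularDesignError:
        return math.inf


def optimize_design(
    schema: AttributeSchema,
    priors: np.ndarray | None = None,
    n_sets: int = 30,
    n_blocks: int = 3,
    seed: int = 0,
    n_iterations: int = 2000,
) -> ChoiceDesign:
    """Seeded random-swap search minimizing the D-error.

    Starts from a random constraint-admissible design and repeatedly proposes
    replacing one alternative's profile with a random admissible profile,
    accepting only strict D-error improvements. The returned design has
    ``n_sets`` pairwise sets (no blocking yet; see
    :func:`block_and_add_repeat`). Deterministic given ``seed``.
    """
    if n_sets % n_blocks != 0:
        raise BlockingError(f"n_sets={n_sets} not divisible by n_blocks={n_blocks}")
    pool = apply_constraints(build_full_factorial(schema), schema)
    if len(pool) < 2:
        raise InfeasibleDesignError("admissible profile pool smaller than 2")
    if priors is None:
        priors = np.zeros(schema.n_dummy_columns)
    rng = np.random.default_rng(seed)

    def random_pair() -> tuple[Profile, Profile]:
        i, j = rng.choice(len(pool), size=2, replace=False)
        return pool[i], pool[j]

    sets = [random_pair() for _ in range(n_sets)]

    def as_design(pairs) -> ChoiceDesign:
        rows = []
        for s, (pa, pb) in enumerate(pairs, start=1):
            rows.append(DesignRow(set_id=s, alternative="A", profile=pa))
            rows.append(DesignRow(set_id=s, alternative="B", profile=pb))
        return ChoiceDesign(schema=schema, rows=rows, n_blocks=n_blocks)

    best = _d_error_or_inf(as_design(sets), priors)
    for _ in range(n_iterations):
        s = int(rng.integers(n_sets))
        side = int(rng.integers(2))
        cand = pool[int(rng.integers(len(pool)))]
        other = sets[s][1 - side]
        if cand == other:
            continue  # never allow two identical profiles in a set
        proposal = list(sets)
        proposal[s] = (cand, other) if side == 0 else (other, cand)
        err = _d_error_or_inf(as_design(proposal), priors)
        if err < best:
            sets, best = proposal, err
    return as_design(sets)


def block_and_add_repeat(
    design: ChoiceDesign,
    n_blocks: int,
    source_pos: int = 2,
    insert_pos: int = 11,
    seed: int = 0,
) -> ChoiceDesign:
    """Randomly partition sets into equal blocks and add the consistency task.

    Within each block the task at ``source_pos`` is duplicated at
    ``insert_pos`` and flagged ``is_repeat``; estimation must drop those rows.
    """
    set_ids = design.set_ids
    if len(set_ids) % n_blocks != 0:
        raise BlockingError(
            f"{len(set_ids)} sets not divisible into {n_blocks} blocks"
        )
    per_block = len(set_ids) // n_blocks
    if not 1 <= source_pos <= per_block:
        raise BlockingError(f"source position {source_pos} outside 1..{per_block}")
    rng = np.random.default_rng(seed)
    order = [set_ids[i] for i in rng.permutation(len(set_ids))]

    rows: list[DesignRow] = []
    for b in range(1, n_blocks + 1):
        block_sets = order[(b - 1) * per_block : b * per_block]
        for pos, sid in enumerate(block_sets, start=1):
            for alt, prof in sorted(design.alternatives_of(sid).items()):
                rows.append(
                    DesignRow(
                        set_id=sid,
                        alternative=alt,
                        profile=prof,
                        block_id=b,
                        position=pos,
                    )
                )
        src = block_sets[source_pos - 1]
        for alt, prof in sorted(design.alternatives_of(src).items()):
            rows.append(
                DesignRow(
                    set_id=src,
                    alternative=alt,
                    profile=prof,
                    block_id=b,
                    position=insert_pos,
                    is_repeat=True,
                )
            )
    return ChoiceDesign(
        schema=design.schema,
        rows=rows,
        n_blocks=n_blocks,
        repeat_task=(source_pos, insert_pos),
    )


def min_sample_size(max_levels: int, n_tasks: int, n_alternatives: int) -> int:
    """Johnson–Orme rule-of-thumb minimum respondent count.

    ``n > 500 c / (t a)`` with ``c`` the largest number of levels of any
    attribute, ``t`` choice tasks per respondent and ``a`` alternatives per
    task; returned as the ceiling.
    """
    for v in (max_levels, n_tasks, n_alternatives):
        if not isinstance(v, (int, np.integer)) or v <= 0:
            raise ValueError("all arguments must be positive integers")
    return math.ceil(500 * max_levels / (n_tasks * n_alternatives))
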
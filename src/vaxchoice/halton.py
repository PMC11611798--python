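"""Halton quasi-random sequences for simulated likelihood.

Column ``d`` of a draw matrix is the radical-inverse (van der Corput)
sequence in base ``primes[d]``, starting at index 1 (so the first base-2
draws are 1/2, 1/4, 3/4) with an optional burn-in of skipped leading terms.
Primes are assigned to dimensions in ascending order by default.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = [
    "PRIMES",
    "radical_inverse",
    "halton_draws",
    "normal_halton_panel",
    "rotated_halton_panel",
]

PRIMES = (
    2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47,
    53, 59, 61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113,
)


def radical_inverse(
    indices: np.ndarray, base: int, permutation: np.ndarray | None = None
) -> np.ndarray:
    """Vectorized radical inverse of integer indices in the given base.

    An optional digit ``permutation`` (with 0 fixed) scrambles each digit
    before accumulation — the classic remedy for the poor equidistribution
    of high-prime Halton dimensions.
    """
    idx = np.asarray(indices, dtype=np.int64)
    out = np.zeros(idx.shape, dtype=float)
    f = 1.0 / base
    rem = idx.copy()
    while rem.max(initial=0) > 0:
        digit = rem % base
        if permutation is not None:
            digit = permutation[digit]
        out += f * digit
        rem //= base
        f /= base
    return out


_SCRAMBLE_SEED = 987654321  # fixed: scrambled sequences are still deterministic


def digit_permutations(primes: tuple[int, ...]) -> dict[int, np.ndarray]:
    """Seeded random digit permutations (0 fixed) per base."""
    rng = np.random.default_rng(_SCRAMBLE_SEED)
    return {
        p: np.concatenate([[0], 1 + rng.permutation(p - 1)]) for p in primes
    }


def halton_draws(
    n_draws: int,
    dim: int,
    primes: tuple[int, ...] | None = None,
    burn: int = 0,
    scramble: bool = False,
) -> np.ndarray:
    """(n_draws, dim) matrix of uniforms in (0, 1); deterministic.

    ``scramble=True`` applies fixed seeded digit permutations per base
    (0 fixed), breaking the cross-dimension correlations of the standard
    sequence in high-prime dimensions while remaining fully reproducible.
    """
    if primes is None:
        primes = PRIMES
    if dim > len(primes):
        raise ValueError(f"dim={dim} exceeds the {len(primes)} supplied primes")
    if len(set(primes[:dim])) != dim:
        raise ValueError("primes must be distinct")
    if burn < 0:
        raise ValueError("burn must be >= 0")
    perms = digit_permutations(primes[:dim]) if scramble else {}
    idx = np.arange(burn + 1, burn + n_draws + 1)
    return np.column_stack(
        [radical_inverse(idx, p, perms.get(p)) for p in primes[:dim]]
    )


_PANEL_CACHE: dict = {}


def normal_halton_panel(
    n_respondents: int,
    n_draws: int,
    dim: int,
    burn: int = 50,
    shift: np.ndarray | None = None,
    scramble: bool = False,
) -> np.ndarray:
    """Standard-normal Halton draws for panel simulation.

    One long Halton sequence per dimension is cut into consecutive
    ``n_draws``-length segments, one per respondent, then mapped through the
    normal quantile function. Returns shape (n_respondents, n_draws, dim).
    An optional ``shift`` (per-dimension, in [0,1)) applies a Cranley-
    Patterson rotation before the quantile transform.
    """
    if dim == 0:
        return np.zeros((n_respondents, n_draws, 0))
    key = (n_respondents, n_draws, dim, burn, scramble)
    if shift is None and key in _PANEL_CACHE:
        return _PANEL_CACHE[key]
    u = halton_draws(n_respondents * n_draws, dim, burn=burn, scramble=scramble)
    if shift is not None:
        u = (u + np.asarray(shift)[None, :]) % 1.0
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = norm.ppf(u).reshape(n_respondents, n_draws, dim)
    if shift is None:
        z.setflags(write=False)
        _PANEL_CACHE[key] = z
        if len(_PANEL_CACHE) > 8:  # bound memory across many configurations
            _PANEL_CACHE.pop(next(iter(_PANEL_CACHE)))
    return z


def rotated_halton_panel(
    n_respondents: int, n_draws: int, dim: int, burn: int = 50, seed: int = 0
) -> np.ndarray:
    """Per-respondent Cranley-Patterson rotations of one leading Halton block.

    All respondents share the leading ``n_draws``-point Halton block (the
    best-distributed prefix of the sequence); each receives an independent
    seeded random shift modulo 1, which preserves the block's low
    discrepancy while decorrelating simulation noise across respondents.
    Returns standard-normal draws of shape (n_respondents, n_draws, dim).
    """
    if dim == 0:
        return np.zeros((n_respondents, n_draws, 0))
    base = halton_draws(n_draws, dim, burn=burn)  # (R, dim)
    shifts = np.random.default_rng(seed).random((n_respondents, dim))
    u = (base[None, :, :] + shifts[:, None, :]) % 1.0
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return norm.ppf(u)
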
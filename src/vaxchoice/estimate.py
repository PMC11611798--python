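"""Panel mixed-logit estimation by maximum simulated likelihood.

The model is a random-utility logit with normally distributed respondent-
level coefficients: respondent ``n`` holds ``beta_n = b + s * z_n`` and
chooses the alternative with the highest utility ``x'beta_n + Gumbel noise``
in each task. The simulated log-likelihood averages, over quasi-random
(Halton) standard-normal draws, the product of logit choice probabilities
across a respondent's tasks — the panel form, since every respondent answers
ten tasks:

    LL = sum_n log( (1/R) sum_r prod_t P_nt(y_nt | b + s*z_nr) )

The unforced stage adds an opt-out alternative whose systematic utility is
an alternative-specific constant with zero attribute contributions. Forced
and unforced stages are fitted as separate models. Estimation always drops
the repeated consistency task.

The sign of a mixing SD is not identified (the likelihood is even in each
``s``); fits report the raw signed estimate and its absolute value.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .dataset import ChoiceDataset
from .halton import PRIMES, normal_halton_panel, rotated_halton_panel

__all__ = [
    "ModelSpec",
    "MixlFit",
    "RankDeficientError",
    "NonConvergenceError",
    "build_design_arrays",
    "add_interactions",
    "loglik_mixl",
    "fit_mixl",
    "stability_check",
]


class RankDeficientError(ValueError):
    def __init__(self, message, aliased_columns=()):
        super().__init__(message)
        self.aliased_columns = tuple(aliased_columns)


class NonConvergenceError(RuntimeError):
    def __init__(self, message, grad_norm=None, last_params=None):
        super().__init__(message)
        self.grad_norm = grad_norm
        self.last_params = last_params


@dataclass(frozen=True)
class ModelSpec:
    """Estimation specification.

    ``coding`` maps attribute name to ``"dummy"`` or ``"continuous"``
    (default: the schema's own coding, i.e. dummy). ``random`` lists the
    columns with normal heterogeneity; ``None`` means every attribute column
    plus the opt-out constant (interactions stay fixed unless listed).

    Draws default to digit-scrambled Halton sequences with antithetic
    pairing: with a dozen or more random coefficients, the unscrambled
    sequence's high-prime dimensions are visibly correlated and the
    resulting integration error attenuates the largest heterogeneity
    parameters at moderate draw counts. ``scramble=False, antithetic=False``
    reproduces plain standard Halton draws.
    """

    stage: str = "unforced"
    coding: dict[str, str] | None = None
    random: tuple[str, ...] | None = None
    include_optout_asc: bool = True
    interactions: tuple[tuple[str, str], ...] = ()
    n_draws: int = 1500
    halton_burn: int = 50
    halton_primes: tuple[int, ...] | None = None
    scramble: bool = True
    antithetic: bool = True
    draw_allocation: str = "segments"  # segments | rotated
    sd_init: float = 0.1
    gtol: float = 1e-5
    maxiter: int = 300
    seed: int = 0
    se_method: str = "hessian"  # hessian | opg | sandwich

    def __post_init__(self):
        if self.stage not in ("forced", "unforced"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


ASC_COLUMN = "asc_optout"


def add_interactions(
    dataset: ChoiceDataset, respondents: pd.DataFrame, pairs
) -> pd.DataFrame:
    """Product columns covariate x level-dummy, aligned to the data rows."""
    resp = respondents.set_index("id")
    out = {}
    level_cols = _attribute_columns(dataset, None)
    for cov, col in pairs:
        if cov not in resp.columns:
            raise ValueError(f"covariate {cov!r} missing from respondent table")
        if resp[cov].isna().any():
            raise ValueError(f"covariate {cov!r} missing for some respondents")
        if col not in level_cols:
            raise ValueError(f"unknown level column {col!r}")
        cov_per_row = dataset.data["respondent_id"].map(resp[cov]).to_numpy(float)
        out[f"{cov}_x_{col}"] = cov_per_row * level_cols[col]
    return pd.DataFrame(out, index=dataset.data.index)


def _attribute_columns(dataset: ChoiceDataset, coding: dict | None) -> dict[str, np.ndarray]:
    """Column name -> per-row values for the configured coding."""
    cols: dict[str, np.ndarray] = {}
    df = dataset.data
    for attr in dataset.schema.attributes:
        mode = (coding or {}).get(attr.name, "dummy")
        vals = df[attr.name]
        if mode == "dummy":
            for i in attr.non_reference_indices():
                lvl = attr.levels[i]
                cols[f"{attr.name}={lvl}"] = (vals == lvl).to_numpy(float)
        elif mode == "continuous":
            if not attr.is_numeric:
                raise ValueError(f"attribute {attr.name!r} cannot be continuous-coded")
            cols[attr.name] = pd.to_numeric(vals).fillna(0.0).to_numpy(float)
        else:
            raise ValueError(f"unknown coding {mode!r} for {attr.name!r}")
    return cols


@dataclass
class _Arrays:
    X: np.ndarray  # (N, T, J, K)
    y: np.ndarray  # (N, T) chosen alternative index
    columns: list[str]
    respondent_ids: list
    n_alts: int


def build_design_arrays(dataset: ChoiceDataset, spec: ModelSpec) -> _Arrays:
    """Rectangular (respondent, task, alternative) design arrays."""
    base = dataset.estimation_rows(spec.stage).copy()
    alt_rank = {"A": 0, "B": 1, "optout": 2}
    base["_alt"] = base["alternative"].map(alt_rank)
    base = base.sort_values(["respondent_id", "position", "_alt"], kind="stable")

    full = ChoiceDataset.__new__(ChoiceDataset)  # column view without re-validation
    full.data = base
    full.respondents = dataset.respondents
    full.schema = dataset.schema
    cols = _attribute_columns(full, spec.coding)
    if spec.stage == "unforced" and spec.include_optout_asc:
        cols[ASC_COLUMN] = (base["alternative"] == "optout").to_numpy(float)
    if spec.interactions:
        if dataset.respondents is None:
            raise ValueError("interactions require a respondent table")
        inter = add_interactions(full, dataset.respondents, spec.interactions)
        for c in inter.columns:
            cols[c] = inter[c].to_numpy(float)

    names = list(cols)
    M = np.column_stack([cols[c] for c in names])
    choice_col = "chosen_forced" if spec.stage == "forced" else "chosen_unforced"
    chosen = base[choice_col].to_numpy(int)

    rids = list(dict.fromkeys(base["respondent_id"]))
    sizes = base.groupby(["respondent_id", "position"], sort=False).size()
    if sizes.nunique() != 1:
        raise ValueError("ragged tasks: all tasks must present the same alternatives")
    J = int(sizes.iloc[0])
    per_resp = base.groupby("respondent_id", sort=False).size()
    if per_resp.nunique() != 1:
        raise ValueError("ragged panel: all respondents must answer the same tasks")
    T = int(per_resp.iloc[0]) // J
    N = len(rids)
    X = M.reshape(N, T, J, -1)
    y = chosen.reshape(N, T, J).argmax(axis=2)
    return _Arrays(X=X, y=y, columns=names, respondent_ids=rids, n_alts=J)


def _check_rank(arr: _Arrays) -> None:
    X = arr.X
    centered = X - X.mean(axis=2, keepdims=True)
    M = centered.reshape(-1, X.shape[-1])
    G = M.T @ M
    s = np.linalg.svd(G, compute_uv=False)
    tol = s.max() * G.shape[0] * np.finfo(float).eps if s.max() > 0 else 0.0
    if s.min() <= tol:
        _, sv, vt = np.linalg.svd(G)
        null = vt[sv <= tol]
        aliased = sorted(
            {arr.columns[i] for row in null for i in np.nonzero(np.abs(row) > 1e-8)[0]}
        )
        raise RankDeficientError(
            f"design matrix rank deficient; aliased columns: {aliased}",
            aliased_columns=aliased,
        )


class _MixlProblem:
    """Cached arrays + draws; simulated log-likelihood, score and Hessian."""

    def __init__(self, dataset: ChoiceDataset, spec: ModelSpec, z_override=None):
        self.spec = spec
        self.arr = build_design_arrays(dataset, spec)
        K = self.arr.X.shape[-1]
        if spec.random is None:
            self.random_names = [c for c in self.arr.columns if "_x_" not in c]
        else:
            unknown = set(spec.random) - set(self.arr.columns)
            if unknown:
                raise ValueError(f"unknown random columns: {sorted(unknown)}")
            self.random_names = [c for c in self.arr.columns if c in set(spec.random)]
        self.rand_idx = np.array(
            [self.arr.columns.index(c) for c in self.random_names], dtype=int
        )
        Kr = len(self.rand_idx)
        N = self.arr.X.shape[0]
        R = spec.n_draws if Kr else 1
        primes = spec.halton_primes or PRIMES
        if Kr > len(primes):
            raise ValueError(f"{Kr} random coefficients exceed the supplied primes")
        if z_override is not None:
            if z_override.shape != (N, R, Kr):
                raise ValueError("draw override has the wrong shape")
            self.z = z_override
        else:
            if spec.draw_allocation == "rotated" and Kr:
                self.z = rotated_halton_panel(
                    N, R, Kr, burn=spec.halton_burn, seed=spec.seed
                )
            elif spec.antithetic and Kr and R > 1:
                # antithetic pairing: each Halton point enters with its
                # mirror image, cancelling odd-order integration error
                half = (R + 1) // 2
                zh = normal_halton_panel(
                    N, half, Kr, burn=spec.halton_burn, scramble=spec.scramble
                )
                self.z = np.concatenate([zh, -zh], axis=1)[:, :R, :]
            else:
                self.z = normal_halton_panel(
                    N, R, Kr, burn=spec.halton_burn, scramble=spec.scramble
                )
        self.R = R
        self.K = K
        self.Kr = Kr
        self.N, self.T = self.arr.y.shape
        self.J = self.arr.n_alts

        # group respondents sharing a design-matrix block (same survey block)
        # so utilities reduce to one large GEMM per group; respondents are
        # permuted group-contiguous internally (all outputs are order-free)
        by_key: dict[bytes, list[int]] = {}
        for n in range(self.N):
            by_key.setdefault(self.arr.X[n].tobytes(), []).append(n)
        perm = np.array([n for members in by_key.values() for n in members])
        self.arr.X = self.arr.X[perm]
        self.arr.y = self.arr.y[perm]
        self.arr.respondent_ids = [self.arr.respondent_ids[i] for i in perm]
        self.groups: list[tuple[np.ndarray, slice]] = []
        start = 0
        for members in by_key.values():
            Xg = np.ascontiguousarray(
                self.arr.X[start].reshape(self.T * self.J, K)
            )
            self.groups.append((Xg, slice(start, start + len(members))))
            start += len(members)

        idx = np.arange(self.T)
        self.x_chosen = self.arr.X[np.arange(self.N)[:, None], idx[None, :], self.arr.y]
        self.xc_sum = self.x_chosen.sum(axis=1)  # (N, K)
        # single-precision copies used only inside the Hessian assembly
        self.z32 = self.z.astype(np.float32)
        self.X32 = self.arr.X.astype(np.float32)

    @property
    def param_names(self) -> list[str]:
        return list(self.arr.columns) + [f"sd_{c}" for c in self.random_names]

    def unpack(self, theta: np.ndarray):
        b = theta[: self.K]
        s = theta[self.K :]
        return b, s

    def _forward(self, theta):
        """Utilities -> in-place choice probabilities, panel weights.

        Returns (ll, ll_n, P, w) with P of shape (N, R, T, J) and the
        per-draw panel weights w (rows sum to 1).
        """
        b, s = self.unpack(theta)
        N, R, T, J, K, Kr = self.N, self.R, self.T, self.J, self.K, self.Kr
        V = np.empty((N, R, T * J))
        for Xg, sl in self.groups:
            nb = sl.stop - sl.start
            base = Xg @ b  # (TJ,) systematic utility at the means
            if Kr:
                M = s[:, None] * Xg[:, self.rand_idx].T  # (Kr, TJ)
                Vg = self.z[sl].reshape(nb * R, Kr) @ M
                Vg += base
                V[sl] = Vg.reshape(nb, R, T * J)
            else:
                V[sl] = base
        V = V.reshape(N, R, T, J)
        v_chosen = np.take_along_axis(
            V, self.arr.y[:, None, :, None], axis=3
        )[:, :, :, 0].copy()
        vmax = V[:, :, :, 0].copy()
        for j in range(1, J):
            np.maximum(vmax, V[:, :, :, j], out=vmax)
        np.subtract(V, vmax[:, :, :, None], out=V)
        np.exp(V, out=V)  # V now holds exp(V - vmax)
        denom = V[:, :, :, 0].copy()
        for j in range(1, J):
            denom += V[:, :, :, j]
        logden = np.log(denom)
        logden += vmax
        L = (v_chosen - logden).sum(axis=2)  # (N, R) panel log-prob per draw
        Lmax = L.max(axis=1, keepdims=True)
        mix = np.exp(L - Lmax).mean(axis=1)
        ll_n = np.log(mix) + Lmax[:, 0]
        V /= denom[:, :, :, None]  # V now holds choice probabilities P
        w = np.exp(L - Lmax - np.log(mix * self.R)[:, None])
        return float(ll_n.sum()), ll_n, V, w

    def _xbar_sum(self, P):
        """sum_t E[x | task t] per respondent and draw: (N, R, K)."""
        N, R, T, J, K = self.N, self.R, self.T, self.J, self.K
        Pflat = P.reshape(N, R, T * J)
        out = np.empty((N, R, K))
        for Xg, sl in self.groups:
            nb = sl.stop - sl.start
            out[sl] = (Pflat[sl].reshape(nb * R, T * J) @ Xg).reshape(nb, R, K)
        return out

    def _score_n(self, P, w):
        g = self.xc_sum[:, None, :] - self._xbar_sum(P)  # per-draw panel score
        w1 = w[:, None, :]
        score_b = np.matmul(w1, g)[:, 0]
        if self.Kr:
            gz = g[:, :, self.rand_idx] * self.z
            score_s = np.matmul(w1, gz)[:, 0]
            return np.concatenate([score_b, score_s], axis=1), g
        return score_b, g

    def loglik_and_score(self, theta: np.ndarray, want_score=True, per_respondent=False):
        theta = np.asarray(theta, dtype=float)
        if not want_score:
            ll, ll_n, _, _ = self._forward(theta)
            return (ll, ll_n) if per_respondent else ll
        ll, ll_n, P, w = self._forward(theta)
        score_n, _ = self._score_n(P, w)
        if per_respondent:
            return ll, ll_n, score_n
        return ll, score_n.sum(axis=0)

    def hessian(self, theta: np.ndarray) -> np.ndarray:
        """Analytic Hessian of the simulated log-likelihood.

        Uses the mixture identity
        ``d2 ll_n = sum_r w_nr (H_nr + g_nr g_nr') - s_n s_n'`` with
        per-draw logit Hessian ``H_nr = -sum_t (sum_j P x x' - xbar xbar')``
        mapped from beta- to (mean, sd)-space via the draw matrix z. The
        large contractions accumulate in single precision (relative error
        ~1e-6 per entry), which is far below the statistical noise of any
        standard error derived from the result.
        """
        theta = np.asarray(theta, dtype=float)
        ll, ll_n, P, w = self._forward(theta)
        N, T, J, R, K, Kr = self.N, self.T, self.J, self.R, self.K, self.Kr
        ridx = self.rand_idx
        score_n, g = self._score_n(P, w)

        f32 = np.float32
        P = P.astype(f32)
        Pflat = P.reshape(N, R, T * J)
        w32 = w.astype(f32)
        z = self.z32
        zf = z.reshape(N * R, Kr)
        X2f = self.X32.reshape(N * T * J, K)
        nP = K + Kr

        # --- T1: sum over rows of  c * x x'  with r-contracted weights c ---
        pairs = [(a, b) for a in range(Kr) for b in range(a, Kr)]
        T1 = np.zeros((nP, nP))
        # weight columns: w | w z_l | w z_a z_b, contracted against P over draws
        wcols = [w32[:, :, None]]
        if Kr:
            wcols.append(w32[:, :, None] * z)
        c_base = np.matmul(
            Pflat.transpose(0, 2, 1), np.concatenate(wcols, axis=2)
        )  # (N, TJ, 1+Kr)
        c0 = c_base[:, :, 0].reshape(-1)
        T1[:K, :K] = X2f.T @ (c0[:, None] * X2f)
        if Kr:
            for li in range(Kr):
                cl = c_base[:, :, 1 + li].reshape(-1)
                T1[:K, K + li] = X2f.T @ (cl * X2f[:, ridx[li]])
            # z_a z_b weights in chunks to bound memory
            chunk = 32
            buf = np.empty((N, R, chunk), dtype=f32)
            for start in range(0, len(pairs), chunk):
                sub = pairs[start : start + chunk]
                wzz = buf[:, :, : len(sub)]
                for off, (a, b) in enumerate(sub):
                    np.multiply(z[:, :, a], z[:, :, b], out=wzz[:, :, off])
                    wzz[:, :, off] *= w32
                czz = np.matmul(Pflat.transpose(0, 2, 1), wzz)  # (N, TJ, len(sub))
                for off, (a, b) in enumerate(sub):
                    val = float(
                        np.sum(czz[:, :, off].reshape(-1) * X2f[:, ridx[a]] * X2f[:, ridx[b]])
                    )
                    T1[K + a, K + b] = val
                    T1[K + b, K + a] = val
            T1[K:, :K] = T1[:K, K:].T

        # --- T2: sum over (n, t, r) of  w * xbar xbar'  (per task!) ---
        T2 = np.zeros((nP, nP))
        sqw = np.sqrt(w32)
        xbar_t = np.empty((N, R, K), dtype=f32)
        for t in range(T):
            for Xg, sl in self.groups:
                nb = sl.stop - sl.start
                Xg_t = self.X32[sl.start, t]  # (J, K) shared within the group
                xbar_t[sl] = (
                    P[sl, :, t, :].reshape(nb * R, J) @ Xg_t
                ).reshape(nb, R, K)
            U = (xbar_t * sqw[:, :, None]).reshape(N * R, K)
            T2[:K, :K] += U.T @ U
            if Kr:
                Vz = U[:, ridx] * zf
                T2[:K, K:] += U.T @ Vz
                T2[K:, K:] += Vz.T @ Vz
        if Kr:
            T2[K:, :K] = T2[:K, K:].T

        # --- sum_r w g g'  and  - s_n s_n' ---
        Gf = (g.astype(f32) * sqw[:, :, None]).reshape(N * R, K)
        GG = np.zeros((nP, nP))
        GG[:K, :K] = Gf.T @ Gf
        if Kr:
            Gz = Gf[:, ridx] * zf
            GG[:K, K:] = Gf.T @ Gz
            GG[K:, :K] = GG[:K, K:].T
            GG[K:, K:] = Gz.T @ Gz

        H = -(T1 - T2) + GG - score_n.T @ score_n
        return 0.5 * (H + H.T)

@dataclass
class MixlFit:
    """Estimated mixed-logit model.

    ``theta`` stacks coefficient means (all design columns, in
    ``column_names`` order) then mixing SDs for ``random_names``. SDs keep
    their raw (possibly negative) sign; ``abs_sds`` exposes magnitudes.
    """

    column_names: list[str]
    random_names: list[str]
    theta: np.ndarray
    cov: np.ndarray
    loglik: float
    warm_start_loglik: float
    n_respondents: int
    n_draws: int
    converged: bool
    n_iter: int
    grad_norm: float
    spec: ModelSpec
    seed: int = 0

    @property
    def param_names(self) -> list[str]:
        return list(self.column_names) + [f"sd_{c}" for c in self.random_names]

    @property
    def means(self) -> dict[str, float]:
        return dict(zip(self.column_names, self.theta[: len(self.column_names)]))

    @property
    def sds(self) -> dict[str, float]:
        return dict(zip(self.random_names, self.theta[len(self.column_names):]))

    @property
    def abs_sds(self) -> dict[str, float]:
        return {k: abs(v) for k, v in self.sds.items()}

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov), 0.0, None))

    def summary(self) -> pd.DataFrame:
        se = self.se
        with np.errstate(divide="ignore", invalid="ignore"):
            zval = np.where(se > 0, self.theta / se, np.nan)
        pval = 2 * norm.sf(np.abs(zval))
        return pd.DataFrame(
            {
                "parameter": self.param_names,
                "estimate": self.theta,
                "se": se,
                "z": zval,
                "p": pval,
                "ci_low": self.theta - 1.96 * se,
                "ci_high": self.theta + 1.96 * se,
            }
        )

    def to_dict(self) -> dict:
        return {
            "column_names": self.column_names,
            "random_names": self.random_names,
            "theta": self.theta.tolist(),
            "cov": self.cov.tolist(),
            "loglik": self.loglik,
            "warm_start_loglik": self.warm_start_loglik,
            "n_respondents": self.n_respondents,
            "n_draws": self.n_draws,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
            "seed": self.seed,
            "spec": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.spec).items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixlFit":
        spec_d = dict(d["spec"])
        if spec_d.get("random") is not None:
            spec_d["random"] = tuple(spec_d["random"])
        if spec_d.get("halton_primes") is not None:
            spec_d["halton_primes"] = tuple(spec_d["halton_primes"])
        spec_d["interactions"] = tuple(tuple(p) for p in spec_d.get("interactions", ()))
        spec = ModelSpec(**spec_d)
        return cls(
            column_names=list(d["column_names"]),
            random_names=list(d["random_names"]),
            theta=np.asarray(d["theta"], dtype=float),
            cov=np.asarray(d["cov"], dtype=float),
            loglik=d["loglik"],
            warm_start_loglik=d["warm_start_loglik"],
            n_respondents=d["n_respondents"],
            n_draws=d["n_draws"],
            converged=d["converged"],
            n_iter=d["n_iter"],
            grad_norm=d["grad_norm"],
            spec=spec,
            seed=d.get("seed", 0),
        )


def loglik_mixl(theta: np.ndarray, dataset: ChoiceDataset, spec: ModelSpec) -> float:
    """Simulated log-likelihood at a stacked (means, sds) parameter vector."""
    prob = _MixlProblem(dataset, spec)
    theta = np.asarray(theta, dtype=float)
    expected = prob.K + prob.Kr
    if theta.shape != (expected,):
        raise ValueError(f"theta must have length {expected}, got {theta.shape}")
    return prob.loglik_and_score(theta, want_score=False)


def _fd_hessian(fun_grad, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    P = len(theta)
    H = np.zeros((P, P))
    for i in range(P):
        h = rel_step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[i] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def _covariance(problem: _MixlProblem, theta: np.ndarray, method: str, hess=None) -> np.ndarray:
    _, _, score_n = problem.loglik_and_score(theta, per_respondent=True)
    B = score_n.T @ score_n  # outer-product-of-gradients information
    if method == "opg":
        return np.linalg.pinv(B)
    if method == "hessian-fd":
        H = _fd_hessian(lambda t: problem.loglik_and_score(t), theta)
    elif hess is not None:
        H = hess
    else:
        H = problem.hessian(theta)
    Hinv = np.linalg.pinv(-H)
    if method in ("hessian", "hessian-fd"):
        return Hinv
    if method == "sandwich":
        return Hinv @ B @ Hinv
    raise ValueError(f"unknown se_method {method!r}")


def fit_mixl(dataset: ChoiceDataset, spec: ModelSpec) -> MixlFit:
    """Maximum simulated likelihood fit with a conditional-logit warm start.

    Means start at the conditional-logit optimum (the model with all SDs
    fixed at zero, for which the simulated likelihood is exact at any draw
    count); SDs start at ``spec.sd_init``. Quasi-Newton (BFGS) iterations
    with the analytic score; standard errors from the inverse finite-
    difference Hessian by default.
    """
    problem = _MixlProblem(dataset, spec)
    if problem.N < 2:
        raise ValueError("need at least 2 respondents")
    _check_rank(problem.arr)

    cl_problem = _MixlProblem(dataset, replace(spec, random=(), n_draws=1))

    def cl_neg(t):
        ll, g = cl_problem.loglik_and_score(t)
        return -ll, -g

    cl0 = np.zeros(problem.K)
    cl_res = minimize(cl_neg, cl0, jac=True, method="BFGS",
                      options={"gtol": spec.gtol, "maxiter": spec.maxiter})
    warm_ll = -cl_res.fun

    theta0 = np.concatenate([cl_res.x, np.full(problem.Kr, spec.sd_init)])

    def neg(t):
        ll, g = problem.loglik_and_score(t)
        return -ll, -g

    # optimize on leading subsets of the same Halton sequence first, then
    # polish at the full draw count by damped Newton with the analytic
    # Hessian; the reported optimum is always the spec.n_draws objective
    n_iter = 0
    hess_at_opt = None
    if problem.Kr and spec.n_draws >= 200:
        for R_stage, gtol_stage in ((50, 1e-3), (150, max(1e-4, 3 * spec.gtol))):
            stage = _MixlProblem(
                dataset,
                replace(spec, n_draws=R_stage),
                z_override=problem.z[:, :R_stage, :],
            )

            def neg_stage(t, p=stage):
                ll, g = p.loglik_and_score(t)
                return -ll, -g

            pre = minimize(neg_stage, theta0, jac=True, method="BFGS",
                           options={"gtol": gtol_stage, "maxiter": spec.maxiter})
            theta0 = pre.x
            n_iter += int(pre.nit)
        theta, ll, grad, hess_at_opt, newton_ok, it = _newton_polish(
            problem, theta0, gtol=spec.gtol, maxiter=25
        )
        n_iter += it
        if not newton_ok:  # rare: fall back to quasi-Newton from this point
            res = minimize(neg, theta, jac=True, method="BFGS",
                           options={"gtol": spec.gtol, "maxiter": spec.maxiter})
            theta, ll, grad = res.x, -float(res.fun), -res.jac
            hess_at_opt = None
            n_iter += int(res.nit)
    else:
        res = minimize(neg, theta0, jac=True, method="BFGS",
                       options={"gtol": spec.gtol, "maxiter": spec.maxiter})
        theta, ll, grad = res.x, -float(res.fun), -res.jac
        n_iter = int(res.nit)

    grad_norm = float(np.max(np.abs(grad)))
    converged = grad_norm < 100 * spec.gtol
    if not converged and grad_norm > 1e-2:
        raise NonConvergenceError(
            f"MSL optimization failed (|grad|={grad_norm:.3g})",
            grad_norm=grad_norm,
            last_params=theta,
        )
    cov = _covariance(problem, theta, spec.se_method, hess=hess_at_opt)
    return MixlFit(
        column_names=list(problem.arr.columns),
        random_names=list(problem.random_names),
        theta=theta,
        cov=cov,
        loglik=float(ll),
        warm_start_loglik=float(warm_ll),
        n_respondents=problem.N,
        n_draws=problem.R,
        converged=converged,
        n_iter=n_iter,
        grad_norm=grad_norm,
        spec=spec,
        seed=spec.seed,
    )


def _newton_polish(problem, theta0, gtol, maxiter=40):
    """Damped (chord) Newton ascent with the analytic Hessian.

    The Hessian is refactored only every few steps or when the line search
    stalls — near the optimum the curvature barely moves, so reusing the
    factorization gives Newton-quality steps at gradient cost.
    """
    from scipy.linalg import cho_factor, cho_solve

    theta = np.asarray(theta0, dtype=float)
    nP = len(theta)
    ll, g = problem.loglik_and_score(theta)
    ok = True
    it = 0
    H = None
    factor = None
    age = 10**9
    for it in range(1, maxiter + 1):
        if np.abs(g).max() < gtol:
            break
        if factor is None or age >= 5:
            H = problem.hessian(theta)
            age = 0
            ev = np.linalg.eigvalsh(H)
            ridge = 1e-8 + (float(ev.max()) + 0.1 * abs(float(ev.min()))
                            if ev.max() > -1e-8 else 0.0)
            try:
                factor = cho_factor(-(H - ridge * np.eye(nP)))
            except np.linalg.LinAlgError:
                factor = cho_factor(-(H - (ridge + abs(float(ev.min()))) * np.eye(nP)))
        step = cho_solve(factor, g)
        d = float(g @ step)  # > 0: ascent direction by construction
        alpha, accepted = 1.0, False
        for _ in range(8):
            ll2, g2 = problem.loglik_and_score(theta + alpha * step)
            if ll2 > ll + 1e-4 * alpha * d:
                accepted = True
                break
            alpha *= 0.25
        if not accepted:
            if age == 0:
                ok = False
                break
            factor = None  # stale curvature: refactor and retry
            continue
        theta, ll, g = theta + alpha * step, ll2, g2
        age += 1
        if alpha < 0.25:
            factor = None
    else:
        ok = bool(np.abs(g).max() < gtol)
    if ok:
        H = problem.hessian(theta)  # curvature at the accepted optimum
    return theta, ll, g, H, ok, it


def stability_check(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    draw_grid: tuple[int, ...],
    tol: float = 0.01,
) -> pd.DataFrame:
    """Refit along an increasing draw grid and track estimate movement.

    The relative change between consecutive grid points is
    ``|delta| / max(|previous|, 0.05)`` elementwise (the floor keeps
    near-zero coefficients from dominating); the model is flagged stable
    once the maximum change drops below ``tol``.
    """
    if list(draw_grid) != sorted(draw_grid) or len(set(draw_grid)) != len(draw_grid):
        raise ValueError("draw_grid must be strictly increasing")
    rows = []
    prev = None
    for R in draw_grid:
        fit = fit_mixl(dataset, replace(spec, n_draws=R))
        if prev is None:
            change = np.nan
        else:
            change = float(
                np.max(np.abs(fit.theta - prev) / np.maximum(np.abs(prev), 0.05))
            )
        rows.append(
            {
                "n_draws": R,
                "loglik": fit.loglik,
                "max_rel_change": change,
                "stable": bool(change < tol) if prev is not None else False,
                "estimates": dict(zip(fit.param_names, fit.theta)),
            }
        )
        prev = fit.theta
    return pd.DataFrame(rows)
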
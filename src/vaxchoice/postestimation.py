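"""Relative importance, selection probabilities, and candidate rankings.

Relative importance (RI) summarizes a dummy-coded fit: each attribute's
range is the spread of its level coefficient means (the reference level
counts as zero); ranges are reported as raw shares of the total and
normalized so the widest attribute scores 100.

Vaccine prioritization uses a continuous-coded refit: the selection
probability of a candidate vaccine is the model-implied probability that it
beats a least-favorable base-case vaccine in a binary comparison, averaged
over the fitted normal mixing distribution (quasi-random draws). Respondent
bootstrap or Krinsky-Robb parameter draws provide 95% intervals, and
price-reduction scenarios rescale candidate costs before re-ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd

from .dataset import ChoiceDataset
from .estimate import ASC_COLUMN, MixlFit, ModelSpec, fit_mixl
from .halton import normal_halton_panel
from .schema import AttributeSchema, default_schema

__all__ = [
    "RIResult",
    "CandidateVaccine",
    "DEFAULT_BASE_CASE",
    "default_evidence_table",
    "relative_importance",
    "refit_continuous",
    "continuous_spec",
    "predict_selection_probability",
    "bootstrap_ci",
    "rank_candidates",
]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass
class RIResult:
    table: pd.DataFrame  # attribute, range, raw_share, ri, ri_rounded

    def ri(self, attribute: str) -> float:
        return float(self.table.set_index("attribute").loc[attribute, "ri"])

    def ri_rounded(self, attribute: str) -> int:
        return int(self.table.set_index("attribute").loc[attribute, "ri_rounded"])


def relative_importance(fit: MixlFit, schema: AttributeSchema | None = None) -> RIResult:
    """Range-based attribute importance from a dummy-coded fit.

    Per attribute the range is ``max - min`` over {0 (reference)} and the
    level coefficient means; the opt-out constant is excluded. Raw shares
    divide by the sum of ranges; normalized RI scales the widest attribute
    to 100, with half-up integer rounding for reporting.
    """
    schema = schema or default_schema()
    means = fit.means
    rows = []
    for attr in schema.attributes:
        coefs = [0.0]
        for i in attr.non_reference_indices():
            col = f"{attr.name}={attr.levels[i]}"
            if col not in means:
                raise ValueError(
                    f"fit is not dummy-coded for attribute {attr.name!r} "
                    f"(missing column {col!r})"
                )
            coefs.append(means[col])
        rows.append({"attribute": attr.name, "range": max(coefs) - min(coefs)})
    table = pd.DataFrame(rows)
    total = table["range"].sum()
    top = table["range"].max()
    table["raw_share"] = table["range"] / total
    table["ri"] = 100.0 * table["range"] / top
    table["ri_rounded"] = table["ri"].map(_round_half_up)
    return RIResult(table=table)


@dataclass(frozen=True)
class CandidateVaccine:
    """One row of the candidate-vaccine evidence table."""

    name: str
    incidence: float  # per 100,000
    mortality: float  # per 100,000
    effectiveness: float  # %
    cost: float  # CNY, all doses
    group: str
    coverage: float  # %

    def __post_init__(self):
        for fname in ("incidence", "mortality", "effectiveness", "cost", "coverage"):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be >= 0")

    def values(self) -> dict:
        return {
            "incidence": self.incidence,
            "mortality": self.mortality,
            "effectiveness": self.effectiveness,
            "cost": self.cost,
            "group": self.group,
            "coverage": self.coverage,
        }


# Least favorable level of every attribute (the base-case comparator).
DEFAULT_BASE_CASE: dict = {
    "incidence": 10,
    "mortality": 0,
    "effectiveness": 20,
    "cost": 100,
    "group": "adults",
    "coverage": 1,
}


def default_evidence_table() -> list[CandidateVaccine]:
    """Published evidence on candidate vaccines for China's NIP.

    Incidence/mortality of the targeted disease per 100,000, effectiveness
    (%), lowest current total cost (CNY), target group, and current
    coverage (%).
    """
    rows = [
        ("varicella", 55.05, 0.0005, 90, 302.0, "preschoolers", 67.1),
        ("hib", 301, 4, 93, 333.6, "preschoolers", 25.0),
        ("ev71", 134.59, 0.03, 89.7, 366.0, "preschoolers", 23.9),
        ("influenza_preschoolers", 1050, 2.67, 57, 269.0, "preschoolers", 28.4),
        ("influenza_school_age", 1050, 2.67, 47, 708.0, "school_age", 25.1),
        ("pcv", 679, 10, 60.9, 1892.0, "preschoolers", 5.1),
        ("hpv_school_age", 11.34, 3.36, 80.72, 1017.0, "school_age", 2.24),
        ("hpv_adults", 11.34, 3.36, 80.72, 1017.0, "adults", 2.24),
        ("influenza_older_adults", 157, 122.79, 18, 1180.0, "older_adults", 26.7),
        ("influenza_adults", 429, 2.67, 36, 2478.0, "adults", 6.7),
        ("rotavirus", 178.1, 0.14, 85, 561.0, "preschoolers", 1.8),
    ]
    return [CandidateVaccine(*r) for r in rows]


def continuous_spec(schema: AttributeSchema | None = None, **overrides) -> ModelSpec:
    """Spec with numeric attributes continuous and categoricals dummy-coded."""
    schema = schema or default_schema()
    coding = {a.name: ("continuous" if a.is_numeric else "dummy") for a in schema.attributes}
    return ModelSpec(coding=coding, **overrides)


def refit_continuous(dataset: ChoiceDataset, spec: ModelSpec | None = None) -> MixlFit:
    """Fit the prediction model: attributes continuous, group dummy-coded."""
    if spec is None:
        spec = continuous_spec(dataset.schema)
    else:
        coding = {
            a.name: ("continuous" if a.is_numeric else "dummy")
            for a in dataset.schema.attributes
        }
        spec = dc_replace(spec, coding=coding)
    return fit_mixl(dataset, spec)


def _utility_row(fit: MixlFit, vaccine: dict, schema: AttributeSchema) -> np.ndarray:
    """Design-row vector for one vaccine under the fit's columns."""
    x = np.zeros(len(fit.column_names))
    for j, col in enumerate(fit.column_names):
        if col == ASC_COLUMN or "_x_" in col:
            continue  # opt-out constant and interactions do not enter predictions
        if "=" in col:
            attr_name, lvl = col.split("=", 1)
            attr = schema[attr_name]
            val = vaccine[attr_name]
            if attr_name == "group" and val not in attr.levels:
                raise ValueError(f"unknown group category {val!r}")
            x[j] = float(str(val) == lvl)
        else:
            x[j] = float(vaccine[col])
    return x


def _beta_draws(fit: MixlFit, n_draws: int, seed: int | None, at_means: bool) -> np.ndarray:
    b = fit.theta[: len(fit.column_names)]
    if at_means:
        return b[None, :]
    rand_idx = np.array([fit.column_names.index(c) for c in fit.random_names], int)
    s = np.array([abs(fit.sds[c]) for c in fit.random_names])
    shift = None
    if seed is not None:
        shift = np.random.default_rng(seed).random(len(rand_idx))
    z = normal_halton_panel(1, n_draws, len(rand_idx), burn=50, shift=shift)[0]
    beta = np.broadcast_to(b, (n_draws, len(b))).copy()
    if len(rand_idx):
        beta[:, rand_idx] += s * z
    return beta


def predict_selection_probability(
    fit: MixlFit,
    candidate: CandidateVaccine | dict,
    base_case: dict | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    at_means: bool = False,
    with_optout: bool = False,
    schema: AttributeSchema | None = None,
) -> float:
    """Probability that the candidate beats the base-case vaccine.

    ``E_beta[ logistic(V_cand - V_base) ]`` with beta drawn from the fitted
    normal mixing distribution via Halton draws (``at_means`` collapses to
    the point estimate). ``with_optout`` adds the opt-out as a third
    alternative with utility equal to the fitted constant.
    """
    schema = schema or default_schema()
    base = dict(DEFAULT_BASE_CASE if base_case is None else base_case)
    cand = candidate.values() if isinstance(candidate, CandidateVaccine) else dict(candidate)
    xc = _utility_row(fit, cand, schema)
    xb = _utility_row(fit, base, schema)
    beta = _beta_draws(fit, n_draws, seed, at_means)
    vc = beta @ xc
    vb = beta @ xb
    if with_optout:
        if ASC_COLUMN not in fit.column_names:
            raise ValueError("fit has no opt-out constant")
        j = fit.column_names.index(ASC_COLUMN)
        va = beta[:, j]
        m = np.maximum.reduce([vc, vb, va])
        ec, eb, ea = np.exp(vc - m), np.exp(vb - m), np.exp(va - m)
        p = ec / (ec + eb + ea)
    else:
        p = 1.0 / (1.0 + np.exp(-(vc - vb)))
    return float(p.mean())


def bootstrap_ci(
    dataset: ChoiceDataset,
    spec: ModelSpec,
    candidates: list[CandidateVaccine],
    B: int = 1000,
    seed: int = 0,
    base_case: dict | None = None,
    n_draws: int = 1000,
    method: str = "bootstrap",
    at_means: bool = False,
) -> pd.DataFrame:
    """95% intervals for candidate selection probabilities.

    ``method="bootstrap"`` resamples respondents with replacement and refits
    the model per replicate (failed refits are dropped and counted; the CI
    is flagged unreliable past 10% failures). ``method="krinsky-robb"``
    draws parameters from the fitted sampling distribution instead of
    refitting. Percentile 2.5/97.5 bounds either way.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    point_fit = fit_mixl(dataset, spec)
    points = {
        c.name: predict_selection_probability(
            point_fit, c, base_case, n_draws, seed, at_means, schema=dataset.schema
        )
        for c in candidates
    }
    reps: dict[str, list[float]] = {c.name: [] for c in candidates}
    n_failed = 0
    if method == "bootstrap":
        ids = dataset.respondent_ids
        for _ in range(B):
            sample = rng.choice(ids, size=len(ids), replace=True)
            try:
                bfit = fit_mixl(dataset.resample_respondents(sample), spec)
            except Exception:
                n_failed += 1
                continue
            for c in candidates:
                reps[c.name].append(
                    predict_selection_probability(
                        bfit, c, base_case, n_draws, seed, at_means, schema=dataset.schema
                    )
                )
    elif method == "krinsky-robb":
        L = np.linalg.cholesky(
            point_fit.cov + 1e-10 * np.eye(point_fit.cov.shape[0])
        )
        for _ in range(B):
            draw = point_fit.theta + L @ rng.standard_normal(len(point_fit.theta))
            dfit = dc_replace(point_fit, theta=draw)
            for c in candidates:
                reps[c.name].append(
                    predict_selection_probability(
                        dfit, c, base_case, n_draws, seed, at_means, schema=dataset.schema
                    )
                )
    else:
        raise ValueError(f"unknown method {method!r}")
    rows = []
    for c in candidates:
        vals = np.array(reps[c.name])
        lo, hi = (np.percentile(vals, [2.5, 97.5]) if len(vals) else (np.nan, np.nan))
        rows.append(
            {
                "name": c.name,
                "probability": points[c.name],
                "ci_low": float(lo),
                "ci_high": float(hi),
                "n_replicates": len(vals),
                "n_failed": n_failed,
                "reliable": n_failed <= 0.1 * B,
            }
        )
    return pd.DataFrame(rows)


def rank_candidates(
    fit: MixlFit,
    evidence: list[CandidateVaccine],
    price_multipliers: tuple[float, ...] = (1.0, 0.5, 0.3),
    base_case: dict | None = None,
    n_draws: int = 1000,
    seed: int | None = None,
    at_means: bool = False,
    schema: AttributeSchema | None = None,
) -> pd.DataFrame:
    """Selection probabilities and dense ranks under price scenarios.

    Each multiplier rescales every candidate's cost (non-price attributes
    unchanged) before probabilities are recomputed; ranking is by descending
    probability within scenario.
    """
    if not evidence:
        raise ValueError("evidence table is empty")
    rows = []
    for mult in price_multipliers:
        for c in evidence:
            scaled = CandidateVaccine(
                name=c.name,
                incidence=c.incidence,
                mortality=c.mortality,
                effectiveness=c.effectiveness,
                cost=c.cost * mult,
                group=c.group,
                coverage=c.coverage,
            )
            p = predict_selection_probability(
                fit, scaled, base_case, n_draws, seed, at_means, schema=schema
            )
            rows.append(
                {
                    "scenario": mult,
                    "name": c.name,
                    "cost": scaled.cost,
                    "probability": p,
                }
            )
    out = pd.DataFrame(rows)
    out["rank"] = (
        out.groupby("scenario")["probability"]
        .rank(method="dense", ascending=False)
        .astype(int)
    )
    return out.sort_values(["scenario", "rank"]).reset_index(drop=True)
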
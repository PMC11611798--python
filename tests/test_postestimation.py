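"""Relative importance, selection probabilities, bootstrap CIs, rankings."""

import numpy as np
import pandas as pd
import pytest

from vaxchoice.estimate import ASC_COLUMN, MixlFit, ModelSpec, fit_mixl
from vaxchoice.population import (
    DEFAULT_UNFORCED_MEANS,
    PopulationParams,
    default_population_params,
)
from vaxchoice.postestimation import (
    DEFAULT_BASE_CASE,
    CandidateVaccine,
    bootstrap_ci,
    continuous_spec,
    default_evidence_table,
    predict_selection_probability,
    rank_candidates,
    refit_continuous,
    relative_importance,
)
from vaxchoice.schema import Attribute, AttributeSchema, default_schema
from vaxchoice.simulate import simulate_choices, simulate_respondents

from conftest import ATTENTIVE_MIX, make_dataset


def fit_from_means(means, random_names=None, spec=None):
    """Wrap a coefficient-mean dictionary as a fitted model object."""
    names = list(means)
    rnames = list(random_names or [])
    theta = np.array([means[c] for c in names] + [0.0] * len(rnames))
    return MixlFit(
        column_names=names,
        random_names=rnames,
        theta=theta,
        cov=np.eye(len(theta)),
        loglik=0.0,
        warm_start_loglik=0.0,
        n_respondents=0,
        n_draws=1,
        converged=True,
        n_iter=0,
        grad_norm=0.0,
        spec=spec or ModelSpec(),
    )


class TestRelativeImportance:
    def test_reference_study_values(self, schema):
        """RI from the published unforced coefficient means: effectiveness
        dominates (100), coverage 94, mortality 22, incidence and cost 19;
        the vaccinated-group range computes to 38 from rounded inputs."""
        fit = fit_from_means(dict(DEFAULT_UNFORCED_MEANS))
        ri = relative_importance(fit, schema)
        assert ri.ri_rounded("effectiveness") == 100
        assert ri.ri_rounded("coverage") == 94
        assert ri.ri_rounded("mortality") == 22
        assert ri.ri_rounded("incidence") == 19
        assert ri.ri_rounded("cost") == 19
        assert abs(ri.ri_rounded("group") - 37) <= 1
        assert ri.table["raw_share"].sum() == pytest.approx(1.0)
        assert (ri.table["ri"] == 100).sum() == 1
        assert ri.table["ri"].between(0, 100).all()

    def test_single_attribute(self):
        s = AttributeSchema(attributes=(Attribute("a", (0, 1, 2)),))
        fit = fit_from_means({"a=1": 0.4, "a=2": 1.1})
        ri = relative_importance(fit, s)
        assert ri.ri("a") == 100
        assert ri.table["raw_share"].iloc[0] == pytest.approx(1.0)

    def test_equal_ranges_tie_at_100(self):
        s = AttributeSchema(
            attributes=(Attribute("a", (0, 1)), Attribute("b", (0, 1)))
        )
        fit = fit_from_means({"a=1": 0.7, "b=1": -0.7})
        ri = relative_importance(fit, s)
        assert ri.ri("a") == ri.ri("b") == 100
        assert np.allclose(ri.table["raw_share"], 0.5)

    def test_scale_invariance(self, schema):
        base = relative_importance(fit_from_means(dict(DEFAULT_UNFORCED_MEANS)), schema)
        scaled = relative_importance(
            fit_from_means({k: 2.7 * v for k, v in DEFAULT_UNFORCED_MEANS.items()}),
            schema,
        )
        assert np.allclose(base.table["ri"], scaled.table["ri"])

    def test_continuous_fit_rejected(self, schema):
        fit = fit_from_means({"incidence": 0.001, "group=adults": -0.4})
        with pytest.raises(ValueError):
            relative_importance(fit, schema)

    def test_asc_excluded_from_ri(self, schema):
        means = dict(DEFAULT_UNFORCED_MEANS)
        with_asc = dict(means, **{ASC_COLUMN: -5.0})
        a = relative_importance(fit_from_means(means), schema)
        b = relative_importance(fit_from_means(with_asc), schema)
        assert np.allclose(a.table["ri"], b.table["ri"])


CONT_MEANS = {
    "incidence": 0.0002,
    "mortality": 0.002,
    "effectiveness": 0.015,
    "cost": 0.0001,
    "group=school_age": -0.187,
    "group=adults": -0.414,
    "group=older_adults": -0.405,
    "coverage": 0.016,
    ASC_COLUMN: -0.953,
}


class TestSelectionProbability:
    def test_candidate_equal_to_base_is_half(self):
        fit = fit_from_means(CONT_MEANS, random_names=["effectiveness"])
        p = predict_selection_probability(fit, dict(DEFAULT_BASE_CASE), n_draws=64)
        assert p == pytest.approx(0.5, abs=0.0)

    def test_degenerate_mixture_is_closed_form_logistic(self):
        fit = fit_from_means(CONT_MEANS)  # no random coefficients
        cand = CandidateVaccine("x", 500, 10, 90, 300, "preschoolers", 60)
        p = predict_selection_probability(fit, cand, n_draws=10)
        delta = (
            CONT_MEANS["incidence"] * (500 - 10)
            + CONT_MEANS["mortality"] * 10
            + CONT_MEANS["effectiveness"] * 70
            + CONT_MEANS["cost"] * 200
            - CONT_MEANS["group=adults"]  # base group is adults
            + CONT_MEANS["coverage"] * 59
        )
        assert p == pytest.approx(1 / (1 + np.exp(-delta)), abs=1e-12)

    def test_one_random_coefficient_matches_quadrature(self):
        fit = fit_from_means(CONT_MEANS, random_names=["effectiveness"])
        fit.theta[-1] = 0.01  # sd on the effectiveness slope
        cand = CandidateVaccine("x", 500, 10, 90, 300, "preschoolers", 60)
        p = predict_selection_probability(fit, cand, n_draws=4000)
        nodes, weights = np.polynomial.hermite.hermgauss(100)
        x0 = np.zeros(len(fit.column_names))
        from vaxchoice.postestimation import _utility_row

        xc = _utility_row(fit, cand.values(), default_schema())
        xb = _utility_row(fit, dict(DEFAULT_BASE_CASE), default_schema())
        b = fit.theta[: len(fit.column_names)]
        j = fit.column_names.index("effectiveness")
        deltas = (xc - xb) @ b + 0.01 * np.sqrt(2) * nodes * (xc[j] - xb[j])
        oracle = np.sum(weights / np.sqrt(np.pi) / (1 + np.exp(-deltas)))
        assert p == pytest.approx(oracle, abs=1e-3)

    def test_monotone_in_positive_coefficient(self):
        fit = fit_from_means(CONT_MEANS)
        probs = [
            predict_selection_probability(
                fit,
                CandidateVaccine("x", 100, 0, eff, 500, "preschoolers", 30),
                n_draws=16,
            )
            for eff in (20, 50, 90)
        ]
        assert probs == sorted(probs)

    def test_unknown_group_rejected(self):
        fit = fit_from_means(CONT_MEANS)
        with pytest.raises(ValueError):
            predict_selection_probability(
                fit, CandidateVaccine("x", 1, 0, 50, 100, "astronauts", 10), n_draws=8
            )

    def test_optout_inclusion_lowers_probability_scale(self):
        fit = fit_from_means(CONT_MEANS, random_names=[ASC_COLUMN])
        fit.theta[-1] = 0.5
        cand = CandidateVaccine("x", 500, 10, 90, 300, "preschoolers", 60)
        p2 = predict_selection_probability(fit, cand, n_draws=256)
        p3 = predict_selection_probability(fit, cand, n_draws=256, with_optout=True)
        assert p3 < p2  # a third alternative absorbs probability mass


class TestRanking:
    def test_dominated_candidate_never_ranks_higher(self):
        """On the published evidence rows, school-age HPV weakly dominates
        adult HPV whenever the fitted group order favors younger groups."""
        fit = fit_from_means(CONT_MEANS)
        table = rank_candidates(
            fit, default_evidence_table(), price_multipliers=(1.0,), n_draws=16
        )
        r = table.set_index("name")["rank"]
        assert r["hpv_school_age"] <= r["hpv_adults"]

    def test_price_multiplier_halves_cost_only(self):
        fit = fit_from_means(CONT_MEANS)
        table = rank_candidates(
            fit, default_evidence_table(), price_multipliers=(1.0, 0.5), n_draws=16
        )
        full = table[table["scenario"] == 1.0].set_index("name")["cost"]
        half = table[table["scenario"] == 0.5].set_index("name")["cost"]
        assert np.allclose(half, full / 2)

    def test_single_candidate_ranks_first(self):
        fit = fit_from_means(CONT_MEANS)
        table = rank_candidates(
            fit, [default_evidence_table()[0]], price_multipliers=(1.0,), n_draws=8
        )
        assert table["rank"].tolist() == [1]

    def test_empty_evidence_rejected(self):
        fit = fit_from_means(CONT_MEANS)
        with pytest.raises(ValueError):
            rank_candidates(fit, [])


@pytest.fixture(scope="module")
def linear_world(blocked_design):
    """Data simulated from utilities exactly linear in the attributes."""
    schema = blocked_design.schema
    slopes = {
        "incidence": 0.0006,
        "mortality": 0.004,
        "effectiveness": 0.014,
        "cost": 0.00012,
        "coverage": 0.017,
    }
    group = {"group=school_age": -0.2, "group=adults": -0.4, "group=older_adults": -0.4}
    mean = {}
    for a in schema.attributes:
        for i in a.non_reference_indices():
            col = f"{a.name}={a.levels[i]}"
            if a.name == "group":
                mean[col] = group[col]
            else:
                ref = a.levels[a.reference_level]
                mean[col] = slopes[a.name] * (a.levels[i] - ref)
    params = PopulationParams(
        mean=mean, sd={k: 0.0 for k in mean}, asc_optout=(-0.953, 0.0)
    )
    roster = simulate_respondents(700, params=params, behavior_mix=ATTENTIVE_MIX, seed=71)
    ds = simulate_choices(blocked_design, roster, params, seed=72)
    return ds, slopes


class TestContinuousRefit:

    def test_slopes_recovered_within_ci(self, linear_world):
        ds, slopes = linear_world
        fit = refit_continuous(ds, ModelSpec(n_draws=20, random=()))
        summ = fit.summary().set_index("parameter")
        hits = sum(
            summ.loc[k, "ci_low"] <= v <= summ.loc[k, "ci_high"]
            for k, v in slopes.items()
        )
        assert hits >= 4  # allow one marginal miss among the five slopes

    def test_dummy_fit_linear_in_levels(self, linear_world):
        """With truly linear effects, the dummy coefficient at an
        equally-informative spacing scales with the level gap."""
        ds, slopes = linear_world
        fit = fit_mixl(ds, ModelSpec(n_draws=1, random=()))
        m = fit.means
        # coverage levels 1/30/60: the 60 dummy is about twice the 30 dummy
        ratio = m["coverage=60"] / m["coverage=30"]
        truth = (60 - 1) / (30 - 1)
        assert ratio == pytest.approx(truth, rel=0.25)

    def test_units_are_per_unit_of_attribute(self, linear_world):
        ds, slopes = linear_world
        fit = refit_continuous(ds, ModelSpec(n_draws=20, random=()))
        # coverage coded in percent units: the slope is per percentage point,
        # so a 59-point move reproduces the dummy gap magnitude
        assert abs(fit.means["coverage"] * 59 - 1.0) < 0.35  # truth: 0.017*59 ~ 1.0


class TestBootstrap:
    def test_smoke_run_with_two_replicates(self, blocked_design):
        ds = make_dataset(blocked_design, 60, seed=81)
        table = bootstrap_ci(
            ds,
            continuous_spec(ds.schema, n_draws=1, random=()),
            default_evidence_table()[:2],
            B=2,
            seed=1,
            n_draws=32,
        )
        assert (table["ci_low"] <= table["ci_high"]).all()
        assert (table["n_replicates"] == 2).all()

    def test_base_case_candidate_ci_brackets_half(self, blocked_design):
        ds = make_dataset(blocked_design, 80, seed=82)
        base_as_candidate = CandidateVaccine("base", 10, 0, 20, 100, "adults", 1)
        table = bootstrap_ci(
            ds,
            continuous_spec(ds.schema, n_draws=1, random=()),
            [base_as_candidate],
            B=5,
            seed=2,
            n_draws=16,
        )
        row = table.iloc[0]
        assert row["probability"] == 0.5
        assert row["ci_low"] == row["ci_high"] == 0.5

    def test_ci_width_shrinks_with_sample_size(self, blocked_design):
        cand = default_evidence_table()[0]
        widths = {}
        for n, seed in ((90, 83), (360, 84)):
            ds = make_dataset(blocked_design, n, seed=seed, sd_scale=0.0)
            table = bootstrap_ci(
                ds,
                continuous_spec(ds.schema, n_draws=1, random=()),
                [cand],
                B=60,
                seed=3,
                n_draws=16,
            )
            widths[n] = float(table["ci_high"].iloc[0] - table["ci_low"].iloc[0])
        assert widths[360] < widths[90]

    def test_krinsky_robb_variant(self, blocked_design):
        ds = make_dataset(blocked_design, 60, seed=85)
        table = bootstrap_ci(
            ds,
            continuous_spec(ds.schema, n_draws=1, random=()),
            default_evidence_table()[:1],
            B=50,
            seed=4,
            n_draws=16,
            method="krinsky-robb",
        )
        row = table.iloc[0]
        assert row["ci_low"] < row["probability"] < row["ci_high"]

    def test_percentile_coverage_near_nominal(self, blocked_design):
        """Scaled-down coverage check: on zero-heterogeneity data the 95%
        respondent bootstrap CI covers the true selection probability at
        close to the nominal rate."""
        schema = blocked_design.schema
        params = default_population_params()
        truth_params = PopulationParams(
            mean=params.mean, sd={k: 0.0 for k in params.sd}, asc_optout=(-0.953, 0.0)
        )
        # true probability: continuous slopes implied by a linear fit to the
        # dummy means are unknown, so define truth by a very large sample fit
        big = make_dataset(blocked_design, 3000, seed=86, sd_scale=0.0)
        spec = continuous_spec(schema, n_draws=1, random=())
        big_fit = refit_continuous(big, spec)
        cand = default_evidence_table()[0]
        p_true = predict_selection_probability(big_fit, cand, n_draws=1)
        hits = 0
        reps = 24
        for r in range(reps):
            ds = make_dataset(blocked_design, 70, seed=900 + r, sd_scale=0.0)
            table = bootstrap_ci(ds, spec, [cand], B=40, seed=r, n_draws=1)
            row = table.iloc[0]
            hits += row["ci_low"] <= p_true <= row["ci_high"]
        # binomial(24, 0.95): >= 19 hits covers all but ~1% of outcomes
        assert hits >= 19
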
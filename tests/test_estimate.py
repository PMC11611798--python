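"""Mixed-logit estimation: oracle equivalences, invariances, recovery smoke.

The conditional-logit and Gauss-Hermite oracles below are written directly
against the long-format data frame, independently of the estimator's own
design-matrix machinery.
"""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from vaxchoice.estimate import (
    ASC_COLUMN,
    MixlFit,
    ModelSpec,
    RankDeficientError,
    add_interactions,
    fit_mixl,
    loglik_mixl,
    stability_check,
)
from vaxchoice.population import PopulationParams, default_population_params
from vaxchoice.simulate import simulate_choices, simulate_respondents

from conftest import ATTENTIVE_MIX, make_dataset


def row_utility(row, means, schema):
    """Utility of one long-format row under dummy coding (test-side oracle)."""
    if row["alternative"] == "optout":
        return means.get(ASC_COLUMN, 0.0)
    v = 0.0
    for attr in schema.attributes:
        for i in attr.non_reference_indices():
            lvl = attr.levels[i]
            if row[attr.name] == lvl:
                v += means.get(f"{attr.name}={lvl}", 0.0)
    return v


def conditional_logit_oracle(dataset, means, stage="unforced"):
    """Plain logit log-likelihood computed row by row from the data frame."""
    df = dataset.data[~dataset.data["is_repeat"]]
    if stage == "forced":
        df = df[df["alternative"] != "optout"]
    col = "chosen_forced" if stage == "forced" else "chosen_unforced"
    ll = 0.0
    for _, task in df.groupby(["respondent_id", "block_id", "position"]):
        v = np.array([row_utility(r, means, dataset.schema) for _, r in task.iterrows()])
        p = np.exp(v - v.max())
        p /= p.sum()
        ll += np.log(p[task[col].to_numpy() == 1][0])
    return ll


class TestLoglikOracles:
    def test_zero_sd_equals_conditional_logit(self, blocked_design):
        ds = make_dataset(blocked_design, 40, seed=51)
        rng = np.random.default_rng(0)
        spec = ModelSpec(n_draws=37)
        cols = [f"{a.name}={a.levels[i]}" for a in ds.schema.attributes
                for i in a.non_reference_indices()] + [ASC_COLUMN]
        means = {c: rng.normal(scale=0.4) for c in cols}
        theta = np.array([means[c] for c in cols] + [0.0] * len(cols))
        msl = loglik_mixl(theta, ds, spec)
        oracle = conditional_logit_oracle(ds, means)
        assert msl == pytest.approx(oracle, abs=1e-10)

    def test_forced_zero_beta_is_bernoulli(self, blocked_design):
        ds = make_dataset(blocked_design, 25, seed=52)
        spec = ModelSpec(stage="forced", include_optout_asc=False, n_draws=5)
        theta = np.zeros(13 * 2)  # 13 means + 13 sds
        n_tasks = 25 * 10
        assert loglik_mixl(theta, ds, spec) == pytest.approx(
            n_tasks * np.log(0.5), abs=1e-9
        )

    def test_single_random_coefficient_matches_gauss_hermite(self, blocked_design):
        """MSL at 2000 Halton draws vs adaptive quadrature, per respondent."""
        ds = make_dataset(blocked_design, 50, seed=53)
        schema = ds.schema
        rng = np.random.default_rng(1)
        cols = [f"{a.name}={a.levels[i]}" for a in schema.attributes
                for i in a.non_reference_indices()] + [ASC_COLUMN]
        means = {c: rng.normal(scale=0.3) for c in cols}
        s_eff = 0.9
        spec = ModelSpec(n_draws=2000, random=("effectiveness=90",))
        theta = np.array([means[c] for c in cols] + [s_eff])
        msl_ll = loglik_mixl(theta, ds, spec)

        # Gauss-Hermite oracle: integrate the panel product over the single
        # normal coefficient, respondent by respondent
        nodes, weights = np.polynomial.hermite.hermgauss(80)
        zs = np.sqrt(2.0) * nodes
        ws = weights / np.sqrt(np.pi)
        ll_oracle = 0.0
        df = ds.data[~ds.data["is_repeat"]]
        for _, resp in df.groupby("respondent_id"):
            panel = np.ones_like(zs)
            for _, task in resp.groupby("position"):
                v0 = np.array(
                    [row_utility(r, means, schema) for _, r in task.iterrows()]
                )
                bump = np.array(
                    [
                        float(r["alternative"] != "optout" and r["effectiveness"] == 90)
                        for _, r in task.iterrows()
                    ]
                )
                chosen = task["chosen_unforced"].to_numpy() == 1
                v = v0[None, :] + s_eff * zs[:, None] * bump[None, :]
                e = np.exp(v - v.max(axis=1, keepdims=True))
                panel *= e[:, chosen][:, 0] / e.sum(axis=1)
            ll_oracle += np.log(np.sum(ws * panel))
        n = df["respondent_id"].nunique()
        assert abs(msl_ll - ll_oracle) / n < 1e-3

    def test_sd_sign_not_identified(self, blocked_design):
        """The mixing distribution is even in each SD. With antithetic
        draws (the default) the draw set is mirror-closed, so flipping all
        SD signs leaves the simulated likelihood exactly unchanged; a
        single-coordinate flip under plain draws agrees in the draw limit."""
        ds = make_dataset(blocked_design, 30, seed=54)
        K = 14
        rng = np.random.default_rng(2)
        theta = rng.normal(scale=0.3, size=2 * K)
        flipped = theta.copy()
        flipped[K:] = -flipped[K:]
        spec = ModelSpec(n_draws=64)  # antithetic default, even draw count
        assert loglik_mixl(theta, ds, spec) == pytest.approx(
            loglik_mixl(flipped, ds, spec), abs=1e-9
        )
        one_flip = theta.copy()
        one_flip[K] = -one_flip[K]
        diffs = {}
        for R in (50, 2000):
            plain = ModelSpec(n_draws=R, antithetic=False, scramble=False)
            diffs[R] = abs(
                loglik_mixl(theta, ds, plain) - loglik_mixl(one_flip, ds, plain)
            )
        assert diffs[2000] < diffs[50]
        assert diffs[2000] / 30 < 5e-3  # per respondent


@pytest.fixture(scope="module")
def small_fit(small_attentive_dataset):
    return fit_mixl(small_attentive_dataset, ModelSpec(n_draws=100, seed=0))


class TestFitContracts:
    def test_likelihood_improves_on_warm_start(self, small_fit):
        assert small_fit.loglik >= small_fit.warm_start_loglik

    def test_covariance_is_symmetric_psd(self, small_fit):
        cov = small_fit.cov
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.linalg.eigvalsh(cov).min() > -1e-8

    def test_ci_bounds_ordered_and_finite(self, small_fit):
        summ = small_fit.summary()
        assert (summ["ci_low"] <= summ["ci_high"]).all()
        assert np.isfinite(small_fit.loglik)

    def test_abs_sds_nonnegative_raw_sds_signed(self, small_fit):
        assert all(v >= 0 for v in small_fit.abs_sds.values())
        assert set(small_fit.sds) == set(small_fit.random_names)

    def test_forced_fit_has_no_asc(self, small_attentive_dataset):
        fit = fit_mixl(
            small_attentive_dataset,
            ModelSpec(stage="forced", include_optout_asc=False, n_draws=50),
        )
        assert ASC_COLUMN not in fit.column_names

    def test_task_permutation_leaves_fit_unchanged(self, blocked_design):
        ds = make_dataset(blocked_design, 60, seed=55)
        spec = ModelSpec(n_draws=60)
        base = fit_mixl(ds, spec)
        shuffled = ds.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ds2 = type(ds)(data=shuffled, respondents=ds.respondents, schema=ds.schema)
        again = fit_mixl(ds2, spec)
        assert np.allclose(base.theta, again.theta, atol=1e-8)

    def test_conditional_logit_invariant_to_relabeling(self, blocked_design):
        ds = make_dataset(blocked_design, 40, seed=56)
        spec = ModelSpec(n_draws=1, random=())
        base = fit_mixl(ds, spec)
        relabeled = ds.data.copy()
        relabeled["respondent_id"] = 10_000 - relabeled["respondent_id"]
        resp = ds.respondents.copy()
        resp["id"] = 10_000 - resp["id"]
        ds2 = type(ds)(data=relabeled, respondents=resp, schema=ds.schema)
        again = fit_mixl(ds2, spec)
        assert np.allclose(sorted(base.theta), sorted(again.theta), atol=1e-8)
        assert base.loglik == pytest.approx(again.loglik, abs=1e-8)

    def test_zero_sd_truth_yields_small_sds_and_insignificant_lr(
        self, homogeneous_dataset
    ):
        fit = fit_mixl(homogeneous_dataset, ModelSpec(n_draws=100))
        lr = 2 * (fit.loglik - fit.warm_start_loglik)
        assert lr < chi2.ppf(0.95, df=len(fit.random_names))
        # weakly identified SDs (notably the opt-out constant's) wander at
        # this sample size; the bulk must still shrink toward zero
        sds = sorted(abs(v) for v in fit.abs_sds.values())
        assert np.median(sds) < 0.2
        assert max(sds) < 1.0


class TestStability:
    def test_degenerate_mixture_identical_across_grid(self, homogeneous_dataset):
        table = stability_check(
            homogeneous_dataset, ModelSpec(random=()), draw_grid=(10, 50, 100)
        )
        assert table["max_rel_change"].iloc[1] == pytest.approx(0.0, abs=1e-9)
        assert table["max_rel_change"].iloc[2] == pytest.approx(0.0, abs=1e-9)

    def test_changes_shrink_along_grid(self, blocked_design):
        """With well-identified heterogeneity (the three largest true SDs
        random, the rest fixed), estimates settle as draws increase."""
        ds = make_dataset(blocked_design, 250, seed=57)
        spec = ModelSpec(
            random=("effectiveness=90", "coverage=60", "asc_optout")
        )
        table = stability_check(ds, spec, draw_grid=(25, 100, 400))
        assert table["max_rel_change"].iloc[2] <= table["max_rel_change"].iloc[1]

    def test_length_one_grid_flagged(self, homogeneous_dataset):
        table = stability_check(
            homogeneous_dataset, ModelSpec(random=()), draw_grid=(20,)
        )
        assert len(table) == 1
        assert np.isnan(table["max_rel_change"].iloc[0])
        assert not table["stable"].iloc[0]

    def test_rejects_non_increasing_grid(self, homogeneous_dataset):
        with pytest.raises(ValueError):
            stability_check(homogeneous_dataset, ModelSpec(), draw_grid=(100, 50))


class TestInteractions:
    def test_product_coding(self, mixed_behavior_dataset):
        cols = add_interactions(
            mixed_behavior_dataset,
            mixed_behavior_dataset.respondents,
            [("eastern", "effectiveness=90")],
        )
        col = cols["eastern_x_effectiveness=90"]
        df = mixed_behavior_dataset.data
        eastern = (
            mixed_behavior_dataset.respondents.set_index("id")["eastern"]
        )
        expect = df["respondent_id"].map(eastern).to_numpy() * (
            df["effectiveness"] == 90
        ).to_numpy(float)
        assert np.array_equal(col.to_numpy(), expect)

    def test_missing_covariate_rejected(self, mixed_behavior_dataset):
        with pytest.raises(ValueError):
            add_interactions(
                mixed_behavior_dataset,
                mixed_behavior_dataset.respondents,
                [("no_such_covariate", "effectiveness=90")],
            )

    def test_all_zero_covariate_reported_as_aliased(self, small_attentive_dataset):
        resp = small_attentive_dataset.respondents.copy()
        resp["dead"] = 0
        ds = type(small_attentive_dataset)(
            data=small_attentive_dataset.data, respondents=resp,
            schema=small_attentive_dataset.schema,
        )
        spec = ModelSpec(n_draws=20, interactions=(("dead", "effectiveness=90"),))
        with pytest.raises(RankDeficientError) as err:
            fit_mixl(ds, spec)
        assert "dead_x_effectiveness=90" in err.value.aliased_columns

    def test_positive_interaction_effect_recovered(self, blocked_design):
        """A planted eastern x effectiveness-90 synergy is estimated with the
        correct sign at moderate sample size."""
        params = default_population_params()
        params = PopulationParams(
            mean=params.mean,
            sd={k: v * 0.5 for k, v in params.sd.items()},
            asc_optout=(-0.953, 1.0),
            interactions={("eastern", "effectiveness=90"): 0.8},
        )
        roster = simulate_respondents(
            500, params=params, behavior_mix=ATTENTIVE_MIX, seed=61
        )
        ds = simulate_choices(blocked_design, roster, params, seed=62)
        fit = fit_mixl(
            ds,
            ModelSpec(n_draws=100, interactions=(("eastern", "effectiveness=90"),)),
        )
        est = fit.means["eastern_x_effectiveness=90"]
        assert est > 0
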
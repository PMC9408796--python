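"""Graded-response model: design, probabilities, likelihood oracle, sampler."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from ghqlong import simulate
from ghqlong.grm import (
    GradedResponseModel,
    GRMParameterSet,
    ModelSpec,
    PosteriorDraws,
    _Posterior,
    build_design,
    category_probabilities,
    check_convergence,
    log_likelihood,
)
from ghqlong.hmc import sample_chains


class TestBuildDesign:
    def test_origin_date_gives_cos_one(self):
        persons = pd.DataFrame(
            {
                "person_id": [1],
                "sex": [1],
                "age": [40],
                "trip_return_date": ["2018-08-12"],
                "diarrhoea_trip": [0],
                "diarrhoea_after": [0],
            }
        )
        persons = pd.concat(
            [persons, persons.assign(person_id=2, age=30)], ignore_index=True
        )
        d = build_design(persons, n_waves=3, spec="m4")
        row = d.loc[(1, 0)]
        assert row["cos_t"] == pytest.approx(1.0)
        assert row["sin_t"] == pytest.approx(0.0)
        assert row["wave1"] == 0.0 and row["wave2"] == 0.0

    def test_wave_dummies_and_standardization(self, small_cohort, toy_design):
        d = toy_design
        assert abs(d["age_z"].groupby("person_id").first().mean()) < 1e-12
        w1 = d["wave1"].groupby("wave").mean()
        assert w1.loc[0] == 0 and w1.loc[1] == 1 and w1.loc[2] == 0
        # cyclic identity per row
        assert np.allclose(d["cos_t"] ** 2 + d["sin_t"] ** 2, 1.0)

    def test_date_before_origin_rejected(self):
        persons = pd.DataFrame(
            {
                "person_id": [1, 2],
                "sex": [1, 0],
                "age": [40, 30],
                "trip_return_date": ["2018-08-01", "2018-08-20"],
            }
        )
        with pytest.raises(ValueError, match="precede"):
            build_design(persons, 3, "m4")

    def test_m5_includes_interactions(self, small_cohort):
        d = build_design(small_cohort["persons"], 3, "m5")
        for col in ["wave1_cos", "wave2_cos", "wave1_sin", "wave2_sin"]:
            assert col in d.columns
        d_cos_only = build_design(
            small_cohort["persons"],
            3,
            ModelSpec("m5", include_sin_interactions=False),
        )
        assert "wave1_sin" not in d_cos_only.columns


class TestCategoryProbabilities:
    def test_normalization_and_symmetric_example(self):
        p = category_probabilities(0.0, 0.0, [-1.0, 0.0, 1.0])
        # logistic(-1), difference structure symmetric around zero
        e = expit(1.0)
        expected = [1 - e, e - 0.5, e - 0.5, 1 - e]
        assert np.allclose(p, expected, atol=1e-12)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(p, [0.26894, 0.23106, 0.23106, 0.26894], atol=1e-5)

    def test_eta_at_threshold_gives_half_cumulative(self):
        p = category_probabilities(0.5, 0.7, [-1.0, 0.5, 2.0])
        assert p[:2].sum() == pytest.approx(0.5, abs=1e-12)

    def test_monotone_in_eta(self):
        etas = np.linspace(-4, 4, 50)
        p = category_probabilities(etas, 0.2, [-1.0, 0.5, 2.0])
        for k in range(1, 4):
            tail = p[:, k:].sum(axis=1)
            assert np.all(np.diff(tail) > 0)

    def test_rejects_unordered_thresholds(self):
        with pytest.raises(ValueError):
            category_probabilities(0.0, 0.0, [1.0, 0.5, 2.0])


def _brute_force_loglik(params, responses, design):
    """Independent loop implementation of the GRM likelihood (oracle)."""
    total = 0.0
    item_row = {int(i): k for k, i in enumerate(params.item_ids)}
    for _, row in responses.dropna(subset=["response"]).iterrows():
        eta = params.theta[row["person_id"]]
        drow = design.loc[(row["person_id"], row["wave"])]
        for col, b in params.beta.items():
            eta += b * drow[col]
        k = item_row[int(row["item"])]
        a = np.exp(params.log_disc[k])
        tau = params.thresholds[k]
        y = int(row["response"])
        hi = 1.0 if y == 3 else 1.0 / (1.0 + np.exp(-a * (tau[y] - eta)))
        lo = 0.0 if y == 0 else 1.0 / (1.0 + np.exp(-a * (tau[y - 1] - eta)))
        total += np.log(hi - lo)
    return total


class TestLogLikelihood:
    def _toy(self, seed, n_persons=3, n_items=3):
        rng = np.random.default_rng(seed)
        persons = pd.DataFrame(
            {
                "person_id": np.arange(1, n_persons + 1),
                "sex": rng.integers(0, 2, n_persons),
                "age": rng.uniform(20, 60, n_persons),
                "t_days": rng.integers(0, 210, n_persons),
                "diarrhoea_trip": rng.integers(0, 2, n_persons),
                "diarrhoea_after": rng.integers(0, 2, n_persons),
            }
        )
        design = build_design(persons, 3, "m4")
        rows = []
        for pid in persons["person_id"]:
            for w in range(3):
                for item in range(1, n_items + 1):
                    rows.append(
                        {
                            "person_id": pid,
                            "wave": w,
                            "item": item,
                            "response": float(rng.integers(0, 4)),
                        }
                    )
        responses = pd.DataFrame(rows)
        thresholds = np.sort(rng.normal(0, 2, (n_items, 3)), axis=1)
        thresholds[:, 1:] += 0.1  # enforce strict ordering
        thresholds[:, 2] += 0.1
        params = GRMParameterSet(
            beta={c: rng.normal(0, 0.5) for c in design.columns},
            theta={pid: rng.normal() for pid in persons["person_id"]},
            log_disc=rng.normal(0, 0.3, n_items),
            thresholds=thresholds,
        )
        return params, responses, design

    def test_oracle_equivalence_many_toys(self):
        for seed in range(100):
            params, responses, design = self._toy(seed)
            total, pointwise = log_likelihood(params, responses, design)
            oracle = _brute_force_loglik(params, responses, design)
            assert total == pytest.approx(oracle, rel=1e-12)
            assert pointwise.sum() == pytest.approx(total, rel=1e-12)

    def test_additivity_and_missing(self):
        params, responses, design = self._toy(0)
        half = len(responses) // 2
        t1, _ = log_likelihood(params, responses.iloc[:half], design)
        t2, _ = log_likelihood(params, responses.iloc[half:], design)
        total, _ = log_likelihood(params, responses, design)
        assert t1 + t2 == pytest.approx(total, rel=1e-12)
        # missing rows contribute nothing
        with_missing = responses.copy()
        with_missing.loc[with_missing.index[:5], "response"] = np.nan
        tm, pw = log_likelihood(params, with_missing, design)
        tr, _ = log_likelihood(params, responses.iloc[5:], design)
        assert tm == pytest.approx(tr, rel=1e-12)

    def test_single_observation_matches_category_probability(self):
        params, responses, design = self._toy(1)
        one = responses.iloc[[0]]
        total, _ = log_likelihood(params, one, design)
        row = one.iloc[0]
        eta = params.theta[row["person_id"]] + sum(
            params.beta[c] * design.loc[(row["person_id"], row["wave"]), c]
            for c in design.columns
        )
        k = int(row["item"]) - 1
        p = category_probabilities(eta, params.log_disc[k], params.thresholds[k])
        assert total == pytest.approx(np.log(p[int(row["response"])]), rel=1e-12)

    def test_invalid_category_rejected(self):
        params, responses, design = self._toy(2)
        responses.loc[0, "response"] = 7.0
        with pytest.raises(ValueError):
            log_likelihood(params, responses, design)


class TestPosteriorGradient:
    @pytest.mark.parametrize("variant", ["m1", "m4"])
    def test_gradient_matches_finite_differences(self, small_cohort, variant):
        spec = ModelSpec(variant)
        persons = small_cohort["persons"]
        design = build_design(persons, 3, spec)
        obs = small_cohort["complete"].dropna(subset=["response"])
        ppos = {p: k for k, p in enumerate(persons["person_id"])}
        ipos = {int(i): k for k, i in enumerate(sorted(obs["item"].unique()))}
        row = design.index.get_indexer(
            pd.MultiIndex.from_arrays([obs["person_id"], obs["wave"]])
        )
        post = _Posterior(
            design.to_numpy(float),
            row,
            obs["person_id"].map(ppos).to_numpy(int),
            obs["item"].astype(int).map(ipos).to_numpy(int),
            obs["response"].to_numpy(int),
            len(persons),
            12,
            spec.shared_thresholds,
        )
        rng = np.random.default_rng(7)
        q = post.initial(rng)
        _, g = post.logp_grad(q)
        eps = 1e-6
        for i in rng.choice(post.dim, size=20, replace=False):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            num = (post.logp_grad(qp)[0] - post.logp_grad(qm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(num, rel=1e-4, abs=1e-6)


class TestSampler:
    def test_recovers_correlated_gaussian(self):
        cov = np.array([[1.0, 0.6], [0.6, 2.0]])
        prec = np.linalg.inv(cov)

        def logp_grad(q):
            return -0.5 * q @ prec @ q, -prec @ q

        draws, stats = sample_chains(
            logp_grad,
            lambda rng: rng.standard_normal(2),
            n_chains=2,
            n_warmup=500,
            n_draws=1500,
            seed=0,
        )
        flat = draws.reshape(-1, 2)
        assert np.allclose(flat.mean(axis=0), 0.0, atol=0.12)
        assert np.allclose(np.cov(flat.T), cov, atol=0.25)
        pdraws = PosteriorDraws(params={"x": draws})
        report = check_convergence(pdraws)
        assert report.passed


class TestCheckConvergence:
    def _draws_from(self, chains):
        return PosteriorDraws(params={"x": np.asarray(chains)})

    def test_well_mixed_chains_pass(self):
        rng = np.random.default_rng(0)
        d = self._draws_from(rng.standard_normal((2, 1000)))
        report = check_convergence(d)
        assert report.passed
        assert 0.99 <= report.rhat_max_observed <= 1.02

    def test_separated_chains_fail(self):
        rng = np.random.default_rng(1)
        chains = np.stack(
            [rng.standard_normal(500), 100.0 + rng.standard_normal(500)]
        )
        report = check_convergence(self._draws_from(chains))
        assert not report.passed
        assert "x" in report.offending

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError, match="two chains"):
            check_convergence(self._draws_from(np.zeros((1, 100))))

    def test_threshold_is_strict(self):
        # construct draws and check the gate against their actual R-hat
        rng = np.random.default_rng(2)
        sep = 0.19  # mild separation puts R-hat just above 1.05
        chains = np.stack(
            [rng.standard_normal(400) - sep, rng.standard_normal(400) + sep]
        )
        d = self._draws_from(chains)
        report = check_convergence(d, rhat_max=1.05)
        r = float(np.atleast_1d(d.rhat["x"])[0])
        assert report.passed == (r < 1.05)
        assert check_convergence(d, rhat_max=r + 1e-9).passed
        assert not check_convergence(d, rhat_max=r - 1e-9).passed


class TestFitContract:
    def test_fit_outputs_and_diagnostics(self, m1_fit_small):
        model = m1_fit_small
        draws = model.draws_
        for name in [
            "b_sex2",
            "b_wave1",
            "b_wave2",
            "theta",
            "disc_intercept",
            "sd_disc",
            "sd_threshold",
            "cor_disc_thr",
            "thresholds_shared",
        ]:
            assert name in draws.params
            assert name in draws.rhat  # every parameter carries a diagnostic
            assert name in draws.ess
            assert np.all(np.isfinite(draws.params[name]))
        assert draws.params["b_wave1"].shape == (2, 250)
        # ordered thresholds in every draw
        assert np.all(np.diff(draws.params["thresholds_shared"], axis=-1) > 0)
        assert np.all(draws.params["sd_disc"] > 0)
        assert np.all(np.abs(draws.params["cor_disc_thr"]) <= 1)

    def test_fit_determinism(self, small_cohort):
        kw = dict(variant="m3", chains=2, warmup=60, draws=60, seed=11)
        a = GradedResponseModel(**kw).fit(
            small_cohort["complete"], small_cohort["persons"]
        )
        b = GradedResponseModel(**kw).fit(
            small_cohort["complete"], small_cohort["persons"]
        )
        np.testing.assert_array_equal(
            a.draws_.params["b_wave1"], b.draws_.params["b_wave1"]
        )

    def test_theta_scale_near_unit(self, m1_fit_small):
        # identification: person intercepts are standard normal a priori and
        # their posterior spread should stay near unit scale
        theta = m1_fit_small.draws_.stacked("theta")
        assert 0.6 < theta.std() < 1.4

    def test_invalid_inputs(self, small_cohort):
        model = GradedResponseModel(variant="m4", chains=2, warmup=10, draws=10)
        bad = small_cohort["complete"].copy()
        bad["response"] = 5.0
        with pytest.raises(ValueError):
            model.fit(bad, small_cohort["persons"])
        with pytest.raises(ValueError):
            ModelSpec("m9")

    def test_sklearn_params_roundtrip(self):
        model = GradedResponseModel(variant="m3", draws=50)
        params = model.get_params()
        assert params["variant"] == "m3"
        model.set_params(draws=77)
        assert model.draws == 77

    def test_uninformative_covariate_posterior_follows_prior(self, small_cohort):
        # a covariate that is identically zero carries no information; its
        # coefficient's posterior should stay close to the Normal(0, 5) prior
        persons = small_cohort["persons"].copy()
        persons["diarrhoea_after"] = 0
        model = GradedResponseModel(
            variant="m4", chains=2, warmup=300, draws=300, seed=13
        )
        model.fit(small_cohort["complete"], persons)
        d = model.draws_.stacked("b_diarrhoea_after")
        assert abs(d.mean()) < 1.0
        assert abs(d.std() - 5.0) < 0.2 * 5.0


def test_shared_and_item_threshold_models_agree_without_item_shifts():
    """When items genuinely share thresholds (shift variance zero), the
    shared-threshold and item-specific-threshold fits give the same wave
    coefficient up to posterior spread."""
    from ghqlong import simulate

    cfg = simulate.CohortConfig(n_persons=90, seed=71)
    items = simulate.draw_item_parameters(n_items=12, re_sd_thr=0.0, seed=72)
    persons, _, _, observed = simulate.simulate_study(cfg, items=items)
    means, sds = {}, {}
    for variant in ("m1", "m3"):
        model = GradedResponseModel(
            variant=variant, chains=2, warmup=250, draws=250, seed=73
        )
        model.fit(observed, persons)
        d = model.draws_.stacked("b_wave1")
        means[variant], sds[variant] = d.mean(), d.std()
    pooled_sd = np.sqrt(sds["m1"] ** 2 + sds["m3"] ** 2)
    assert abs(means["m1"] - means["m3"]) < 2 * pooled_sd
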
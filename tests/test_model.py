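import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

import patchchoice as pc
from patchchoice.domain import DomainError, TripRecord
from patchchoice.model import (
    ModelLayout,
    ModelParams,
    PriorConfig,
    build_design,
    choice_loglik,
    gp_age_cov,
    joint_log_density,
    linear_predictor_choice,
    log_prior,
    sample_params_from_prior,
    softmax_probs,
    success_loglik,
    success_prob,
)


def _record(**kw):
    base = dict(
        trip_id="t1", harvester_id="h1", household_id="hh1", gender="man",
        age_class="30to40", season="ice", patch="winter_marine", success=1,
        group_size=3, income=50.0, in_degree=4, out_degree=4,
        income_std=0.2, in_degree_std=-0.5, out_degree_std=1.1, group_size_std=0.0,
    )
    base.update(kw)
    return TripRecord(**base)


class TestSoftmax:
    def test_uniform_at_zero(self):
        p = softmax_probs(np.zeros(7))
        np.testing.assert_allclose(p, np.full(7, 1 / 7), atol=1e-15)

    def test_hand_normalized_example(self):
        p = softmax_probs(np.array([np.log(2), 0, 0, 0, 0, 0, 0]))
        np.testing.assert_allclose(p, [2 / 8] + [1 / 8] * 6, atol=1e-14)

    def test_shift_invariance(self):
        eta = np.array([0.3, -1.2, 2.0, 0.0, 5.0, -3.0, 1.1])
        np.testing.assert_allclose(softmax_probs(eta), softmax_probs(eta + 123.4), atol=1e-12)

    def test_masked_patches_exactly_zero(self):
        mask = np.array([True, False, True, True, False, True, True])
        p = softmax_probs(np.zeros(7), mask)
        assert (p[~mask] == 0.0).all()
        np.testing.assert_allclose(p[mask], 1 / 5, atol=1e-14)

    def test_empty_mask_rejected(self):
        with pytest.raises(DomainError, match="mask excludes"):
            softmax_probs(np.zeros(7), np.zeros(7, bool))

    def test_sums_to_one_and_stable_for_large_eta(self):
        rng = np.random.default_rng(0)
        eta = rng.uniform(-700, 700, size=(10_000, 7))
        p = softmax_probs(eta)
        assert np.isfinite(p).all()
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestLinearPredictorChoice:
    def test_zero_params(self, catalog):
        params = ModelParams.zeros(ModelLayout.default(catalog))
        np.testing.assert_array_equal(linear_predictor_choice(_record(), params), np.zeros(7))

    def test_single_intercept_term(self, catalog):
        layout = ModelLayout.default(catalog)
        params = ModelParams.zeros(layout)
        params.alpha_choice[2, layout.seasons.index("ice")] = 1.5
        eta = linear_predictor_choice(_record(season="ice"), params)
        expected = np.zeros(7)
        expected[2] = 1.5
        np.testing.assert_array_equal(eta, expected)

    def test_matches_hand_computed_sum(self, random_params):
        """Independent re-implementation: explicit per-patch summation."""
        rec = _record()
        layout = random_params.layout
        s = layout.seasons.index(rec.season)
        g = layout.genders.index(rec.gender)
        a = layout.age_classes.index(rec.age_class)
        x = {"income_std": rec.income_std, "in_degree_std": rec.in_degree_std,
             "out_degree_std": rec.out_degree_std, "group_size_std": rec.group_size_std}
        expected = np.empty(7)
        for k in range(7):
            val = random_params.alpha_choice[k, s] + random_params.gamma_choice[k, g]
            val += random_params.age_effect_choice[k, a]
            for c, name in enumerate(layout.choice_covariates):
                val += random_params.beta_choice[k, c] * x[name]
            expected[k] = val
        np.testing.assert_allclose(linear_predictor_choice(rec, random_params), expected, atol=1e-12)

    def test_missing_income_without_latent_rejected(self, catalog):
        params = ModelParams.zeros(ModelLayout.default(catalog))
        with pytest.raises(DomainError, match="imputation latent"):
            linear_predictor_choice(_record(income_std=float("nan")), params)


class TestChoiceLoglik:
    def test_uniform_single_trip(self, std_fixture, catalog):
        std, _, _ = std_fixture
        layout = ModelLayout.default(catalog, impute_income=True)
        params = ModelParams.zeros(layout)
        one = pc.TripTable(std.df.iloc[[0]], catalog, validate=False)
        assert choice_loglik(one, params) == pytest.approx(np.log(1 / 7))

    def test_additive_over_identical_trips(self, std_fixture, catalog, random_params):
        std, _, _ = std_fixture
        row = std.df.iloc[[4]]
        rep = pc.TripTable(
            __import__("pandas").concat([row] * 6).assign(trip_id=[f"r{i}" for i in range(6)]),
            catalog, validate=False,
        )
        params = _bind_latent(random_params)
        single = choice_loglik(pc.TripTable(row, catalog, validate=False), params)
        assert choice_loglik(rep, params) == pytest.approx(6 * single, rel=1e-12)

    def test_brute_force_oracle(self, std_fixture, catalog, random_params):
        """Per-row categorical log-pmf computed independently from the frame."""
        std, _, _ = std_fixture
        sub = pc.TripTable(std.df.iloc[:50], catalog, validate=False)
        params = _bind_latent(random_params)
        layout = params.layout
        total = 0.0
        for rec in sub:
            x = {"income_std": rec.income_std if not np.isnan(rec.income_std) else params.income_miss,
                 "in_degree_std": rec.in_degree_std, "out_degree_std": rec.out_degree_std,
                 "group_size_std": rec.group_size_std}
            s, g = layout.seasons.index(rec.season), layout.genders.index(rec.gender)
            a = layout.age_classes.index(rec.age_class)
            eta = np.array([
                params.alpha_choice[k, s] + params.gamma_choice[k, g]
                + params.age_effect_choice[k, a]
                + sum(params.beta_choice[k, c] * x[n] for c, n in enumerate(layout.choice_covariates))
                for k in range(7)
            ])
            probs = np.exp(eta) / np.exp(eta).sum()
            total += np.log(probs[layout.patches.index(rec.patch)])
        assert choice_loglik(sub, params) == pytest.approx(total, abs=1e-10)

    def test_observed_masked_patch_rejected(self, std_fixture, catalog):
        std, _, _ = std_fixture
        layout = ModelLayout.default(catalog, impute_income=True)
        params = ModelParams.zeros(layout)
        mask = np.ones(7, bool)
        mask[layout.patches.index(std.df["patch"].iloc[0])] = False
        with pytest.raises(DomainError, match="excluded"):
            choice_loglik(pc.TripTable(std.df.iloc[[0]], catalog, validate=False), params, mask=mask)


def _bind_latent(params):
    """Give the random full-model params an imputation latent for fixture data."""
    import copy

    p = copy.deepcopy(params)
    if p.layout.impute_income:
        return p
    from dataclasses import replace as dc_replace

    layout = dc_replace(p.layout, impute_income=True)
    p2 = ModelParams.zeros(layout)
    for name in ("alpha_choice", "gamma_choice", "beta_choice", "age_effect_choice", "gp_choice",
                 "alpha_succ", "gamma_succ", "beta_succ", "age_effect_succ", "gp_succ"):
        setattr(p2, name, getattr(p, name).copy())
    p2.income_mu, p2.income_sigma, p2.income_miss = 0.5, 1.0, 0.3
    return p2


class TestGpAgeCov:
    def test_limits(self):
        K = gp_age_cov(1.0, 1e12, 0.25)
        np.testing.assert_allclose(K, np.diag([1.25] * 4), atol=1e-12)
        K0 = gp_age_cov(1.0, 0.0, 0.25)
        np.testing.assert_allclose(K0, np.ones((4, 4)) + np.diag([0.25] * 4), atol=1e-12)

    def test_formula_value(self):
        K = gp_age_cov(2.0, 0.5, 0.1)
        assert K[0, 1] == pytest.approx(2.0 * np.exp(-0.5), abs=1e-10)
        assert K[0, 0] == pytest.approx(2.1)
        assert K[0, 3] == pytest.approx(2.0 * np.exp(-0.5 * 9), abs=1e-12)

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(DomainError):
            gp_age_cov(-1.0, 0.5, 0.1)
        with pytest.raises(DomainError):
            gp_age_cov(1.0, 0.5, 0.0)

    def test_cholesky_factorizable_for_random_hyperparameters(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            eta2, rho2, sig2 = rng.lognormal(0, 1.5, size=3)
            L = np.linalg.cholesky(gp_age_cov(eta2, rho2, sig2))
            assert np.isfinite(L).all()


class TestSuccessModel:
    def test_half_at_zero(self, catalog):
        params = ModelParams.zeros(ModelLayout.default(catalog))
        assert success_prob(_record(), params) == 0.5

    def test_intercept_maps_through_logit(self, catalog):
        layout = ModelLayout.default(catalog)
        params = ModelParams.zeros(layout)
        k = layout.patches.index("winter_marine")
        params.alpha_succ[k, :] = logit(0.225)
        assert success_prob(_record(patch="winter_marine"), params) == pytest.approx(0.225)

    def test_negating_params_flips_probability(self, random_params):
        import copy

        rec = _record()
        p = copy.deepcopy(random_params)
        n = copy.deepcopy(random_params)
        for name in ("alpha_succ", "gamma_succ", "beta_succ", "age_effect_succ"):
            setattr(n, name, -getattr(n, name))
        assert success_prob(rec, n) == pytest.approx(1 - success_prob(rec, p), abs=1e-12)

    def test_single_trip_loglik(self, std_fixture, catalog):
        std, _, _ = std_fixture
        params = ModelParams.zeros(ModelLayout.default(catalog, impute_income=True))
        row = std.df.iloc[[0]].copy()
        row["success"] = 1
        assert success_loglik(pc.TripTable(row, catalog, validate=False), params) == pytest.approx(np.log(0.5))

    def test_brute_force_oracle(self, std_fixture, catalog, random_params):
        std, _, _ = std_fixture
        sub = pc.TripTable(std.df.iloc[:50], catalog, validate=False)
        params = _bind_latent(random_params)
        layout = params.layout
        total = 0.0
        for rec in sub:
            x = {"income_std": rec.income_std if not np.isnan(rec.income_std) else params.income_miss,
                 "in_degree_std": rec.in_degree_std, "out_degree_std": rec.out_degree_std,
                 "group_size_std": rec.group_size_std}
            k = layout.patches.index(rec.patch)
            s, g = layout.seasons.index(rec.season), layout.genders.index(rec.gender)
            a = layout.age_classes.index(rec.age_class)
            theta = params.alpha_succ[k, s] + params.gamma_succ[k, g] + params.age_effect_succ[a]
            theta += sum(params.beta_succ[c] * x[n] for c, n in enumerate(layout.success_covariates))
            p = expit(theta)
            total += np.log(p) if rec.success else np.log1p(-p)
        assert success_loglik(sub, params) == pytest.approx(total, abs=1e-10)

    def test_finite_for_extreme_linear_predictor(self, std_fixture, catalog):
        std, _, _ = std_fixture
        layout = ModelLayout.default(catalog, impute_income=True)
        params = ModelParams.zeros(layout)
        params.alpha_succ[:, :] = 35.0
        ll = success_loglik(pc.TripTable(std.df.iloc[:10], catalog, validate=False), params)
        assert np.isfinite(ll)


class TestPriorsAndJoint:
    def test_standard_normal_block_closed_form(self):
        from patchchoice.domain import Patch, PatchCatalog

        cat = PatchCatalog(patches=(Patch("a", "ice"), Patch("b", "ice")))
        layout = ModelLayout(patches=cat.names, seasons=("ice", "ice_free"), genders=(),
                             age_classes=(), choice_covariates=(), success_covariates=(),
                             include_success=False)
        params = ModelParams.zeros(layout)
        m = layout.n_params  # 4 intercepts
        assert log_prior(params, PriorConfig.default()) == pytest.approx(-(m / 2) * np.log(2 * np.pi))

    def test_income_mu_mode_contribution(self, catalog):
        layout = ModelLayout.default(catalog, impute_income=True)
        at_mode = ModelParams.zeros(layout)
        at_mode.income_mu = 0.5
        at_mode.income_miss = 0.5
        off = ModelParams.zeros(layout)
        off.income_mu = 1.5
        off.income_miss = 1.5
        pri = PriorConfig.default()
        # moving the hyper-mean one prior sd off its Normal(0.5, 1) mode costs 1/2 nat
        assert log_prior(at_mode, pri) - log_prior(off, pri) == pytest.approx(0.5)

    def test_negative_scale_is_out_of_support(self, catalog):
        layout = ModelLayout.default(catalog, impute_income=True)
        params = ModelParams.zeros(layout)
        params.gp_choice = np.array([1.0, 1.0, -0.5])
        assert log_prior(params, PriorConfig.default()) == -np.inf

    def test_joint_density_additivity(self, std_fixture, catalog, random_params):
        std, _, _ = std_fixture
        params = _bind_latent(random_params)
        sub = pc.TripTable(std.df.iloc[:40], catalog, validate=False)
        pri = PriorConfig.default()
        expected = log_prior(params, pri) + choice_loglik(sub, params) + success_loglik(sub, params)
        assert joint_log_density(sub, params, pri) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None)
    def test_pack_unpack_round_trip(self, seed):
        layout = ModelLayout.default(impute_income=True)
        rng = np.random.default_rng(seed)
        params = sample_params_from_prior(PriorConfig.default(), layout, rng)
        vec = params.pack()
        back = ModelParams.unpack(vec, layout)
        np.testing.assert_allclose(back.pack(), vec, rtol=1e-12)
        np.testing.assert_allclose(back.alpha_choice, params.alpha_choice)
        np.testing.assert_allclose(back.gp_succ, params.gp_succ, rtol=1e-12)
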
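import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import multivariate_normal

from erpdcm.compare import (
    bma,
    compare_modulations,
    coupling_trajectory,
    enumerate_reduced_models,
    model_posterior,
    parametric_design,
    reduce,
    reduced_prior_for_pattern,
)
from erpdcm.laplace import GaussianBelief, invert, invert_erp
from erpdcm.network import ModelParameters
from erpdcm.synth import generate_dataset

from conftest import make_linear_problem


class TestModelSpace:
    def test_four_effects_give_sixteen_models(self):
        space = enumerate_reduced_models(["b1", "b2", "b3", "b4"])
        assert space.n_models == 16
        assert len(set(space.patterns)) == 16

    def test_one_effect_gives_two_models(self):
        assert enumerate_reduced_models(["b1"]).n_models == 2

    def test_binary_counting_order(self):
        space = enumerate_reduced_models(["e1", "e2", "e3"])
        assert space.patterns[0] == (0, 0, 0)
        assert space.patterns[1] == (1, 0, 0)  # effect 1 = least significant
        assert space.patterns[-1] == (1, 1, 1)
        assert space.full_model_index == 7

    def test_guard_against_explosion(self):
        with pytest.raises(ValueError):
            enumerate_reduced_models([])
        with pytest.raises(ValueError):
            enumerate_reduced_models([f"e{i}" for i in range(21)])


def _linear_evidence(y, X, m0, S0, sigma2):
    return float(multivariate_normal.logpdf(
        y, X @ m0, sigma2 * np.eye(len(y)) + X @ S0 @ X.T))


class TestReduce:
    def test_identity_reduction_is_exact_zero(self, linear_problem):
        y, X, prior, lam, m_post, Sig, _ = linear_problem
        post = GaussianBelief(prior.names, m_post, Sig)
        dF, reduced = reduce(post, prior, prior)
        assert dF == 0.0
        assert np.array_equal(reduced.mean, post.mean)

    def test_matches_closed_form_evidence_difference(self, linear_problem):
        # independent oracle: both evidences in closed conjugate form
        y, X, prior, lam, m_post, Sig, logZ_full = linear_problem
        sigma2 = 1.0 / np.exp(lam)
        post = GaussianBelief(prior.names, m_post, Sig)
        r_prior = prior.copy()
        i = 1
        r_prior.mean[i] = 0.0
        r_prior.cov[i, :] = 0.0
        r_prior.cov[:, i] = 0.0
        r_prior.cov[i, i] = 1e-8
        dF, r_post = reduce(post, prior, r_prior)
        logZ_red = _linear_evidence(y, X, r_prior.mean, r_prior.cov, sigma2)
        assert abs(dF - (logZ_red - logZ_full)) / abs(logZ_full) < 1e-6
        # reduced posterior pins the removed coefficient at ~0
        assert abs(r_post.mean[i]) < 1e-4

    def test_matches_direct_reinversion_linear(self, linear_problem):
        y, X, prior, lam, m_post, Sig, logZ_full = linear_problem
        post = GaussianBelief(prior.names, m_post, Sig)
        r_prior = reduced_prior_for_pattern(prior, [prior.names[0]], [0])
        dF_bmr, _ = reduce(post, prior, r_prior)
        fwd = lambda Th: Th @ X.T
        res_full = invert(y, fwd, prior, fix_noise=True, noise_prior=(lam, 1e-8))
        res_red = invert(y, fwd, r_prior, fix_noise=True, noise_prior=(lam, 1e-8))
        assert abs(dF_bmr - (res_red.free_energy - res_full.free_energy)) < 1e-6

    def test_occams_effect_on_truly_zero_coefficient(self):
        # removing a coefficient whose true value is zero should gain
        # evidence on average (complexity saving beats accuracy loss)
        dFs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((30, 3))
            beta = np.array([0.8, 0.0, -0.5])  # middle coefficient inert
            y = X @ beta + rng.normal(0, 0.5, 30)
            prior = GaussianBelief(("b0", "b1", "b2"), np.zeros(3), np.eye(3))
            lam = np.log(1 / 0.25)
            res = invert(y, lambda Th: Th @ X.T, prior, fix_noise=True,
                         noise_prior=(lam, 1e-8))
            rp = reduced_prior_for_pattern(prior, ["b1"], [0])
            dF, _ = reduce(res.posterior, prior, rp)
            dFs.append(dF)
        assert np.mean(dFs) > 0

    def test_bmr_close_to_reinversion_on_cmc_fixture(self, spec, scenario):
        # nonlinear forward model: BMR is approximate but must stay within
        # 0.5 nats of brute-force re-inversion under the reduced prior
        _, true_params, _ = scenario
        data, _ = generate_dataset(spec, true_params, snr_db=20.0, seed=5)
        base = ModelParameters(spec=spec)
        res_full = invert_erp(data, spec, base, max_iter=48)
        rp = reduced_prior_for_pattern(res_full.prior, ["b[1:rTPJ->lFEF]"], [0])
        dF_bmr, _ = reduce(res_full.posterior, res_full.prior, rp)
        res_red = invert_erp(data, spec, base, prior=rp, max_iter=48)
        dF_direct = res_red.free_energy - res_full.free_energy
        assert abs(dF_bmr - dF_direct) <= 0.5

    def test_mismatched_names_fail(self, linear_problem):
        _, _, prior, _, m_post, Sig, _ = linear_problem
        post = GaussianBelief(("x", "y", "z"), m_post, Sig)
        with pytest.raises(ValueError):
            reduce(post, prior, prior)


class TestModelPosterior:
    def test_symmetry(self):
        assert np.allclose(model_posterior([0.0, 0.0]), [0.5, 0.5])

    def test_closed_form(self):
        assert np.allclose(model_posterior([np.log(3.0), 0.0]), [0.75, 0.25])

    def test_prior_model_probabilities(self):
        p = model_posterior([0.0, 0.0], [0.9, 0.1])
        assert np.allclose(p, [0.9, 0.1])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-500, 500), min_size=1, max_size=20))
    def test_normalisation_and_overflow_safety(self, F):
        p = model_posterior(F)
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_empty_fails(self):
        with pytest.raises(ValueError):
            model_posterior([])


class TestBma:
    def test_single_model_identity(self):
        q = GaussianBelief(("a",), np.array([0.7]), np.array([[2.0]]))
        avg = bma([q], [1.0])
        assert np.allclose(avg.mean, q.mean)
        assert np.allclose(avg.cov, q.cov)

    def test_identical_posteriors(self):
        q = GaussianBelief(("a", "b"), np.array([1.0, -1.0]), np.eye(2))
        avg = bma([q, q], [0.5, 0.5])
        assert np.allclose(avg.mean, q.mean)
        assert np.allclose(avg.cov, q.cov)

    def test_two_point_mixture_moment_matching(self):
        # means +-1, unit variances, equal weights: mixture variance = 2
        qa = GaussianBelief(("a",), np.array([1.0]), np.eye(1))
        qb = GaussianBelief(("a",), np.array([-1.0]), np.eye(1))
        avg = bma([qa, qb], [0.5, 0.5])
        assert np.allclose(avg.mean, 0.0)
        assert np.allclose(avg.cov, [[2.0]])
        # Monte-Carlo cross-check of the same mixture
        rng = np.random.default_rng(0)
        comp = rng.integers(0, 2, 200_000)
        draws = rng.normal(np.where(comp, 1.0, -1.0), 1.0)
        assert abs(draws.var() - 2.0) < 0.02

    def test_invalid_probabilities(self):
        q = GaussianBelief(("a",), np.zeros(1), np.eye(1))
        with pytest.raises(ValueError):
            bma([q, q], [0.7, 0.7])


class TestParametricDesign:
    def test_sixteen_events(self):
        assert np.array_equal(parametric_design(16), np.arange(16.0))

    def test_two_events_recover_contrast(self):
        assert np.array_equal(parametric_design(2), [0.0, 1.0])

    def test_baseline_convention(self):
        for n in (2, 5, 16):
            assert parametric_design(n)[0] == 0.0

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            parametric_design(1)


class TestCouplingTrajectory:
    def test_starts_at_hundred_percent(self):
        for b in (-0.3, 0.0, 0.4):
            assert coupling_trajectory(b, 0) == 100.0

    def test_no_slope_stays_flat(self):
        assert np.allclose(coupling_trajectory(0.0, np.arange(16)), 100.0)

    def test_monoexponential_value(self):
        assert np.isclose(coupling_trajectory(-0.05, 15),
                          100.0 * np.exp(-0.75))

    def test_negative_index_fails(self):
        with pytest.raises(ValueError):
            coupling_trajectory(0.1, -1)


class TestCompareModulations:
    def test_probabilities_sum_to_one(self, linear_problem):
        y, X, prior, lam, m_post, Sig, _ = linear_problem
        post = GaussianBelief(prior.names, m_post, Sig)
        result = compare_modulations(post, prior, list(prior.names))
        assert result.space.n_models == 8
        assert abs(result.probabilities.sum() - 1.0) < 1e-12
        assert np.all(result.probabilities >= 0)

    def test_full_model_delta_f_is_zero(self, linear_problem):
        y, X, prior, lam, m_post, Sig, _ = linear_problem
        post = GaussianBelief(prior.names, m_post, Sig)
        result = compare_modulations(post, prior, list(prior.names))
        assert result.delta_F[result.space.full_model_index] == 0.0

    def test_table_shape(self, linear_problem):
        _, _, prior, _, m_post, Sig, _ = linear_problem
        post = GaussianBelief(prior.names, m_post, Sig)
        tbl = compare_modulations(post, prior, list(prior.names)).table()
        assert list(tbl.columns) == ["model", "kept_effects", "delta_F",
                                     "probability"]
        assert len(tbl) == 8
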
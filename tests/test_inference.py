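import numpy as np
import pytest

from optibias.inference import infer_states, marginal_free_energy
from optibias.model import one_hot, softmax, stable_log

from .oracles import bayes_posterior, free_energy_reference


class TestSingleTimestep:
    def test_deterministic_likelihood_dominates(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2))
        belief = infer_states(model, [[one_hot(0, 2)]])
        assert np.allclose(belief.s[0], [1.0, 0.0], atol=1e-6)

    def test_flat_likelihood_returns_prior(self, single_factor_model_factory):
        model = single_factor_model_factory([0.7, 0.3], np.full((2, 2), 0.5))
        belief = infer_states(model, [[one_hot(0, 2)]])
        assert np.allclose(belief.s[0], [0.7, 0.3], atol=1e-6)

    def test_matches_exact_bayes_on_fixed_example(self, single_factor_model_factory):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        model = single_factor_model_factory([0.5, 0.5], A)
        belief = infer_states(model, [[one_hot(0, 2)]])
        expected = bayes_posterior([0.5, 0.5], A, 0)
        assert np.allclose(expected, [8 / 11, 3 / 11])
        assert np.allclose(belief.s[0], expected, atol=1e-3)

    def test_matches_exact_bayes_on_random_models(self, rng, random_model_factory):
        for _ in range(50):
            model = random_model_factory(rng)
            n_out = model.modality(0).n_outcomes
            obs = one_hot(int(rng.integers(n_out)), n_out)
            belief = infer_states(model, [[obs]])
            oracle = bayes_posterior(model.joint_prior(), model.joint_likelihood(0), int(obs.argmax()))
            assert np.allclose(belief.s[0], oracle, atol=1e-3)

    def test_iteration_budget_respected(self, random_model_factory, rng):
        model = random_model_factory(rng)
        belief = infer_states(model, [[one_hot(0, model.modality(0).n_outcomes)]])
        assert 1 <= belief.iterations <= 16

    def test_max_iterations_validated(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2))
        with pytest.raises(ValueError):
            infer_states(model, [[one_hot(0, 2)]], max_iterations=0)


class TestObservationHandling:
    def test_soft_observations_supported(self, single_factor_model_factory):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        model = single_factor_model_factory([0.5, 0.5], A)
        soft = np.array([0.9, 0.1])
        belief = infer_states(model, [[soft]])
        # fixed point: softmax(ln A^T o + ln D)
        expected = softmax(stable_log(A).T @ soft + stable_log([0.5, 0.5]))
        assert np.allclose(belief.s[0], expected, atol=1e-6)

    def test_wrong_observation_length_rejected(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2))
        with pytest.raises(ValueError, match="match"):
            infer_states(model, [[np.array([1.0, 0.0, 0.0])]])

    def test_unobserved_future_timestep_is_prediction(self, single_factor_model_factory):
        B = np.array([[0.9, 0.2], [0.1, 0.8]])[:, :, None]
        model = single_factor_model_factory([0.5, 0.5], np.eye(2), horizon=2, B=B)
        belief = infer_states(model, [[one_hot(0, 2)], None])
        assert np.allclose(belief.s[1], B[:, :, 0] @ belief.s[0], atol=1e-4)


class TestPosteriorInvariants:
    def test_posterior_stays_on_simplex(self, rng, random_model_factory):
        for _ in range(20):
            model = random_model_factory(rng)
            n_out = model.modality(0).n_outcomes
            belief = infer_states(model, [[one_hot(int(rng.integers(n_out)), n_out)]])
            assert np.all(belief.s >= 0)
            assert np.allclose(belief.s.sum(axis=1), 1.0, atol=1e-10)
            assert np.allclose(belief.s, softmax(belief.v, axis=1))


class TestFreeEnergy:
    def _loglik(self, model, observations):
        out = []
        for obs_t in observations:
            ll = np.zeros(model.n_states)
            if obs_t is not None:
                for m, o in enumerate(obs_t):
                    ll += stable_log(model.joint_likelihood(m)).T @ np.asarray(o)
            out.append(ll)
        return out

    def test_matches_reference_evaluation(self, rng, random_model_factory):
        for _ in range(20):
            model = random_model_factory(rng)
            n_out = model.modality(0).n_outcomes
            obs = [[one_hot(int(rng.integers(n_out)), n_out)]]
            belief = infer_states(model, obs, max_iterations=3)
            F = marginal_free_energy(belief, model, obs)
            ref = free_energy_reference(
                belief.s, model.joint_prior(), [], self._loglik(model, obs)
            )
            assert np.allclose(F, ref, atol=1e-10)

    def test_flat_likelihood_value_at_prior(self, single_factor_model_factory):
        # with a flat A and s fixed at the prior D, every term can be
        # evaluated by hand: F = s.(ln s - ln D - ln A^T o) = -ln 2
        model = single_factor_model_factory([0.7, 0.3], np.full((2, 2), 0.5))
        belief = infer_states(model, [[one_hot(0, 2)]])
        F = marginal_free_energy(belief, model, [[one_hot(0, 2)]])
        assert np.allclose(F, -np.log(0.5 + 1e-16), atol=1e-6)

    def test_descent_from_uniform_initialisation(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2))
        obs = [[one_hot(0, 2)]]
        start = infer_states(model, obs, max_iterations=1)
        end = infer_states(model, obs, max_iterations=16)
        F_start = marginal_free_energy(start, model, obs).sum()
        F_end = marginal_free_energy(end, model, obs).sum()
        assert F_end <= F_start + 1e-12

    def test_mostly_non_increasing_over_iterations(self, rng, random_model_factory):
        ok = 0
        n_models = 40
        for _ in range(n_models):
            model = random_model_factory(rng)
            n_out = model.modality(0).n_outcomes
            obs = [[one_hot(int(rng.integers(n_out)), n_out)]]
            values = []
            for k in range(1, 8):
                belief = infer_states(model, obs, max_iterations=k)
                values.append(marginal_free_energy(belief, model, obs).sum())
            diffs = np.diff(values)
            if np.all(diffs <= 1e-8):
                ok += 1
        assert ok / n_models >= 0.95

    def test_length_mismatch_rejected(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2), horizon=2)
        belief = infer_states(model, [[one_hot(0, 2)], None])
        with pytest.raises(ValueError):
            marginal_free_energy(belief, model, [[one_hot(0, 2)]])


class TestSmoothing:
    def test_evidence_propagates_backward_with_identity_transitions(
        self, single_factor_model_factory
    ):
        # a later decisive observation should pull the first-timestep
        # posterior toward the observed state when B is the identity
        A = np.array([[0.8, 0.2], [0.2, 0.8]])
        model = single_factor_model_factory([0.5, 0.5], A, horizon=3)
        obs = [[np.array([0.5, 0.5])], [one_hot(0, 2)], [one_hot(0, 2)]]
        belief = infer_states(model, obs)
        assert belief.s[0][0] > 0.6
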
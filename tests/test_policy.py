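import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optibias.inference import BeliefState, infer_states
from optibias.model import (
    DirichletCounts,
    GenerativeModel,
    Modality,
    StateFactor,
    log_softmax,
    one_hot,
    softmax,
)
from optibias.policy import (
    expected_free_energy,
    novelty_weight,
    policy_posterior,
    select_action,
)

from .oracles import efe_reference, novelty_weight_reference


def make_preference_model(A, prior, preferences, a_counts=None, learnable=True):
    n = len(prior)
    factor = StateFactor("state", DirichletCounts(np.asarray(prior, float), learnable=False), np.eye(n)[:, :, None])
    counts = DirichletCounts(np.asarray(a_counts if a_counts is not None else A, float), learnable=learnable)
    modality = Modality("outcome", counts, preferences=np.asarray(preferences, float))
    return GenerativeModel([factor], [modality], np.zeros((1, 0, 1), int), horizon=1)


def belief_at(s):
    s = np.atleast_2d(np.asarray(s, float))
    return BeliefState(s=s, v=np.log(s + 1e-16), epsilon=np.zeros_like(s), iterations=1)


class TestNoveltyWeight:
    def test_unit_counts(self):
        assert np.allclose(novelty_weight(np.array([1.0, 1.0])), 0.25)

    def test_large_count_limit(self):
        W = novelty_weight(np.array([1000.0, 1000.0]))
        assert np.allclose(W, 0.00025)

    def test_matches_reference_on_random_counts(self, rng):
        counts = rng.uniform(0.1, 5.0, size=(3, 3))
        assert np.allclose(novelty_weight(counts), novelty_weight_reference(counts), atol=1e-12)

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValueError):
            novelty_weight(np.array([1.0, 0.0]))

    def test_nonnegative_when_counts_below_column_sums(self, rng):
        counts = rng.uniform(0.1, 5.0, size=(4, 2))
        assert np.all(novelty_weight(counts) >= 0)


class TestExpectedFreeEnergy:
    def test_all_terms_vanish_in_the_preferred_deterministic_limit(self):
        # identity likelihood, huge counts, preferences matching the
        # predicted outcome distribution: risk, ambiguity, novelty all -> 0
        prefs = np.array([1.0, 0.0])
        counts = (np.eye(2) + 1e-9) * 1e12
        model = make_preference_model(np.eye(2), [0.5, 0.5], prefs, a_counts=counts)
        ev = expected_free_energy(model, belief_at(softmax(prefs)))
        assert abs(ev.risk.sum()) < 1e-4
        assert abs(ev.ambiguity.sum()) < 1e-4
        assert abs(ev.novelty.sum()) < 1e-3
        assert abs(ev.G) < 1e-3

    def test_flat_likelihood_ambiguity_is_ln2(self, rng):
        model = make_preference_model(np.full((2, 2), 0.5), [0.5, 0.5], [0.3, -0.2])
        for _ in range(3):
            s = rng.dirichlet(np.ones(2))
            ev = expected_free_energy(model, belief_at(s))
            assert np.allclose(ev.ambiguity, np.log(2), atol=1e-10)

    def test_matches_reference_term_by_term(self):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        counts = np.array([[2.0, 1.0], [1.0, 2.0]])
        prefs = np.array([1.0, 0.0])
        s = np.array([0.5, 0.5])
        model = make_preference_model(A, [0.5, 0.5], prefs, a_counts=counts)
        # the model's A is the normalised counts table
        A_model = model.joint_likelihood(0)
        ev = expected_free_energy(model, belief_at(s))
        G_ref, risk_ref, amb_ref, nov_ref = efe_reference(
            A_model, counts, s, log_softmax(prefs)
        )
        assert np.allclose(ev.risk.sum(), risk_ref, atol=1e-10)
        assert np.allclose(ev.ambiguity.sum(), amb_ref, atol=1e-10)
        assert np.allclose(ev.novelty.sum(), nov_ref, atol=1e-10)
        assert np.allclose(ev.G, G_ref, atol=1e-10)

    def test_missing_preferences_rejected(self, single_factor_model_factory):
        model = single_factor_model_factory([0.5, 0.5], np.eye(2))
        with pytest.raises(ValueError, match="preference"):
            expected_free_energy(model, belief_at([0.5, 0.5]))

    def test_locked_counts_contribute_no_novelty(self):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        model = make_preference_model(A, [0.5, 0.5], [1.0, 0.0], learnable=False)
        ev = expected_free_energy(model, belief_at([0.5, 0.5]))
        assert np.all(ev.novelty == 0)

    def test_novelty_vanishes_as_counts_grow(self):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        novelty = []
        for scale in (1.0, 100.0, 10000.0):
            model = make_preference_model(A, [0.5, 0.5], [1.0, 0.0], a_counts=A * scale)
            novelty.append(expected_free_energy(model, belief_at([0.5, 0.5])).novelty.sum())
        assert novelty[0] > novelty[1] > novelty[2]
        assert novelty[2] < 1e-4

    def test_preference_shift_invariance(self, rng):
        A = np.array([[0.8, 0.3], [0.2, 0.7]])
        s_list = [rng.dirichlet(np.ones(2)) for _ in range(3)]
        prefs = np.array([1.5, -0.5])
        for shift in (0.0, 2.0, -3.0):
            model = make_preference_model(A, [0.5, 0.5], prefs + shift)
            G = [expected_free_energy(model, belief_at(s)).G for s in s_list]
            if shift == 0.0:
                G0 = G
            else:
                # softmax normalisation of C absorbs any constant shift
                assert np.allclose(G, G0, atol=1e-12)

    def test_outcomes_closer_to_preferences_score_lower(self):
        # two candidate posteriors under an identity mapping: the one whose
        # predicted outcomes are closer (in KL) to C gets lower G and hence
        # higher posterior probability
        prefs = np.array([2.0, 0.0])
        model = make_preference_model(np.eye(2), [0.5, 0.5], prefs, a_counts=(np.eye(2) + 1e-9) * 1e12)
        target = softmax(prefs)
        close = belief_at(0.9 * target + 0.1 * np.array([0.5, 0.5]))
        far = belief_at([0.3, 0.7])
        G_close = expected_free_energy(model, close).G
        G_far = expected_free_energy(model, far).G
        post = policy_posterior([G_close, G_far])
        assert G_close < G_far
        assert post[0] > post[1]


class TestPolicyPosterior:
    def test_equal_G_gives_uniform(self):
        assert np.allclose(policy_posterior([1.3, 1.3, 1.3]), 1 / 3)

    def test_dominant_policy(self):
        post = policy_posterior([0.0, 1e6])
        assert np.allclose(post, [1.0, 0.0], atol=1e-12)

    def test_hand_computed_softmax(self):
        post = policy_posterior([1.0, 2.0, 3.0])
        expected = np.exp([-1.0, -2.0, -3.0])
        expected /= expected.sum()
        assert np.allclose(post, expected, atol=1e-12)
        assert post[0] > post[1] > post[2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            policy_posterior([])


class TestSelectAction:
    def test_degenerate_posterior(self, rng):
        assert select_action([1.0, 0.0, 0.0], "sample", rng) == 0
        assert select_action([1.0, 0.0, 0.0], "argmax") == 0

    def test_sampling_reproducible_under_seed(self):
        draws_a = [select_action([0.25, 0.25, 0.25, 0.25], "sample", np.random.default_rng(7)) for _ in range(5)]
        draws_b = [select_action([0.25, 0.25, 0.25, 0.25], "sample", np.random.default_rng(7)) for _ in range(5)]
        assert draws_a == draws_b

    def test_argmax_tie_breaks_low(self):
        assert select_action([0.5, 0.5], "argmax") == 0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            select_action([1.0], "greedy")


@given(st.floats(min_value=-5, max_value=5))
@settings(deadline=None, max_examples=30)
def test_posterior_shift_invariance_in_G(shift):
    base = np.array([0.3, 1.0, -0.7])
    assert np.allclose(policy_posterior(base), policy_posterior(base + shift), atol=1e-12)
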
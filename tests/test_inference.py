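"""Belief updating: modulation, state posteriors, G, and policy selection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from active_vision import (
    Policy,
    ambiguity,
    build_model,
    expected_free_energy,
    modulate_likelihood,
    policy_posterior,
    predicted_outcomes,
    select_action,
    update_state_posteriors,
)
from active_vision.inference import modulated_likelihoods

from .oracles import enumerate_posterior, expected_free_energy_loops


class TestModulateLikelihood:
    def test_unit_precision_is_identity(self, rng):
        A = rng.dirichlet(np.ones(4), size=5).T
        np.testing.assert_allclose(modulate_likelihood(A, 1.0), A, atol=1e-12)

    def test_zero_precision_is_uniform(self, rng):
        A = rng.dirichlet(np.ones(3), size=4).T
        np.testing.assert_allclose(modulate_likelihood(A, 0.0), np.full((3, 4), 1 / 3))

    def test_high_precision_is_deterministic(self):
        A = np.array([[0.9], [0.1]])
        np.testing.assert_allclose(modulate_likelihood(A, 50.0), [[1.0], [0.0]], atol=1e-6)

    def test_negative_precision_rejected(self):
        with pytest.raises(ValueError):
            modulate_likelihood(np.eye(2), -0.5)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 10_000), st.floats(0.0, 5.0), st.floats(0.1, 5.0))
    def test_monotone_in_zeta(self, seed, z1, dz):
        """Raising zeta never decreases the largest entry of any column."""
        A = np.random.default_rng(seed).dirichlet(np.ones(3), size=4).T
        lo, hi = modulate_likelihood(A, z1), modulate_likelihood(A, z1 + dz)
        assert np.all(hi.max(axis=0) >= lo.max(axis=0) - 1e-12)


class TestStatePosteriors:
    def test_delta_likelihood_concentrates(self):
        spec = {
            "factors": [
                {
                    "name": "s",
                    "levels": ["a", "b", "c"],
                    "transitions": "identity",
                    "initial": "uniform",
                    "controllable": True,
                }
            ],
            "modalities": [
                {
                    "name": "o",
                    "parents": ["s"],
                    "array": np.eye(3).tolist(),
                    "outcomes": ["x", "y", "z"],
                }
            ],
        }
        m = build_model(spec)
        res = update_state_posteriors(m, [{"o": 2}], [])
        assert res.marginals[0][0][2] >= 1 - 1e-6

    def test_uninformative_likelihood_returns_prior(self, chain_model_factory):
        model, spec = chain_model_factory(seed=5)
        prior = np.array(spec["factors"][0]["initial"])
        # a uniform likelihood (the zeta = 0 limit) leaves the prior untouched
        spec["modalities"][0]["array"] = np.full((3, 3), 1 / 3).tolist()
        flat = build_model(spec)
        res = update_state_posteriors(flat, [{"obs": 1}], [])
        np.testing.assert_allclose(res.marginals[0][0], prior, atol=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    @pytest.mark.parametrize("with_zeros", [False, True])
    def test_matches_exact_bayes_on_chains(self, chain_model_factory, seed, with_zeros):
        """Structured VB equals enumeration on single-factor chains."""
        model, spec = chain_model_factory(seed=seed, with_zeros=with_zeros)
        A = np.array(spec["modalities"][0]["array"])
        Bs = np.array(spec["factors"][0]["transitions"])
        D = np.array(spec["factors"][0]["initial"])
        rng = np.random.default_rng(seed + 100)
        actions = [int(a) for a in rng.integers(0, 2, 2)]
        obs = [{"obs": int(o)} for o in rng.integers(0, 3, 3)]
        res = update_state_posteriors(model, obs, actions)
        exact, logZ = enumerate_posterior(
            D, [Bs[a] for a in actions], A, [o["obs"] for o in obs]
        )
        for t in range(3):
            tv = 0.5 * np.abs(res.marginals[t][0] - exact[t]).sum()
            assert tv < 1e-4
        assert abs(res.free_energy + logZ) < 1e-6

    def test_free_energy_non_increasing(self, foraging_model):
        obs = [
            {"vision": 1, "proprioception": 0},
            {"vision": 2, "proprioception": 1},
            {"vision": 0, "proprioception": 2},
        ]
        res = update_state_posteriors(foraging_model, obs, [1, 2])
        diffs = np.diff(res.free_energy_trace)
        assert np.all(diffs <= 1e-6)
        assert res.converged

    def test_partial_optimization_has_higher_free_energy(self, foraging_model):
        """F is a bound: stopping early can only leave it higher."""
        obs = [
            {"vision": 1, "proprioception": 0},
            {"vision": 2, "proprioception": 1},
        ]
        with pytest.warns(RuntimeWarning):
            early = update_state_posteriors(
                foraging_model, obs, [1], max_iterations=1, tol=0.0
            )
        full = update_state_posteriors(foraging_model, obs, [1])
        assert full.free_energy <= early.free_energy + 1e-9

    def test_all_marginals_normalized(self, foraging_model):
        obs = [{"vision": 1, "proprioception": 0}]
        res = update_state_posteriors(foraging_model, obs, [3])
        for row in res.marginals:
            for marg in row:
                assert np.all(marg >= 0)
                assert abs(marg.sum() - 1) < 1e-8


class TestPredictedOutcomes:
    def test_delta_state_selects_column(self, rng):
        A = rng.dirichlet(np.ones(3), size=4).T
        s = np.zeros(4)
        s[2] = 1.0
        np.testing.assert_allclose(predicted_outcomes(A, [s]), A[:, 2])

    def test_uniform_everything_uniform(self):
        A = np.full((3, 2), 1 / 3)
        np.testing.assert_allclose(
            predicted_outcomes(A, [np.full(2, 0.5)]), np.full(3, 1 / 3)
        )

    def test_two_factor_contraction_matches_loops(self, rng):
        A = rng.dirichlet(np.ones(3), size=(2, 4)).transpose(2, 0, 1)
        s1, s2 = rng.dirichlet(np.ones(2)), rng.dirichlet(np.ones(4))
        expected = np.zeros(3)
        for i in range(3):
            for j in range(2):
                for k in range(4):
                    expected[i] += A[i, j, k] * s1[j] * s2[k]
        np.testing.assert_allclose(predicted_outcomes(A, [s1, s2]), expected)


class TestAmbiguity:
    def test_deterministic_column_zero(self):
        np.testing.assert_allclose(ambiguity(np.eye(3)), np.zeros(3), atol=1e-13)

    def test_uniform_column_is_neg_log_n(self):
        A = np.full((3, 2), 1 / 3)
        np.testing.assert_allclose(ambiguity(A), [-np.log(3)] * 2)

    def test_printed_value(self):
        A = np.array([[0.25], [0.75]])
        np.testing.assert_allclose(ambiguity(A), [-0.5623], atol=1e-4)

    def test_always_nonpositive(self, rng):
        A = rng.dirichlet(np.ones(4), size=6).T
        assert np.all(ambiguity(A) <= 0)


class TestExpectedFreeEnergy:
    def test_matches_loop_oracle(self, chain_model_factory):
        model, spec = chain_model_factory(seed=9)
        A = np.array(spec["modalities"][0]["array"])
        D = np.array(spec["factors"][0]["initial"])
        Bs = np.array(spec["factors"][0]["transitions"])
        for a in (0, 1):
            G = expected_free_energy(model, [D], Policy((a,)))
            s_next = Bs[a] @ D
            C = np.full(3, 1 / 3)
            expected = expected_free_energy_loops(A, C, s_next)
            assert abs(G - expected) < 1e-10

    def test_unresolved_location_has_lower_G(self):
        """Epistemic drive: saccade to an unknown beats re-examining a known."""
        from active_vision import build_foraging_model

        priors = np.full((4, 3), 1 / 3)
        priors[0] = [0.995, 0.0025, 0.0025]  # LL essentially resolved
        model = build_foraging_model(priors, sensory_fidelity=1.0)
        beliefs = [f.initial.probs for f in model.factors]
        G_known = expected_free_energy(model, beliefs, Policy((0,)))
        G_unknown = expected_free_energy(model, beliefs, Policy((1,)))
        assert G_unknown < G_known


class TestPolicySelection:
    def test_equal_G_gives_uniform(self):
        np.testing.assert_allclose(policy_posterior([2.0, 2.0, 2.0]), np.full(3, 1 / 3))

    def test_closed_form_softmax(self):
        np.testing.assert_allclose(policy_posterior([0.0, np.log(9)]), [0.9, 0.1])

    def test_shift_invariance(self, rng):
        G = rng.normal(size=6)
        np.testing.assert_allclose(
            policy_posterior(G), policy_posterior(G + 7.0), atol=1e-12
        )

    def test_single_policy(self):
        assert select_action([1.0], [Policy((2,))]) == 2

    def test_marginal_argmax(self):
        pols = [Policy((0,)), Policy((3,))]
        assert select_action([0.6, 0.4], pols) == 0

    def test_tie_breaks_to_lowest_index(self):
        pols = [Policy((3,)), Policy((1,))]
        assert select_action([0.5, 0.5], pols) == 1

    def test_empty_policy_space_rejected(self):
        with pytest.raises(ValueError):
            select_action([], [])


def test_per_location_modulation(foraging_model):
    """Only the visual likelihood is modulated, per fixated-location zeta."""
    from active_vision import PrecisionBelief

    m = foraging_model.with_precisions(
        [PrecisionBelief(1.0, 1.0)] * 3 + [PrecisionBelief(1.0, 1e9)]
    )
    Abar = modulated_likelihoods(m)
    np.testing.assert_array_equal(
        Abar["proprioception"], m.modality("proprioception").array
    )
    vis = m.modality("vision").array
    # locations 0-2 keep zeta = 1 (unchanged); location 3 becomes uniform
    np.testing.assert_allclose(Abar["vision"][..., :3], vis[..., :3], atol=1e-12)
    np.testing.assert_allclose(Abar["vision"][..., 3], 1 / 3, atol=1e-6)
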
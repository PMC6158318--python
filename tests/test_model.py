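"""Container construction, validation, and serialization round-trips."""

import json

import numpy as np
import pytest

from active_vision import (
    CategoricalBelief,
    ModelValidationError,
    PrecisionBelief,
    TransitionMapping,
    build_model,
    load_model,
    log_stable,
    model_from_dict,
    model_to_dict,
    save_model,
)
from active_vision.model import EPS


class TestLogStable:
    def test_exact_values(self):
        np.testing.assert_allclose(
            log_stable([0.25, 0.75]), [-1.3862944, -0.2876821], atol=1e-6
        )
        np.testing.assert_allclose(log_stable([0.5, 0.5]), np.log([0.5, 0.5]))

    def test_zero_is_floored(self):
        out = log_stable([1.0, 0.0])
        assert out[0] == 0.0
        assert out[1] == np.log(EPS)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            log_stable([-0.1, 1.1])


class TestBeliefInvariants:
    def test_duplicate_labels_rejected(self):
        with pytest.raises(ModelValidationError):
            CategoricalBelief(("a", "a"), [0.5, 0.5])

    def test_unnormalized_rejected(self):
        with pytest.raises(ModelValidationError):
            CategoricalBelief(("a", "b"), [0.5, 0.4])

    def test_delta_and_uniform(self):
        d = CategoricalBelief.delta(("a", "b", "c"), "b")
        assert d.map_index() == 1
        u = CategoricalBelief.uniform(("a", "b"))
        np.testing.assert_allclose(u.probs, [0.5, 0.5])

    def test_precision_requires_positive_rates(self):
        with pytest.raises(ModelValidationError):
            PrecisionBelief(0.0, 1.0)
        with pytest.raises(ModelValidationError):
            PrecisionBelief(1.0, -2.0)
        p = PrecisionBelief(2.0, 4.0)
        assert p.zeta == 0.25 and p.zeta_prior == 0.5
        assert p.reset().beta_posterior == 2.0


class TestBuildModel:
    def test_minimal_two_state_model(self):
        spec = {
            "factors": [
                {
                    "name": "s",
                    "levels": ["x", "y"],
                    "transitions": [np.eye(2).tolist()],
                    "initial": "uniform",
                    "controllable": True,
                }
            ],
            "modalities": [
                {
                    "name": "o",
                    "parents": ["s"],
                    "array": np.eye(2).tolist(),
                    "outcomes": ["ox", "oy"],
                }
            ],
            "horizon": 1,
        }
        m = build_model(spec)
        assert m.n_actions == 1 and len(m.factors) == 1

    def test_foraging_model_shape(self, foraging_model):
        assert len(foraging_model.factors) == 5
        assert len(foraging_model.modalities) == 2
        assert len(foraging_model.precisions) == 4
        assert foraging_model.controllable_factor == 4

    def test_non_stochastic_column_rejected(self):
        spec = {
            "factors": [
                {
                    "name": "s",
                    "levels": ["x", "y"],
                    "transitions": "identity",
                    "initial": "uniform",
                    "controllable": True,
                }
            ],
            "modalities": [
                {
                    "name": "o",
                    "parents": ["s"],
                    "array": [[0.5, 0.5], [0.4, 0.5]],
                    "outcomes": ["a", "b"],
                }
            ],
        }
        with pytest.raises(ModelValidationError, match="o"):
            build_model(spec)

    def test_dangling_parent_rejected(self):
        spec = {
            "factors": [
                {
                    "name": "s",
                    "levels": ["x", "y"],
                    "transitions": "identity",
                    "initial": "uniform",
                    "controllable": True,
                }
            ],
            "modalities": [
                {
                    "name": "o",
                    "parents": ["nope"],
                    "array": np.eye(2).tolist(),
                    "outcomes": ["a", "b"],
                }
            ],
        }
        with pytest.raises(ModelValidationError, match="nope"):
            build_model(spec)

    def test_nonpositive_beta_rejected(self, chain_model_factory):
        _, spec = chain_model_factory(seed=3)
        spec["precision"] = {"factor": None, "beta_prior": 0.0, "modalities": ["obs"]}
        with pytest.raises(ModelValidationError, match="beta"):
            build_model(spec)

    def test_two_controllable_factors_rejected(self, chain_model_factory):
        _, spec = chain_model_factory(seed=4)
        spec["factors"].append(dict(spec["factors"][0], name="state2"))
        with pytest.raises(ModelValidationError, match="controllable"):
            build_model(spec)


class TestSerialization:
    @pytest.mark.parametrize("fmt", ["json", "yaml"])
    def test_round_trip_bit_for_bit(self, tmp_path, foraging_model, fmt):
        path = tmp_path / f"model.{fmt}"
        save_model(foraging_model, path)
        loaded = load_model(path)
        for f0, f1 in zip(foraging_model.factors, loaded.factors):
            assert np.array_equal(f0.transitions.array, f1.transitions.array)
            assert np.array_equal(f0.initial.probs, f1.initial.probs)
        for m0, m1 in zip(foraging_model.modalities, loaded.modalities):
            assert np.array_equal(m0.array, m1.array)
        assert model_to_dict(loaded) == model_to_dict(foraging_model)

    def test_dict_round_trip_preserves_posteriors(self, foraging_model):
        m = foraging_model.with_precisions(
            PrecisionBelief(1.0, b) for b in (0.5, 2.0, 3.0, 4.0)
        )
        m2 = model_from_dict(json.loads(json.dumps(model_to_dict(m))))
        assert [p.beta_posterior for p in m2.precisions] == [0.5, 2.0, 3.0, 4.0]

    def test_valid_model_has_finite_logs(self, chain_model_factory, foraging_model):
        for model in (chain_model_factory(seed=11, with_zeros=True)[0], foraging_model):
            for f in model.factors:
                assert np.all(np.isfinite(log_stable(f.transitions.array)))
            for m in model.modalities:
                assert np.all(np.isfinite(log_stable(m.array)))


def test_identity_transitions_detected():
    t = TransitionMapping("f", np.broadcast_to(np.eye(3), (4, 3, 3)).copy())
    assert t.is_identity()
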
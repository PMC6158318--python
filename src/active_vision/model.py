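"""Generative-model containers for discrete-state active inference.

A generative model here is a partially observed Markov decision process
factorized into independent hidden-state factors.  Each factor carries a
per-action transition array B and an initial-state prior; each outcome
modality carries a likelihood array A mapping combinations of parent-factor
levels to outcome distributions.  Sensory precision zeta acts as an inverse
temperature on likelihood columns and is itself a random variable with
Gamma(1, beta) prior and posterior beliefs (so E[zeta] = 1/beta).

This module only defines and validates the containers; all belief updating
lives in :mod:`active_vision.inference`.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

#: Probability floor applied before any logarithm.  The task's transition
#: mappings are identities with exact zeros, and every update takes logs,
#: so a documented floor is part of the model semantics.
EPS = 1e-16

#: Tolerance on "sums to one" checks for stored distributions.
NORM_TOL = 1e-8


class ModelValidationError(ValueError):
    """A model component violates its invariants.

    The message always names the offending component.
    """


def log_stable(probs, eps: float = EPS) -> np.ndarray:
    """Elementwise ln(max(p, eps)) for a non-negative array.

    Raises ``ValueError`` on negative entries.
    """
    p = np.asarray(probs, dtype=float)
    if np.any(p < 0):
        raise ValueError("log_stable: negative entries in probability array")
    return np.log(np.maximum(p, eps))


def _check_distribution(p: np.ndarray, what: str, axis: int | None = None) -> None:
    if np.any(p < -NORM_TOL):
        raise ModelValidationError(f"{what}: negative probabilities")
    sums = p.sum() if axis is None else p.sum(axis=axis)
    if not np.allclose(sums, 1.0, atol=NORM_TOL):
        raise ModelValidationError(f"{what}: distribution does not sum to 1 (got {sums})")


@dataclass(frozen=True)
class CategoricalBelief:
    """A normalized probability vector over a labeled discrete support."""

    labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if len(set(self.labels)) != len(self.labels):
            raise ModelValidationError(f"CategoricalBelief: duplicate labels {self.labels}")
        if self.probs.shape != (len(self.labels),):
            raise ModelValidationError(
                f"CategoricalBelief: {len(self.labels)} labels but probs shape {self.probs.shape}"
            )
        _check_distribution(self.probs, "CategoricalBelief")

    @classmethod
    def uniform(cls, labels) -> "CategoricalBelief":
        labels = tuple(labels)
        return cls(labels, np.full(len(labels), 1.0 / len(labels)))

    @classmethod
    def delta(cls, labels, label: str) -> "CategoricalBelief":
        labels = tuple(labels)
        p = np.zeros(len(labels))
        p[labels.index(label)] = 1.0
        return cls(labels, p)

    @classmethod
    def from_unnormalized(cls, labels, weights) -> "CategoricalBelief":
        w = np.asarray(weights, dtype=float)
        total = w.sum()
        if total <= 0:
            raise ModelValidationError("CategoricalBelief: non-positive total mass")
        return cls(tuple(labels), w / total)

    def __len__(self) -> int:
        return len(self.labels)

    def map_index(self) -> int:
        return int(np.argmax(self.probs))


@dataclass(frozen=True)
class LikelihoodMapping:
    """Conditional outcome distributions P(o | parent state combination).

    ``array`` has shape ``(n_outcomes, *parent_dims)``; every column (slice
    along axis 0) is a distribution over outcomes.  ``parents`` holds the
    indices of the state factors this modality depends on, in axis order.
    """

    modality: str
    array: np.ndarray
    parents: tuple[int, ...]
    outcomes: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "array", np.asarray(self.array, dtype=float))
        object.__setattr__(self, "parents", tuple(self.parents))
        object.__setattr__(self, "outcomes", tuple(self.outcomes))
        a = self.array
        if a.ndim != 1 + len(self.parents):
            raise ModelValidationError(
                f"modality '{self.modality}': array ndim {a.ndim} does not match "
                f"1 + {len(self.parents)} parents"
            )
        if a.shape[0] != len(self.outcomes):
            raise ModelValidationError(
                f"modality '{self.modality}': {len(self.outcomes)} outcome labels "
                f"but array has {a.shape[0]} rows"
            )
        _check_distribution(a, f"modality '{self.modality}' likelihood columns", axis=0)

    @property
    def n_outcomes(self) -> int:
        return self.array.shape[0]


@dataclass(frozen=True)
class TransitionMapping:
    """Per-action transition arrays B[u][next, previous] for one factor."""

    factor: str
    array: np.ndarray  # shape (n_actions, n, n)

    def __post_init__(self):
        a = np.asarray(self.array, dtype=float)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ModelValidationError(
                f"factor '{self.factor}': transition array must be (n_actions, n, n), got {a.shape}"
            )
        object.__setattr__(self, "array", a)
        _check_distribution(a, f"factor '{self.factor}' transition columns", axis=1)

    @property
    def n_actions(self) -> int:
        return self.array.shape[0]

    @property
    def n_states(self) -> int:
        return self.array.shape[1]

    def is_identity(self) -> bool:
        eye = np.eye(self.n_states)
        return all(np.array_equal(self.array[u], eye) for u in range(self.n_actions))


@dataclass(frozen=True)
class PrecisionBelief:
    """Gamma(1, beta) prior and posterior beliefs about sensory precision.

    The expected precision is exactly ``zeta = 1 / beta_posterior``.
    """

    beta_prior: float
    beta_posterior: float

    def __post_init__(self):
        if not (self.beta_prior > 0):
            raise ModelValidationError(f"PrecisionBelief: beta_prior {self.beta_prior} must be > 0")
        if not (self.beta_posterior > 0):
            raise ModelValidationError(
                f"PrecisionBelief: beta_posterior {self.beta_posterior} must be > 0"
            )

    @property
    def zeta(self) -> float:
        return 1.0 / self.beta_posterior

    @property
    def zeta_prior(self) -> float:
        return 1.0 / self.beta_prior

    def reset(self) -> "PrecisionBelief":
        return PrecisionBelief(self.beta_prior, self.beta_prior)


@dataclass(frozen=True)
class Policy:
    """An ordered sequence of saccade actions (target location indices)."""

    actions: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "actions", tuple(int(a) for a in self.actions))


@dataclass(frozen=True)
class StateFactor:
    name: str
    levels: tuple[str, ...]
    transitions: TransitionMapping
    initial: CategoricalBelief
    controllable: bool = False

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))
        n = len(self.levels)
        if self.transitions.n_states != n:
            raise ModelValidationError(
                f"factor '{self.name}': transition size {self.transitions.n_states} != {n} levels"
            )
        if len(self.initial) != n:
            raise ModelValidationError(
                f"factor '{self.name}': initial prior length {len(self.initial)} != {n} levels"
            )

    @property
    def n_states(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class GenerativeModel:
    """A validated discrete-state generative model.

    Exactly one factor is controllable (its transitions depend on the chosen
    action); all other factors must have action-independent transitions.
    ``precisions`` holds one Gamma precision belief per level of
    ``precision_factor`` (or a single shared belief when it is None), and
    ``precision_modalities`` names the modalities whose likelihoods are
    modulated by the expected precision.
    """

    factors: tuple[StateFactor, ...]
    modalities: tuple[LikelihoodMapping, ...]
    outcome_priors: dict = field(default_factory=dict)  # modality -> CategoricalBelief
    precisions: tuple[PrecisionBelief, ...] = (PrecisionBelief(1.0, 1.0),)
    precision_factor: int | None = None
    precision_modalities: frozenset = frozenset()
    horizon: int = 1
    policy_depth: int = 1

    def __post_init__(self):
        object.__setattr__(self, "factors", tuple(self.factors))
        object.__setattr__(self, "modalities", tuple(self.modalities))
        object.__setattr__(self, "precisions", tuple(self.precisions))
        object.__setattr__(self, "precision_modalities", frozenset(self.precision_modalities))
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n_factors = len(self.factors)
        controllable = [i for i, f in enumerate(self.factors) if f.controllable]
        if len(controllable) != 1:
            raise ModelValidationError(
                f"model: exactly one controllable factor required, found {len(controllable)}"
            )
        n_actions = self.n_actions
        for i, f in enumerate(self.factors):
            if f.controllable:
                continue
            B = f.transitions.array
            if B.shape[0] not in (1, n_actions):
                raise ModelValidationError(
                    f"factor '{f.name}': {B.shape[0]} action slices but model has {n_actions} actions"
                )
            if B.shape[0] > 1 and not all(np.array_equal(B[0], B[u]) for u in range(B.shape[0])):
                raise ModelValidationError(
                    f"factor '{f.name}': transitions must be action-independent "
                    "(only the controllable factor may depend on the action)"
                )
        for m in self.modalities:
            for p in m.parents:
                if not (0 <= p < n_factors):
                    raise ModelValidationError(
                        f"modality '{m.modality}': parent factor index {p} out of range"
                    )
            expected = tuple(self.factors[p].n_states for p in m.parents)
            if m.array.shape[1:] != expected:
                raise ModelValidationError(
                    f"modality '{m.modality}': array parent dims {m.array.shape[1:]} "
                    f"!= factor sizes {expected}"
                )
        for name, c in self.outcome_priors.items():
            mod = self.modality(name)
            if len(c) != mod.n_outcomes:
                raise ModelValidationError(
                    f"outcome prior for '{name}': length {len(c)} != {mod.n_outcomes} outcomes"
                )
        if self.precision_factor is not None:
            pf = self.precision_factor
            if not (0 <= pf < n_factors):
                raise ModelValidationError(f"precision_factor index {pf} out of range")
            if len(self.precisions) != self.factors[pf].n_states:
                raise ModelValidationError(
                    f"model: {len(self.precisions)} precision beliefs but precision factor "
                    f"'{self.factors[pf].name}' has {self.factors[pf].n_states} levels"
                )
            for m in self.modalities:
                if m.modality in self.precision_modalities and pf not in m.parents:
                    raise ModelValidationError(
                        f"modality '{m.modality}' is precision-modulated but does not "
                        f"list the precision factor as a parent"
                    )
        for name in self.precision_modalities:
            self.modality(name)  # raises if dangling
        if self.horizon < 1:
            raise ModelValidationError("model: horizon must be >= 1")
        if self.policy_depth < 1:
            raise ModelValidationError("model: policy_depth must be >= 1")

    # -- convenience -----------------------------------------------------
    @property
    def controllable_factor(self) -> int:
        return next(i for i, f in enumerate(self.factors) if f.controllable)

    @property
    def n_actions(self) -> int:
        return self.factors[self.controllable_factor].transitions.n_actions

    def modality(self, name: str) -> LikelihoodMapping:
        for m in self.modalities:
            if m.modality == name:
                return m
        raise ModelValidationError(f"unknown modality '{name}'")

    def outcome_prior(self, name: str) -> CategoricalBelief:
        """C for a modality; defaults to uniform when unspecified."""
        if name in self.outcome_priors:
            return self.outcome_priors[name]
        return CategoricalBelief.uniform(self.modality(name).outcomes)

    def policies(self) -> list[Policy]:
        """All action sequences of length ``policy_depth``."""
        return [
            Policy(seq)
            for seq in itertools.product(range(self.n_actions), repeat=self.policy_depth)
        ]

    def transition(self, factor: int, action: int) -> np.ndarray:
        B = self.factors[factor].transitions.array
        return B[action if B.shape[0] > 1 else 0]

    def with_precisions(self, precisions) -> "GenerativeModel":
        return dataclasses.replace(self, precisions=tuple(precisions))


# ---------------------------------------------------------------------------
# Spec-dict construction and serialization
# ---------------------------------------------------------------------------

def build_model(spec: dict) -> GenerativeModel:
    """Build and validate a :class:`GenerativeModel` from a plain-dict spec.

    Schema (JSON/YAML friendly)::

        factors:
          - name: str
            levels: [str, ...]
            transitions: "identity" | nested list (n_actions, n, n)
            initial: [float, ...] | "uniform"
            controllable: bool (default false)
        modalities:
          - name: str
            parents: [factor name, ...]
            array: nested list (n_outcomes, *parent_dims)
            outcomes: [str, ...]
        outcome_priors: {modality: [float, ...]}          # optional, default uniform
        precision:                                         # optional
          factor: factor name | null
          beta_prior: float | [float, ...]
          modalities: [modality name, ...]
        horizon: int
        policy_depth: int (default 1)
    """
    try:
        factor_specs = spec["factors"]
        modality_specs = spec["modalities"]
    except KeyError as e:
        raise ModelValidationError(f"model spec missing required key {e}") from None

    names = [fs["name"] for fs in factor_specs]
    if len(set(names)) != len(names):
        raise ModelValidationError("model spec: duplicate factor names")
    controllable = [fs for fs in factor_specs if fs.get("controllable", False)]
    n_actions = len(controllable[0]["levels"]) if controllable else 1

    factors = []
    for fs in factor_specs:
        levels = tuple(fs["levels"])
        n = len(levels)
        trans = fs.get("transitions", "identity")
        if isinstance(trans, str) and trans == "identity":
            arr = np.broadcast_to(np.eye(n), (max(n_actions, 1), n, n)).copy()
        else:
            arr = np.asarray(trans, dtype=float)
        initial = fs.get("initial", "uniform")
        init = (
            CategoricalBelief.uniform(levels)
            if isinstance(initial, str) and initial == "uniform"
            else CategoricalBelief(levels, np.asarray(initial, dtype=float))
        )
        factors.append(
            StateFactor(
                name=fs["name"],
                levels=levels,
                transitions=TransitionMapping(fs["name"], arr),
                initial=init,
                controllable=fs.get("controllable", False),
            )
        )

    modalities = []
    for ms in modality_specs:
        try:
            parents = tuple(names.index(p) for p in ms["parents"])
        except ValueError:
            raise ModelValidationError(
                f"modality '{ms['name']}': unknown parent factor in {ms['parents']}"
            ) from None
        modalities.append(
            LikelihoodMapping(
                modality=ms["name"],
                array=np.asarray(ms["array"], dtype=float),
                parents=parents,
                outcomes=tuple(ms["outcomes"]),
            )
        )

    outcome_priors = {}
    for name, probs in spec.get("outcome_priors", {}).items():
        mod = next((m for m in modalities if m.modality == name), None)
        if mod is None:
            raise ModelValidationError(f"outcome prior for unknown modality '{name}'")
        outcome_priors[name] = CategoricalBelief(mod.outcomes, np.asarray(probs, dtype=float))

    prec_spec = spec.get("precision", {})
    pf_name = prec_spec.get("factor")
    precision_factor = names.index(pf_name) if pf_name is not None else None
    beta = prec_spec.get("beta_prior", 1.0)
    n_prec = len(factors[precision_factor].levels) if precision_factor is not None else 1
    betas = list(beta) if isinstance(beta, (list, tuple, np.ndarray)) else [beta] * n_prec
    precisions = tuple(PrecisionBelief(b, b) for b in betas)
    precision_modalities = frozenset(prec_spec.get("modalities", []))

    return GenerativeModel(
        factors=tuple(factors),
        modalities=tuple(modalities),
        outcome_priors=outcome_priors,
        precisions=precisions,
        precision_factor=precision_factor,
        precision_modalities=precision_modalities,
        horizon=int(spec.get("horizon", 1)),
        policy_depth=int(spec.get("policy_depth", 1)),
    )


def model_to_dict(model: GenerativeModel) -> dict:
    """Plain-dict form of a model; round-trips bit-for-bit through JSON."""
    names = [f.name for f in model.factors]
    return {
        "factors": [
            {
                "name": f.name,
                "levels": list(f.levels),
                "transitions": f.transitions.array.tolist(),
                "initial": f.initial.probs.tolist(),
                "controllable": f.controllable,
            }
            for f in model.factors
        ],
        "modalities": [
            {
                "name": m.modality,
                "parents": [names[p] for p in m.parents],
                "array": m.array.tolist(),
                "outcomes": list(m.outcomes),
            }
            for m in model.modalities
        ],
        "outcome_priors": {k: v.probs.tolist() for k, v in model.outcome_priors.items()},
        "precision": {
            "factor": names[model.precision_factor] if model.precision_factor is not None else None,
            "beta_prior": [p.beta_prior for p in model.precisions],
            "beta_posterior": [p.beta_posterior for p in model.precisions],
            "modalities": sorted(model.precision_modalities),
        },
        "horizon": model.horizon,
        "policy_depth": model.policy_depth,
    }


def model_from_dict(d: dict) -> GenerativeModel:
    model = build_model(d)
    post = d.get("precision", {}).get("beta_posterior")
    if post is not None:
        model = model.with_precisions(
            PrecisionBelief(p.beta_prior, b) for p, b in zip(model.precisions, post)
        )
    return model


def save_model(model: GenerativeModel, path) -> None:
    path = str(path)
    d = model_to_dict(model)
    with open(path, "w") as fh:
        if path.endswith((".yml", ".yaml")):
            yaml.safe_dump(d, fh, sort_keys=False)
        else:
            json.dump(d, fh, indent=1)


def load_model(path) -> GenerativeModel:
    path = str(path)
    with open(path) as fh:
        d = yaml.safe_load(fh) if path.endswith((".yml", ".yaml")) else json.load(fh)
    return model_from_dict(d)
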
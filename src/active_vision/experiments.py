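"""Configured scenario runners and fixtures.

Five headline scenarios probe how perceptual inference and sensory
precision depend on the confidence and correctness of prior beliefs:

Single level (10 saccades):

* ``matched_precise``   — confident prior that matches the world: the
  posterior agrees with both, precision barely moves.
* ``mismatched_vague``  — weakly held wrong prior: sensory evidence
  dominates, the posterior tracks the truth, precision barely moves.
* ``mismatched_precise`` — confidently held wrong prior: the prior
  dominates the percept and the conflict is resolved by a collapse of the
  expected sensory precision at the contradicted locations (the
  false-inference regime).

Hierarchical (epochs of 5 saccades under a scene library):

* ``healthy``  — uniform scene prior: the true scene is identified and
  confirmed empirical priors raise sensory precision, most at the start
  location.
* ``lesioned`` — the true scene's prior is zeroed (simulated loss of the
  neuronal population encoding it): a confident *wrong* scene is inferred,
  its empirical priors conflict with the sensory stream, and precision
  falls — a computational picture of hallucination with reduced sensory
  gain.  An optional rescue epoch pins fixation on the informative
  location to test whether persistent sampling corrects the percept.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import DEFAULT_ETA, EpochSchedule, run_hierarchical_trial
from .task import (
    DEFAULT_FIDELITY,
    N_FEATURES,
    N_LOCATIONS,
    SceneLibrary,
    WorldState,
    build_foraging_model,
    default_scene_library,
    lesion_scene_prior,
)
from .trial import TrialConfig, run_trial

SINGLE_LEVEL_VARIANTS = ("matched_precise", "mismatched_vague", "mismatched_precise")
HIERARCHICAL_VARIANTS = ("healthy", "lesioned")

#: Prior content shared by all three single-level variants: green circle
#: lower-left, blue lower-right, upper locations empty.
DEFAULT_PRIOR_PATTERN = (1, 2, 0, 0)
#: World used by the mismatched variants: differs from the prior pattern at
#: every location, so prior-sensory conflict is probed wherever the agent
#: looks.
DEFAULT_MISMATCHED_WORLD = (2, 0, 1, 2)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a scenario run."""

    scenario: str = "custom"
    prior_confident: float = 0.9995  # MAP mass of a "precise" (near-delta) prior
    prior_vague: float = 0.5        # MAP mass of an "imprecise" prior
    sensory_fidelity: float = DEFAULT_FIDELITY
    beta_prior: float = 1.0
    n_saccades: int = 10
    n_epochs: int = 3
    saccades_per_epoch: int = 5
    rescue_saccades: int = 10
    prior_pattern: tuple = DEFAULT_PRIOR_PATTERN
    mismatched_world: tuple = DEFAULT_MISMATCHED_WORLD
    true_scene: str = "LL-green"
    eta: float = DEFAULT_ETA
    small_change_frac: float = 0.25  # |dzeta|/zeta below this counts as "little change"
    seed: int = 0
    trial: TrialConfig = field(default_factory=TrialConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prior_pattern"] = list(self.prior_pattern)
        d["mismatched_world"] = list(self.mismatched_world)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def confident_prior(believed, confidence: float) -> np.ndarray:
    """(4, 3) feature priors with ``confidence`` on each believed value."""
    rest = (1.0 - confidence) / (N_FEATURES - 1)
    prior = np.full((N_LOCATIONS, N_FEATURES), rest)
    for loc, feat in enumerate(believed):
        prior[loc, feat] = confidence
    return prior


@dataclass
class RunSummary:
    """Deterministic digest of a trial record."""

    variant: str
    zeta_initial: np.ndarray
    zeta_final: np.ndarray
    map_prior: np.ndarray
    map_posterior: np.ndarray
    truth: np.ndarray
    contradicted: np.ndarray      # bool per location: prior MAP != truth
    zeta_change_frac: np.ndarray
    small_change_frac: float
    record: object = None
    scene_posteriors: list | None = None
    true_scene_index: int | None = None
    manifest: dict = field(default_factory=dict)

    # -- signature predicates -------------------------------------------
    @property
    def posterior_matches_truth(self) -> bool:
        return bool(np.array_equal(self.map_posterior, self.truth))

    @property
    def posterior_matches_prior(self) -> bool:
        return bool(np.array_equal(self.map_posterior, self.map_prior))

    @property
    def zeta_change_small(self) -> bool:
        return bool(np.all(np.abs(self.zeta_change_frac) < self.small_change_frac))

    @property
    def zeta_dropped_at_contradicted(self) -> bool:
        if not self.contradicted.any():
            return False
        return bool(
            np.all(self.zeta_change_frac[self.contradicted] < -self.small_change_frac)
        )

    @property
    def final_scene_posterior(self) -> np.ndarray:
        return self.scene_posteriors[-1]

    @property
    def inferred_scene_index(self) -> int:
        return int(np.argmax(self.final_scene_posterior))


def _summarize(variant, record, prior, truth, config, **extra) -> RunSummary:
    zeta = record.zeta_trajectory()
    post = record.final_feature_posteriors()
    z0 = np.full(N_LOCATIONS, 1.0 / config.beta_prior)
    zf = zeta[-1]
    return RunSummary(
        variant=variant,
        zeta_initial=z0,
        zeta_final=zf,
        map_prior=np.argmax(prior, axis=1),
        map_posterior=np.argmax(post, axis=1),
        truth=np.asarray(truth),
        contradicted=np.argmax(prior, axis=1) != np.asarray(truth),
        zeta_change_frac=(zf - z0) / z0,
        small_change_frac=config.small_change_frac,
        record=record,
        manifest={"config_hash": config.content_hash(), "seed": config.seed},
        **extra,
    )


def run_single_level(variant: str, config: ExperimentConfig | None = None) -> RunSummary:
    """Run one of the three single-level prior-precision scenarios."""
    config = config or ExperimentConfig()
    if variant not in SINGLE_LEVEL_VARIANTS:
        raise ValueError(f"unknown single-level variant '{variant}'")
    # The prior content is identical across variants; what changes is how
    # confidently it is held and whether the world agrees with it.
    confidence = (
        config.prior_vague if variant == "mismatched_vague" else config.prior_confident
    )
    truth = (
        config.prior_pattern if variant == "matched_precise" else config.mismatched_world
    )

    prior = confident_prior(config.prior_pattern, confidence)
    model = build_foraging_model(
        prior,
        beta_prior=config.beta_prior,
        horizon=config.n_saccades + 1,
        sensory_fidelity=config.sensory_fidelity,
    )
    world = WorldState(truth, fixation=0)
    record, *_ = run_trial(model, world, config.n_saccades, config.trial)
    record.manifest.update({"scenario": variant, "config": config.to_dict()})
    return _summarize(variant, record, prior, truth, config)


def run_hierarchical(
    variant: str,
    config: ExperimentConfig | None = None,
    *,
    rescue: bool = False,
    library: SceneLibrary | None = None,
    true_scene: str | None = None,
) -> RunSummary:
    """Run the healthy or lesioned hierarchical scenario."""
    config = config or ExperimentConfig()
    if variant not in HIERARCHICAL_VARIANTS:
        raise ValueError(f"unknown hierarchical variant '{variant}'")
    library = library or default_scene_library()
    scene_name = true_scene or config.true_scene
    scene_idx = library.index(scene_name)
    scene = library.scenes[scene_idx]
    if variant == "lesioned":
        library = lesion_scene_prior(library, scene_name)
    schedule = EpochSchedule(
        n_epochs=config.n_epochs,
        saccades_per_epoch=config.saccades_per_epoch,
        rescue_saccades=config.rescue_saccades if rescue else 0,
        rescue_fixation=int(np.argmax(np.array(scene.features) != 0))
        if any(scene.features)
        else 0,
    )
    world = scene.to_world(fixation=0)
    record, scene_posteriors = run_hierarchical_trial(
        library,
        world,
        schedule,
        config.trial,
        beta_prior=config.beta_prior,
        sensory_fidelity=config.sensory_fidelity,
        eta=config.eta,
    )
    record.manifest.update({"scenario": variant, "config": config.to_dict()})
    prior0 = (library.prior.probs @ _scene_onehots(library)).reshape(
        N_LOCATIONS, N_FEATURES
    )
    return _summarize(
        variant,
        record,
        prior0,
        scene.features,
        config,
        scene_posteriors=scene_posteriors,
        true_scene_index=scene_idx,
    )


def _scene_onehots(library: SceneLibrary) -> np.ndarray:
    """(n_scenes, n_locations * n_features) one-hot feature assignments."""
    fmap = library.feature_map()
    out = np.zeros((len(library), N_LOCATIONS * N_FEATURES))
    for m in range(len(library)):
        for loc in range(N_LOCATIONS):
            out[m, loc * N_FEATURES + fmap[m, loc]] = 1.0
    return out


# ---------------------------------------------------------------------------
# Fixtures and sweeps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    """A reproducible random world / prior / library bundle."""

    world: WorldState
    feature_priors: np.ndarray
    confidence: float
    library: SceneLibrary
    seed: int
    difficulty: str

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "difficulty": self.difficulty,
                "world_features": list(self.world.features),
                "fixation": self.world.fixation,
                "confidence": self.confidence,
                "feature_priors": self.feature_priors.tolist(),
                "library": [
                    {"name": s.name, "features": list(s.features)}
                    for s in self.library.scenes
                ],
                "library_prior": self.library.prior.probs.tolist(),
            },
            sort_keys=True,
        )


def generate_fixture(
    seed: int,
    difficulty: str = "random",
    *,
    confidence_range=(0.5, 0.98),
) -> Fixture:
    """Random world, prior-belief settings, and scene library.

    ``difficulty="conflict"`` guarantees at least one location where the
    prior MAP differs from the truth.
    """
    rng = np.random.default_rng(seed)
    features = tuple(int(f) for f in rng.integers(0, N_FEATURES, N_LOCATIONS))
    confidence = float(rng.uniform(*confidence_range))
    believed = list(features)
    if difficulty == "conflict":
        loc = int(rng.integers(0, N_LOCATIONS))
        believed[loc] = int((believed[loc] + 1 + rng.integers(0, N_FEATURES - 1)) % N_FEATURES)
    elif difficulty == "random":
        believed = [int(f) for f in rng.integers(0, N_FEATURES, N_LOCATIONS)]
    else:
        raise ValueError(f"unknown difficulty '{difficulty}'")
    priors = confident_prior(believed, confidence)
    return Fixture(
        world=WorldState(features, fixation=0),
        feature_priors=priors,
        confidence=confidence,
        library=default_scene_library(),
        seed=int(seed),
        difficulty=difficulty,
    )


def sweep_prior_precision(
    confidences, config: ExperimentConfig | None = None
) -> pd.DataFrame:
    """Posterior allegiance and precision change across prior confidence.

    For each confidence level, runs the mismatched-prior world and reports
    whether the posterior at contradicted locations follows the prior or
    the truth, and the fractional precision change there.  Below a
    crossover confidence the posterior tracks the truth; above it the prior
    wins and precision collapses.
    """
    config = config or ExperimentConfig()
    rows = []
    for c in confidences:
        cfg = dataclasses.replace(config, prior_vague=float(c))
        summary = run_single_level("mismatched_vague", cfg)
        mask = summary.contradicted
        rows.append(
            {
                "confidence": float(c),
                "posterior_matches_truth": bool(
                    np.all(summary.map_posterior[mask] == summary.truth[mask])
                ),
                "posterior_matches_prior": bool(
                    np.all(summary.map_posterior[mask] == summary.map_prior[mask])
                ),
                "dzeta_frac_contradicted": float(summary.zeta_change_frac[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


def crossover_confidence(sweep: pd.DataFrame) -> float | None:
    """Lowest confidence at which the prior wins at contradicted locations."""
    winners = sweep[sweep["posterior_matches_prior"]]
    return float(winners["confidence"].min()) if len(winners) else None
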
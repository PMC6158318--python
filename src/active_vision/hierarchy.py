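"""Two-level inference: scenes above, features-and-fixations below.

The second level holds a categorical belief over scenes (no policies,
identity dynamics — the scene is assumed constant).  Levels exchange
messages at epoch boundaries only, expressing the separation of temporal
scales: descending messages turn the scene belief into empirical priors
over the feature at each location; after a fixed number of saccades the
first level's feature posteriors ascend as soft evidence on scenes.
Sensory precision is reset to its prior whenever a new empirical prior is
issued.

Both directions use the same soft scene-to-feature map
``(1 - eta) * delta + eta / n_features``: ascending, it keeps a single
noisy belief from annihilating every scene; descending, it keeps lesioned
hypotheses' features merely improbable rather than impossible, so that
persistent contradictory evidence can still rescue the percept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import softmax

from .task import (
    DEFAULT_FIDELITY,
    N_FEATURES,
    N_LOCATIONS,
    SceneLibrary,
    WorldState,
    build_foraging_model,
)
from .trial import TrialConfig, TrialRecord, run_trial

#: Smoothing of the deterministic scene->feature assignment.
DEFAULT_ETA = 1e-3


@dataclass(frozen=True)
class EpochSchedule:
    """Epoch structure of a hierarchical trial.

    ``rescue_saccades``/``rescue_fixation``: optional extra final epoch in
    which every saccade is forced to one location, probing whether
    persistent sampling can correct a false percept.
    """

    n_epochs: int = 3
    saccades_per_epoch: int = 5
    rescue_saccades: int = 0
    rescue_fixation: int = 0

    def __post_init__(self):
        if self.n_epochs < 1 or self.saccades_per_epoch < 1:
            raise ValueError("EpochSchedule: epochs and saccades per epoch must be >= 1")


@dataclass
class HierarchicalBeliefState:
    """Scene posterior, the epoch index, and the latest level-1 record."""

    scene_posterior: np.ndarray
    epoch: int = 0
    level1: object = None


def _soft_assignment(library: SceneLibrary, eta: float) -> np.ndarray:
    """(n_scenes, n_locations, n_features) soft scene->feature map."""
    fmap = library.feature_map()
    M = np.full((len(library), N_LOCATIONS, N_FEATURES), eta / N_FEATURES)
    for m in range(len(library)):
        for loc in range(N_LOCATIONS):
            M[m, loc, fmap[m, loc]] += 1.0 - eta
    return M


def descend_empirical_prior(
    scene_posterior, library: SceneLibrary, *, eta: float = DEFAULT_ETA
) -> np.ndarray:
    """Empirical feature priors: the scene-belief-weighted feature map.

    Returns (n_locations, n_features), each row normalized.
    """
    q = np.asarray(scene_posterior, dtype=float)
    M = _soft_assignment(library, eta)
    prior = np.tensordot(q, M, axes=([0], [0]))
    return prior / prior.sum(axis=1, keepdims=True)


def ascend_evidence(
    feature_posteriors,
    library: SceneLibrary,
    scene_prior,
    *,
    eta: float = DEFAULT_ETA,
) -> np.ndarray:
    """Update the scene belief from first-level feature posteriors.

    ln q(m) is the log prior plus the posterior-weighted log probability of
    each location's feature under scene m's (eta-smoothed) assignment.
    Scenes with exactly zero prior stay at exactly zero — a lesioned
    hypothesis cannot be resurrected by evidence.
    """
    s = np.asarray(feature_posteriors, dtype=float)
    prior = np.asarray(scene_prior, dtype=float)
    M = _soft_assignment(library, eta)
    logev = np.tensordot(np.log(M), s, axes=([1, 2], [0, 1]))
    alive = prior > 0.0
    q = np.zeros(len(prior))
    q[alive] = softmax(np.log(prior[alive]) + logev[alive])
    return q


def reset_precision(precisions):
    """Posterior rates back to their priors; priors untouched. Idempotent."""
    return [p.reset() for p in precisions]


def run_hierarchical_trial(
    library: SceneLibrary,
    world: WorldState,
    schedule: EpochSchedule,
    config: TrialConfig | None = None,
    *,
    beta_prior=1.0,
    sensory_fidelity=None,
    eta: float = DEFAULT_ETA,
    initial_fixation: int = 0,
):
    """Run epochs of saccadic foraging under descending empirical priors.

    Per epoch: descend the scene belief into feature priors, reset the
    precision beliefs, run ``saccades_per_epoch`` steps of first-level
    active inference, then ascend the final feature posteriors into a new
    scene belief.  Returns ``(record, scene_posteriors)`` where
    ``scene_posteriors[k]`` is the belief after k epochs (entry 0 is the
    library prior).
    """
    config = config or TrialConfig()
    fidelity = DEFAULT_FIDELITY if sensory_fidelity is None else sensory_fidelity
    record = TrialRecord()
    scene_q = library.prior.probs.copy()
    scene_posteriors = [scene_q.copy()]

    epochs = [(schedule.saccades_per_epoch, None)] * schedule.n_epochs
    if schedule.rescue_saccades > 0:
        epochs.append(
            (schedule.rescue_saccades, [schedule.rescue_fixation] * schedule.rescue_saccades)
        )

    for epoch, (n_sacc, forced) in enumerate(epochs):
        priors = descend_empirical_prior(scene_q, library, eta=eta)
        model = build_foraging_model(
            priors,
            beta_prior=beta_prior,
            horizon=n_sacc + 1,
            sensory_fidelity=fidelity,
            initial_fixation=initial_fixation,
        )
        # Precision beliefs are created fresh from their priors each epoch
        # (the reset that accompanies every new empirical prior).
        model = model.with_precisions(reset_precision(model.precisions))
        world = WorldState(world.features, initial_fixation)

        start_row = len(record.rows)
        record, result, precisions, world = run_trial(
            model, world, n_sacc, config, forced_actions=forced, record=record, epoch=epoch
        )
        # Level-2 beliefs are constant within the epoch; log the belief that
        # generated this epoch's empirical prior on each of its rows.
        for row in record.rows[start_row:]:
            for m, qm in enumerate(scene_q):
                row[f"scene_post_{m}"] = float(qm)

        feature_post = np.array(
            [result.marginals[n_sacc][li] for li in range(N_LOCATIONS)]
        )
        scene_q = ascend_evidence(feature_post, library, scene_q, eta=eta)
        scene_posteriors.append(scene_q.copy())

    record.manifest.update(
        {
            "schedule": {
                "n_epochs": schedule.n_epochs,
                "saccades_per_epoch": schedule.saccades_per_epoch,
                "rescue_saccades": schedule.rescue_saccades,
                "rescue_fixation": schedule.rescue_fixation,
            },
            "eta": eta,
            "beta_prior": beta_prior,
        }
    )
    return record, scene_posteriors
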
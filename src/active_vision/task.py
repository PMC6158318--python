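"""The visual-foraging task: model builder, world, scenes, and lesions.

The scene is a 2x2 grid of features.  Each feature is a circle that is
absent (white), green, or blue; the agent foveates one location at a time
and saccades between them.  Hidden states: four feature factors (identity
dynamics — the scene is static within a trial) plus one controllable
fixation factor.  Outcomes: a visual modality reporting the feature at the
fixated location, and a proprioceptive modality reporting the fixation
itself.  Each location carries its own Gamma belief about sensory
precision, and only the visual modality is precision-modulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .model import (
    CategoricalBelief,
    GenerativeModel,
    ModelValidationError,
    build_model,
)

FEATURES = ("white", "green", "blue")
LOCATIONS = ("LL", "LR", "UL", "UR")
N_FEATURES = len(FEATURES)
N_LOCATIONS = len(LOCATIONS)

#: Default probability that the visual outcome reports the fixated feature.
#: Mildly below 1 so that likelihood columns have a finite log-gradient:
#: precision beliefs can then both rise under confirmation and fall under
#: conflict, and a 0.98-confident prior can outweigh a single glimpse.
DEFAULT_FIDELITY = 0.95


# ---------------------------------------------------------------------------
# Generative model (the agent's beliefs)
# ---------------------------------------------------------------------------

def visual_likelihood(fidelity: float = DEFAULT_FIDELITY) -> np.ndarray:
    """Visual A[o, fixation, f_LL, f_LR, f_UL, f_UR].

    P(o | states) = fidelity when o equals the feature at the fixated
    location, (1 - fidelity) / 2 otherwise.
    """
    if not (1.0 / N_FEATURES <= fidelity <= 1.0):
        raise ModelValidationError(f"sensory fidelity {fidelity} outside [1/3, 1]")
    off = (1.0 - fidelity) / (N_FEATURES - 1)
    A = np.full((N_FEATURES, N_LOCATIONS) + (N_FEATURES,) * N_LOCATIONS, off)
    feats = np.indices((N_FEATURES,) * N_LOCATIONS)
    for o in range(N_FEATURES):
        for loc in range(N_LOCATIONS):
            A[o, loc][feats[loc] == o] = fidelity
    return A


def build_foraging_model(
    feature_priors=None,
    *,
    beta_prior=1.0,
    horizon: int = 11,
    policy_depth: int = 1,
    sensory_fidelity: float = DEFAULT_FIDELITY,
    initial_fixation: int = 0,
) -> GenerativeModel:
    """Build the 5-factor, 2-modality foraging model.

    Parameters
    ----------
    feature_priors:
        (4, 3) array of prior beliefs over the feature at each location
        (rows sum to 1); default uniform.
    beta_prior:
        Gamma rate of the precision prior, scalar or one per location
        (expected prior precision is 1 / beta_prior).
    horizon:
        Number of timesteps (an initial observation plus horizon-1 saccades).
    """
    if feature_priors is None:
        feature_priors = np.full((N_LOCATIONS, N_FEATURES), 1.0 / N_FEATURES)
    feature_priors = np.asarray(feature_priors, dtype=float)
    if feature_priors.shape != (N_LOCATIONS, N_FEATURES):
        raise ModelValidationError(
            f"feature_priors must be {(N_LOCATIONS, N_FEATURES)}, got {feature_priors.shape}"
        )

    # The fixation factor is action-deterministic: a saccade to location u
    # lands at u from anywhere.
    B_fix = np.zeros((N_LOCATIONS, N_LOCATIONS, N_LOCATIONS))
    for u in range(N_LOCATIONS):
        B_fix[u, u, :] = 1.0

    factors = [
        {
            "name": f"feature_{loc}",
            "levels": list(FEATURES),
            "transitions": "identity",
            "initial": feature_priors[i].tolist(),
        }
        for i, loc in enumerate(LOCATIONS)
    ]
    factors.append(
        {
            "name": "fixation",
            "levels": list(LOCATIONS),
            "transitions": B_fix.tolist(),
            "initial": np.eye(N_LOCATIONS)[initial_fixation].tolist(),
            "controllable": True,
        }
    )

    A_vis = visual_likelihood(sensory_fidelity)
    # Reorder visual parents to (features..., fixation) axis order used below.
    A_vis = np.moveaxis(A_vis, 1, -1)

    spec = {
        "factors": factors,
        "modalities": [
            {
                "name": "vision",
                "parents": [f"feature_{loc}" for loc in LOCATIONS] + ["fixation"],
                "array": A_vis.tolist(),
                "outcomes": list(FEATURES),
            },
            {
                "name": "proprioception",
                "parents": ["fixation"],
                "array": np.eye(N_LOCATIONS).tolist(),
                "outcomes": list(LOCATIONS),
            },
        ],
        "precision": {
            "factor": "fixation",
            "beta_prior": (
                list(beta_prior)
                if isinstance(beta_prior, (list, tuple, np.ndarray))
                else float(beta_prior)
            ),
            "modalities": ["vision"],
        },
        "horizon": horizon,
        "policy_depth": policy_depth,
    }
    return build_model(spec)


# ---------------------------------------------------------------------------
# Generative process (the true world)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WorldState:
    """True feature at each location plus the current fixation.

    Features are constant across a trial (identity dynamics); outcomes are
    noiseless.
    """

    features: tuple[int, ...]
    fixation: int = 0

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(int(f) for f in self.features))
        if len(self.features) != N_LOCATIONS:
            raise ValueError(f"world needs {N_LOCATIONS} features, got {len(self.features)}")
        for f in self.features:
            if not 0 <= f < N_FEATURES:
                raise ValueError(f"invalid feature index {f}")
        if not 0 <= self.fixation < N_LOCATIONS:
            raise ValueError(f"invalid fixation location {self.fixation}")


def observe(world: WorldState) -> dict:
    """Noiseless outcomes at the current fixation."""
    return {
        "vision": world.features[world.fixation],
        "proprioception": world.fixation,
    }


def step_world(world: WorldState, action: int) -> tuple[WorldState, dict]:
    """Execute a saccade: fixation moves to the target, outcomes follow."""
    if not 0 <= int(action) < N_LOCATIONS:
        raise ValueError(f"invalid saccade target {action}")
    new = dataclasses.replace(world, fixation=int(action))
    return new, observe(new)


# ---------------------------------------------------------------------------
# Scenes (second-level hypotheses)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scene:
    """One second-level hypothesis: a feature value at every location."""

    name: str
    features: tuple[int, ...]

    def __post_init__(self):
        object.__setattr__(self, "features", tuple(int(f) for f in self.features))
        if len(self.features) != N_LOCATIONS:
            raise ValueError(f"scene '{self.name}' needs {N_LOCATIONS} feature values")

    def to_world(self, fixation: int = 0) -> WorldState:
        return WorldState(self.features, fixation)


@dataclass(frozen=True)
class SceneLibrary:
    """An ordered set of scenes with a prior belief over them."""

    scenes: tuple[Scene, ...]
    prior: CategoricalBelief

    def __post_init__(self):
        object.__setattr__(self, "scenes", tuple(self.scenes))
        if len(self.scenes) < 2:
            raise ModelValidationError("scene library needs at least 2 scenes")
        if self.prior.labels != tuple(s.name for s in self.scenes):
            raise ModelValidationError("scene prior labels must match scene names in order")

    def __len__(self) -> int:
        return len(self.scenes)

    def index(self, name: str) -> int:
        return self.prior.labels.index(name)

    def feature_map(self) -> np.ndarray:
        """(n_scenes, n_locations) array of feature indices."""
        return np.array([s.features for s in self.scenes], dtype=int)

    def with_prior(self, probs) -> "SceneLibrary":
        return SceneLibrary(self.scenes, CategoricalBelief(self.prior.labels, probs))


def default_scene_library() -> SceneLibrary:
    """Eight single-object scenes: one colored circle, everything else white.

    Ordering: (LL-green, LL-blue, LR-green, LR-blue, UL-green, UL-blue,
    UR-green, UR-blue), uniform prior.  The ordering is a documented
    convention so that named indices (e.g. the designated lesion target)
    are well-defined.
    """
    scenes = []
    for loc_i, loc in enumerate(LOCATIONS):
        for color in ("green", "blue"):
            feats = [FEATURES.index("white")] * N_LOCATIONS
            feats[loc_i] = FEATURES.index(color)
            scenes.append(Scene(f"{loc}-{color}", tuple(feats)))
    return SceneLibrary(tuple(scenes), CategoricalBelief.uniform([s.name for s in scenes]))


def lesion_scene_prior(library: SceneLibrary, scene) -> SceneLibrary:
    """Zero a scene's prior mass and renormalize the rest.

    ``scene`` may be an index or a scene name.  Simulates the loss of the
    neuronal population encoding that second-level hypothesis.
    """
    idx = library.index(scene) if isinstance(scene, str) else int(scene)
    if not 0 <= idx < len(library):
        raise ValueError(f"scene index {idx} out of range")
    p = library.prior.probs.copy()
    if p[idx] == 0.0:
        return library
    p[idx] = 0.0
    total = p.sum()
    if total <= 0:
        raise ValueError("cannot lesion the only scene with positive prior mass")
    return library.with_prior(p / total)


def format_scene(scene: Scene) -> str:
    """ASCII 2x2 grid of a scene (upper row first)."""
    sym = {0: ".", 1: "G", 2: "B"}
    ul, ur = sym[scene.features[2]], sym[scene.features[3]]
    ll, lr = sym[scene.features[0]], sym[scene.features[1]]
    return f"{scene.name}\n  {ul} {ur}\n  {ll} {lr}"
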
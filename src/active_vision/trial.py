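"""Single-level trial loop: observe, infer states, infer precision, saccade.

Each timestep the agent (1) receives outcomes at its fixation, (2) refreshes
state posteriors over the whole trial so far, (3) takes gradient steps on
the fixated location's precision belief and re-infers states under the new
expected precision, then (4) scores one-step policies by expected free
energy and saccades to the best target.  Everything is logged to a
:class:`TrialRecord` with one row per timestep.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import inference as inf
from .model import GenerativeModel
from .task import FEATURES, LOCATIONS, WorldState, observe, step_world


@dataclass
class TrialConfig:
    """Numerical knobs of the belief-update loop."""

    kappa: float = 1.0          # precision learning rate
    precision_steps: int = 4    # beta gradient steps per observation
    max_iterations: int = 16    # state-update sweeps
    tol: float = 1e-4           # state-update convergence tolerance
    damping: float = 1.0        # 1.0 = full coordinate updates
    policy_gamma: float = 1.0   # softmax temperature on -G
    allow_refixation: bool = False  # a saccade relocates gaze by default

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class TrialRecord:
    """Per-timestep log of a trial (or one epoch of a hierarchical trial)."""

    rows: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def append(self, **row) -> None:
        self.rows.append(row)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def zeta_trajectory(self) -> np.ndarray:
        """(n_steps, n_locations) expected precision after each step."""
        return np.array(
            [[r[f"zeta_{loc}"] for loc in LOCATIONS] for r in self.rows]
        )

    def final_feature_posteriors(self) -> np.ndarray:
        """(n_locations, n_features) marginals at the last logged step."""
        last = self.rows[-1]
        return np.array(
            [[last[f"post_{loc}_{feat}"] for feat in FEATURES] for loc in LOCATIONS]
        )

    def fixations(self) -> list:
        return [r["fixation"] for r in self.rows]

    def actions(self) -> list:
        return [r["action"] for r in self.rows if r["action"] is not None]


def run_trial(
    model: GenerativeModel,
    world: WorldState,
    n_saccades: int,
    config: TrialConfig | None = None,
    *,
    forced_actions=None,
    record: TrialRecord | None = None,
    epoch: int = 0,
):
    """Run ``n_saccades`` saccades (plus the initial observation).

    ``forced_actions`` overrides policy selection (used to pin fixation in
    rescue epochs).  Returns ``(record, result, precisions, world)`` — the
    log, the final inference result, the final per-location precision
    beliefs, and the final world state.
    """
    config = config or TrialConfig()
    record = record if record is not None else TrialRecord()
    precisions = list(model.precisions)
    policies = model.policies()
    fix_factor = model.controllable_factor
    vision = model.modality("vision")

    observations = []
    actions: list[int] = []
    result = None

    def infer():
        return inf.update_state_posteriors(
            model.with_precisions(precisions),
            observations,
            actions,
            max_iterations=config.max_iterations,
            tol=config.tol,
            damping=config.damping,
        )

    for t in range(n_saccades + 1):
        obs = observe(world)
        observations.append(obs)
        result = infer()

        # Precision inference at the fixated location only.  State and
        # precision beliefs descend their free-energy gradients together:
        # each beta step is followed by a state refresh under the new
        # expected precision, so the two estimates stay mutually consistent.
        loc = world.fixation
        target_axis = vision.parents.index(loc)  # feature factor at this location
        for _ in range(config.precision_steps):
            beliefs_t = result.marginals[t]
            parent_beliefs = [beliefs_t[p] for p in vision.parents]
            A_cols = inf.effective_columns(vision.array, parent_beliefs, target_axis)
            s = beliefs_t[vision.parents[target_axis]]
            precisions[loc] = inf.update_precision(
                A_cols,
                s,
                obs["vision"],
                precisions[loc],
                kappa=config.kappa,
                n_steps=1,
            )
            result = infer()

        # Policy evaluation and action selection.
        action = None
        G = None
        if t < n_saccades:
            candidates = policies
            if not config.allow_refixation:
                kept = [p for p in policies if p.actions[0] != world.fixation]
                candidates = kept or policies
            beliefs_now = result.marginals[t]
            Abar = inf.modulated_likelihoods(model.with_precisions(precisions))
            G = np.array(
                [
                    inf.expected_free_energy(model, beliefs_now, pol, Abar=Abar)
                    for pol in candidates
                ]
            )
            pi = inf.policy_posterior(G, gamma=config.policy_gamma)
            if forced_actions is not None:
                action = int(forced_actions[t])
            else:
                action = inf.select_action(pi, candidates)

        row = {
            "epoch": epoch,
            "step": t,
            "fixation": world.fixation,
            "obs_vision": obs["vision"],
            "obs_proprioception": obs["proprioception"],
            "action": action,
            "free_energy": result.free_energy,
            "converged": result.converged,
        }
        for li, locname in enumerate(LOCATIONS):
            row[f"zeta_{locname}"] = precisions[li].zeta
            marg = result.marginals[t][li]
            for fi, feat in enumerate(FEATURES):
                row[f"post_{locname}_{feat}"] = float(marg[fi])
        if G is not None:
            for pol, g in zip(policies, G):
                row[f"G_{LOCATIONS[pol.actions[0]]}"] = float(g)
        record.append(**row)

        if action is not None:
            world, _ = step_world(world, action)
            actions.append(action)

    return record, result, precisions, world
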
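# Methods

This note records the model, the numerical scheme, the parameter choices
that matter, and the limits of what the simulations show.

## Generative model

Hidden states factorize into four *feature* factors (one per location, each
with levels white/green/blue and identity dynamics — the scene is static
within a trial) and one *fixation* factor (four locations) whose
transitions are action-deterministic: a saccade to location u lands at u.
Two outcome modalities: **vision** reports the feature at the fixated
location through a likelihood with fidelity p (P(correct) = p, the
remainder split evenly; default p = 0.95, see below) and **proprioception**
reports fixation through an identity mapping. Outcome priors C are uniform
for both modalities, so policy selection is driven purely by uncertainty
resolution. Time is discrete saccade steps, 0-based internally and 1-based
in reports; the agent receives an observation at its initial (lower-left)
fixation, so a 10-saccade trial carries 11 observations.

Each location has its own sensory precision ζ with Gamma(1, β) prior and
posterior beliefs; E[ζ] = 1/β exactly. Only the visual likelihood is
precision-modulated, Ā = softmax(ζ ln A) column-wise, computed with the
fixated location's current expected ζ. Probabilities are floored at
ε = 1e-16 before any logarithm; the floor is part of the model semantics
because identity mappings contain exact zeros.

The generative *process* (the world) is noiseless: the visual outcome
always equals the true feature at fixation. Only beliefs are manipulated
across conditions, never world noise.

## State inference

Beliefs over states are updated by structured variational inference: the
posterior over each factor's whole trajectory is kept as a chain, and a
coordinate update refreshes one factor at a time by exact forward–backward
smoothing against pseudo-likelihoods exp(E_others[ln Ā]). Each refresh is
the exact minimizer of F over that factor's chain, so free energy is
non-increasing across sweeps (asserted in tests to 1e-6), and the scheme is
exact whenever the true posterior factorizes across factors — in
particular on single-factor models, where it reproduces brute-force
enumeration to machine precision, and on the foraging task itself, where
the observed fixation sequence decouples the feature factors. Defaults: at
most 16 sweeps, convergence when the largest marginal change falls below
1e-4, full (undamped) coordinate updates; a geometric damping knob exists
for stiff custom models. A naive fully factorized mean-field update was
rejected: with identity transitions and floored logs its fixed points
collapse static-factor beliefs toward deltas (the familiar mean-field
overconfidence), which breaks agreement with exact Bayes.

## Precision inference

For the fixated location, β takes gradient steps on the ζ-gradient of the
assembled free energy for the current observation,

dF/dζ = −Σⱼ sⱼ ln A_oj + Σⱼ sⱼ Σₖ Āₖⱼ(ζ) ln Aₖⱼ + (β₀ − β),

where the last term is the ζ-derivative of KL[Gamma(1, β) ‖ Gamma(1, β₀)].
The update is β ← β + κ·dF/dζ (a preconditioned descent: dF/dβ and dF/dζ
differ by the positive factor 1/β²), clipped below at 1e-6, with κ = 1 and
4 steps per observation. Each β step is followed by a state re-inference at
the new expected precision, so the two gradient flows stay mutually
consistent — with a frozen posterior, the first step would see a belief
already loosened by full-gain evidence and the conflict response would
bottom out too shallow. The analytic gradient is validated against central
differences of the assembled free energy (1e-5 relative, 100+ random
models, in both the test suite and the acceptance script).

Consequences of this gradient, all verified numerically:

- An observation matching a confident prediction *raises* ζ toward an
  equilibrium where the confirmation drive balances the prior pull (~ +13%
  per well-sampled location at p = 0.95).
- An observation contradicting a precise belief *collapses* ζ (~ −65% and
  deeper under sustained conflict).
- With a uniform posterior (no prediction), ζ *falls*: by Jensen's
  inequality the expected log-likelihood of any observation under a
  uniform belief is maximized as ζ → 0, so an agent without predictions
  rationally turns its sensory gain down.

## Policy selection

Policies are single saccades to each location, re-evaluated after every
saccade (receding horizon of depth 1; depth is a config parameter).
G sums, per modality, the risk o·(ln o − ln C) and the expected ambiguity
−H·s of the precision-modulated likelihood; with uniform C this equals a
constant minus the mutual information between states and predicted
outcomes. Policy posterior is softmax(−G) at unit temperature (no separate
policy-precision machinery), action selection is argmax with deterministic
tie-break to the lowest location index, and re-fixation of the current
location is excluded by default — a saccade relocates gaze; forced-fixation
schedules bypass selection, so persistent re-fixation remains expressible.
Runs are therefore fully deterministic given a configuration; random seeds
enter only through fixture generation.

## Hierarchy

The second level holds a categorical belief over scenes (eight single-object
hypotheses by default: one green or blue circle at one location, uniform
prior; ordering LL-green, LL-blue, LR-green, LR-blue, UL-green, UL-blue,
UR-green, UR-blue). It has no policies and identity dynamics. Levels
exchange messages only at epoch boundaries (default 3 epochs × 5 saccades),
expressing the separation of temporal scales. Both directions use the same
soft scene→feature map (1 − η)·δ + η/3 with η = 1e-3: ascending, it
prevents a single noisy belief from annihilating every scene; descending,
it keeps a lesioned hypothesis's features merely ~8 nats improbable rather
than impossible, which is what allows persistent fixation to rescue the
percept. Scenes with exactly zero prior stay at exactly zero in the
ascending update — evidence cannot resurrect a lesioned hypothesis.
Precision beliefs reset to their priors whenever a new empirical prior is
issued; the prior on precision is not conditioned on second-level states
(a deliberate non-goal), so precision estimates cannot outlive an epoch.

## Calibration of the study conditions

Three parameter choices were genuinely open and are worth recording:

- **Sensory fidelity p = 0.95 (not 1).** With a floored delta likelihood,
  a confirmed observation has an essentially zero ζ-gradient (no precision
  rise under confirmed priors) and a single glimpse carries ln(1/ε) ≈ 37
  nats (no finite prior can ever dominate). A mildly dispersed likelihood
  gives both regimes finite scales: per-glimpse evidence ζ·ln(p/q) ≈ 3.6
  nats at ζ = 1, and a finite positive confirmation gradient.
- **Precise-prior confidence 0.9995.** After the conflict-driven collapse,
  each glimpse still carries ~1.2–1.3 nats (the ratio of evidence to crash
  depth is nearly invariant to p, because both scale with the same
  log-likelihood contrast). The epistemic agent gives each contradicted
  location up to ~5 glimpses in 10 saccades, so prior log-odds must exceed
  ~7.5 nats for the prior to dominate a whole trial. This is the
  quantitative content of "a very precise prior": weaker confident priors
  (e.g. 0.98) are overturned by the third glimpse — more data genuinely
  wins, which is also what makes the rescue epoch work.
- **Mismatch at all four locations.** Contradicted locations retain the
  highest expected information gain, so if only one or two locations
  disagreed with the prior, the agent would concentrate its spare saccades
  there and accumulate flipping evidence; with the conflict spread over
  all four, visits spread too (3–5 per location). The prior *content* is
  identical across the three single-level variants; only its confidence
  and the world change.

Interpretive thresholds: "little change" in ζ is |Δζ|/ζ₀ < 25%, "decrease"
is Δζ/ζ₀ < −25%; both config-exposed. β₀ = 1 (prior E[ζ] = 1) per location.

## What the simulations do and do not show

The synthetic worlds are static 2x2 scenes with noiseless outcomes; the
scene library is a small discrete hypothesis space. Passing tests show that
the *belief dynamics* — precision collapse under precise-wrong priors,
hierarchical transmission of confident false empirical priors after a
lesion, rescue by persistent sampling — follow from the stated free-energy
gradients. They do not show anything about richer scenes (multiple objects,
occlusion), saccade kinematics, learning of likelihood or transition
parameters (no Dirichlet updates), continuous-time formulations, or
quantitative fits to human eye-tracking data; those are out of scope. The
number and ordering of scene hypotheses is a convention; results are stated
by scene name, not index, wherever possible. Problem sizes used throughout
(10-saccade trials, 2–3 epochs of 5 saccades, 50-draw recovery statistics,
100-model gradient checks, 3-state/3-step enumeration toys) keep every
check exact or tightly converged at negligible cost.

## Degenerate inputs and numerical conventions

Validation rejects non-stochastic arrays, dangling factor references and
non-positive Gamma rates by name. ζ = 0 is legal (uniform likelihood;
posterior equals prior); ζ → ∞ is reached in practice by large finite
values (ζ = 50 is deterministic to 1e-6). Exact ties in G are broken by
location index; ties in the "largest precision rise at the start location"
statement can occur between equally-sampled locations and are treated as
satisfying it. Non-convergence of the state updates raises a warning and
returns the last iterate with a `converged=False` flag in the trial record.
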
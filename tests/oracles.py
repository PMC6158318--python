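"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's inference code paths: posteriors are
computed by exhaustive enumeration of state sequences, expected free energy
by explicit loops, and gradients by central differences.
"""

import itertools

import numpy as np


def enumerate_posterior(D, B_seq, A, obs):
    """Exact smoothing marginals and log evidence for a single-factor chain.

    D: initial prior (n,);  B_seq: list of (n, n) transition matrices
    B[next, prev] for steps 0..T-2;  A: (n_out, n) likelihood;  obs: list of
    outcome indices per timestep (may be shorter than T).
    Returns (marginals (T, n), log_evidence).
    """
    T = len(B_seq) + 1
    n = len(D)
    marg = np.zeros((T, n))
    Z = 0.0
    for seq in itertools.product(range(n), repeat=T):
        w = D[seq[0]]
        if len(obs) > 0:
            w *= A[obs[0], seq[0]]
        for t in range(1, T):
            w *= B_seq[t - 1][seq[t], seq[t - 1]]
            if t < len(obs):
                w *= A[obs[t], seq[t]]
        Z += w
        for t in range(T):
            marg[t, seq[t]] += w
    return marg / Z, float(np.log(Z))


def expected_free_energy_loops(Abar, C, s_next):
    """One-modality, one-step G by explicit loops over states and outcomes.

    Abar: (n_out, n_states); C: outcome prior (n_out,); s_next: predicted
    state belief (n_states,).  Risk + expected ambiguity.
    """
    n_out, n_states = Abar.shape
    o = np.zeros(n_out)
    for i in range(n_out):
        for j in range(n_states):
            o[i] += Abar[i, j] * s_next[j]
    risk = 0.0
    for i in range(n_out):
        if o[i] > 0:
            risk += o[i] * (np.log(o[i]) - np.log(max(C[i], 1e-16)))
    amb = 0.0
    for j in range(n_states):
        H_j = 0.0
        for i in range(n_out):
            if Abar[i, j] > 0:
                H_j += Abar[i, j] * np.log(Abar[i, j])
        amb += -H_j * s_next[j]
    return risk + amb


def numerical_zeta_gradient(free_energy_fn, zeta, h=1e-5):
    """Central-difference derivative of a free energy in zeta."""
    return (free_energy_fn(zeta + h) - free_energy_fn(zeta - h)) / (2 * h)
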
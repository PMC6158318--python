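"""Optional figure output: belief grids and precision trajectories.

Correctness is always asserted on logged numbers, never on images; these
plots exist for inspection only.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .task import FEATURES, LOCATIONS


def plot_zeta(record, ax=None):
    """Expected sensory precision per location across the trial."""
    ax = ax or plt.gca()
    zeta = record.zeta_trajectory()
    for li, loc in enumerate(LOCATIONS):
        ax.plot(zeta[:, li], label=loc)
    ax.set_xlabel("step")
    ax.set_ylabel(r"expected precision $\zeta$")
    ax.legend(fontsize=8)
    return ax


def plot_beliefs(record, ax=None):
    """Final feature posteriors as a 2x2 grid of RGB patches.

    Green/blue channel intensity encodes the posterior probability of the
    corresponding feature; near-white means 'absent' dominates.
    """
    ax = ax or plt.gca()
    post = record.final_feature_posteriors()
    img = np.ones((2, 2, 3))
    layout = {"LL": (1, 0), "LR": (1, 1), "UL": (0, 0), "UR": (0, 1)}
    for li, loc in enumerate(LOCATIONS):
        r, c = layout[loc]
        p_green = post[li, FEATURES.index("green")]
        p_blue = post[li, FEATURES.index("blue")]
        img[r, c] = [1 - p_green - p_blue + p_green * 0, 1 - p_blue, 1 - p_green]
    ax.imshow(img, vmin=0, vmax=1)
    ax.set_xticks([])
    ax.set_yticks([])
    return ax


def save_run_figure(record, path):
    fig, axes = plt.subplots(1, 2, figsize=(8, 3))
    plot_zeta(record, axes[0])
    plot_beliefs(record, axes[1])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
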
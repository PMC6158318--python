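import numpy as np
import pytest

from active_vision import build_model, build_foraging_model


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def foraging_model():
    return build_foraging_model()


def random_chain_spec(rng, n=3, n_out=3, T=3, n_actions=2, with_zeros=False):
    """A random single-factor controllable chain model spec."""
    A = rng.dirichlet(np.ones(n_out), size=n).T
    Bs = np.stack([rng.dirichlet(np.ones(n), size=n).T for _ in range(n_actions)])
    D = rng.dirichlet(np.ones(n))
    if with_zeros:
        A[0, 0] = 0.0
        A[:, 0] /= A[:, 0].sum()
        Bs[0] = np.eye(n)
    return {
        "factors": [
            {
                "name": "state",
                "levels": [f"s{i}" for i in range(n)],
                "transitions": Bs.tolist(),
                "initial": D.tolist(),
                "controllable": True,
            }
        ],
        "modalities": [
            {
                "name": "obs",
                "parents": ["state"],
                "array": A.tolist(),
                "outcomes": [f"o{i}" for i in range(n_out)],
            }
        ],
        "horizon": T,
    }


@pytest.fixture
def chain_model_factory(rng):
    def make(seed=None, **kw):
        r = np.random.default_rng(seed) if seed is not None else rng
        spec = random_chain_spec(r, **kw)
        return build_model(spec), spec

    return make
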
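import numpy as np
import pytest

from sgm.model import PARAM_BOUNDS, PARAM_NAMES, SGMParams, is_stable
from sgm.synth import gen_connectome


@pytest.fixture(scope="session")
def conn10():
    return gen_connectome(10, density=0.5, seed=4)


@pytest.fixture(scope="session")
def conn12():
    return gen_connectome(12, density=0.5, seed=7)


@pytest.fixture(scope="session")
def conn20():
    return gen_connectome(20, density=0.4, seed=3)


@pytest.fixture(scope="session")
def conn86():
    return gen_connectome(86, density=0.3, seed=1)


@pytest.fixture(scope="session")
def table1_params():
    """First optimizer starting point (a known-stable parameter set)."""
    return SGMParams(tau_e=15, tau_i=10, alpha=1.0, v=5, g_ei=0.3, g_ii=0.6, tau_G=6)


def draw_uniform_params(rng: np.random.Generator) -> SGMParams:
    return SGMParams(**{n: rng.uniform(*PARAM_BOUNDS[n]) for n in PARAM_NAMES})


def draw_stable_uniform(rng: np.random.Generator, max_tries: int = 200) -> SGMParams:
    for _ in range(max_tries):
        p = draw_uniform_params(rng)
        if is_stable(p):
            return p
    raise RuntimeError("no stable draw")
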
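import numpy as np
import pytest

import mixamount as mx
from mixamount.design import Design, DesignPoint


@pytest.fixture(scope="session")
def paper_config():
    """Canonical five-phenolic study configuration."""
    return mx.paper_study_config(seed=1)


@pytest.fixture(scope="session")
def paper_design(paper_config):
    """The 100-run blocked design, built once per session (seed 1)."""
    return paper_config.build_design(seed=1)


@pytest.fixture(scope="session")
def quad_lin_terms():
    """Quadratic-mixture x linear-amount crossed terms for 5 components."""
    return mx.enumerate_terms(5, 2, 1)


@pytest.fixture
def space3():
    return mx.ComponentSpace(("A", "B", "C"))


@pytest.fixture
def factor():
    return mx.AmountFactor("amt", 75.0, 225.0)


def make_small_design(seed=0, n_unique=12, n_dup=2, n_blocks=2, q=3):
    """A small replicated random design for oracle comparisons."""
    rng = np.random.default_rng(seed)
    space = mx.ComponentSpace(tuple("ABCDE"[:q]))
    fac = mx.AmountFactor("amt", 10.0, 30.0)
    P = rng.dirichlet(np.ones(q), n_unique)
    P = np.vstack([P, P[:n_dup]])
    amts = fac.decode(rng.choice([-1.0, 0.0, 1.0], len(P)))
    pts = [
        DesignPoint(tuple(P[i]), float(amts[i]), int(i % n_blocks), "model")
        for i in range(len(P))
    ]
    return Design(pts, space, fac, n_blocks)


@pytest.fixture
def small_design():
    return make_small_design()
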
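import logging

import numpy as np
import pytest

import dmckit as dk
from dmckit.cg_sim import SimParams, make_pull_protocol, run_pulling

# the protocol helper logs every loading-rate rescale; keep test output quiet
logging.getLogger("dmckit.cg_sim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_build():
    """A small tetrahedron analog: 8 bp edges, 3 FB pairs (96 beads)."""
    return dk.build_tetrahedron(dk.TetraDesign(edge_bp=8, fb_bp=3))


@pytest.fixture(scope="session")
def pull_run(small_build):
    """A pulling run through rupture on the small analog, with its protocol.

    Shared across modules: the force curve, the bond-event log and the
    post-rupture frames all come from this single trajectory.
    """
    params = SimParams(seed=5, n_steps=150_000, stride=500)
    protocol = make_pull_protocol(small_build, params, pull_distance=60.0,
                                  stiffness=11.42)
    result = run_pulling(small_build, params, protocol)
    return small_build, params, protocol, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
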
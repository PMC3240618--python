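"""Shared fixtures: the default model and the expensive reference runs are
built once per session and reused across test modules."""

import numpy as np
import pytest

from spinesim.model import build_model
from spinesim.protocols import SimulationConfig, make_protocol, run


@pytest.fixture(scope="session")
def model():
    return build_model()


@pytest.fixture(scope="session")
def run_5x50_mglur(model):
    """Five releases at 50 Hz, mGluRI only, 100 nm — the spine calcium
    calibration protocol."""
    proto = make_protocol("train", frequency=50.0, n_pulses=5)
    return run(model, proto, SimulationConfig(receptors="mglur",
                                              mglur_location_nm=100.0,
                                              post_stimulus=15.0))


@pytest.fixture(scope="session")
def run_single_all(model):
    """One release, all receptors, mGluRI at 100 nm."""
    return run(model, make_protocol("single"),
               SimulationConfig(receptors="all", post_stimulus=10.0))


@pytest.fixture(scope="session")
def tbs9_runs(model):
    """9-TBS and single-release runs used by the frequency/location AUC
    analyses: mGluRI-only at both locations plus full-model 9-TBS at both."""
    out = {}
    for loc in (100.0, 1000.0):
        for pname in ("single", "tbs9"):
            proto = make_protocol(pname)
            out[("mglur", pname, loc)] = run(
                model, proto, SimulationConfig(receptors="mglur",
                                               mglur_location_nm=loc))
        out[("all", "tbs9", loc)] = run(
            model, make_protocol("tbs9"),
            SimulationConfig(receptors="all", mglur_location_nm=loc))
    return out


def rng(seed=0):
    return np.random.default_rng(seed)
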
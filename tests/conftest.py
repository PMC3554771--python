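"""Shared fixtures: screen-grade solver config and session-scoped screens.

The scaled screens are computed once per session and shared between the
statistical and property tests; their sizes are chosen so the whole suite
runs on one CPU in well under the integration budget.
"""

import numpy as np
import pytest

from mapkscreen.config import RunConfig, SolverConfig
from mapkscreen.fixtures import make_fixture
from mapkscreen.network import build_network
from mapkscreen.sampling import ScreenDesign, run_screen

#: classification-grade solver: the indicators threshold at 0.1 / 1.0 / 1.5,
#: so 1e-7 relative accuracy is ample and screens run ~3x faster
SCREEN_SOLVER = SolverConfig(rtol=1e-7, atol=1e-9, ss_tol=1e-8)

TEST_SEED = 202


@pytest.fixture(scope="session")
def screen_config() -> RunConfig:
    return RunConfig(solver=SCREEN_SOLVER)


@pytest.fixture(scope="session")
def networks():
    return {t: build_network(t) for t in ("none", "positive", "negative")}


@pytest.fixture(scope="session")
def fixture_catalog():
    return {name: make_fixture(name)
            for name in ("quiescent", "linear-responder", "ultrasensitive",
                         "bistable", "oscillator", "transient")}


@pytest.fixture(scope="session")
def classify_screen(screen_config):
    """36 x 100 x 3 responsiveness/temporal screen at saturating S = 10."""
    design = ScreenDesign.generate(100, seed=TEST_SEED)
    return design, run_screen(design, screen_config, full=False)


@pytest.fixture(scope="session")
def full_screen(screen_config):
    """36 x 25 x 3 screen with dose-response indicators."""
    design = ScreenDesign.generate(25, seed=TEST_SEED)
    return design, run_screen(design, screen_config, full=True)


@pytest.fixture(scope="session")
def low_stimulus_screen(screen_config):
    """36 x 50 x 3 classification screen at weak stimulus S_max = 1.0.

    Uses the same seed as the saturating-stimulus screen, so its 50 rate
    vectors are exactly the first 50 of that screen's 100.
    """
    import dataclasses
    cfg = dataclasses.replace(screen_config, s_max=1.0)
    design = ScreenDesign.generate(50, seed=TEST_SEED)
    return design, run_screen(design, cfg, full=False)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
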
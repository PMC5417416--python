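"""Shared fixtures.

The expensive simulations (full-sheet onset demos, the deterministic
excitability sweep, tracking and surgery runs) are session-scoped so the
acceptance-style tests and the property tests share them.
"""

import numpy as np
import pytest

import ictalsheet as ish
from ictalsheet.model_core import DEFAULT_Q

DEMO_SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def geom20():
    return ish.SheetGeometry(n_rows=20, n_cols=20)


@pytest.fixture(scope="session")
def geom30():
    return ish.SheetGeometry(n_rows=30, n_cols=30)


@pytest.fixture(scope="session")
def conn30(geom30):
    return ish.build_connectivity(geom30, ish.ConnectivityConfig(seed=1))


@pytest.fixture(scope="session")
def conn20(geom20):
    return ish.build_connectivity(geom20, ish.ConnectivityConfig(seed=1))


@pytest.fixture(scope="session")
def demo_runs():
    """Full-sheet LAF and HAS onset demos, three seeds each."""
    out = {}
    for preset in ("LAF", "HAS"):
        for seed in DEMO_SEEDS:
            out[(preset, seed)] = ish.run_onset_demo(preset, seed=seed,
                                                     stride=2)
    return out


@pytest.fixture(scope="session")
def band_labels():
    """Deterministic state labels over the P grid of the excitability sweep."""
    grid = np.round(np.arange(-4.0, 0.01, 0.1), 10)
    return {float(P): ish.classify_state(float(P)).label for P in grid}


@pytest.fixture(scope="session")
def tracking_runs():
    return {seed: ish.run_excitability_tracking(seed=seed)
            for seed in DEMO_SEEDS}


@pytest.fixture(scope="session")
def surgery_run():
    return ish.run_surgery_experiment(seed=1)


@pytest.fixture(scope="session")
def quiet_run(conn30, geom30):
    """A noisy background run with no scheduled events (pure baseline)."""
    return ish.simulate(ish.DEFAULT_PARAMS, conn30, ish.EventSchedule(),
                        10000.0, ish.NoiseModel(seed=21), geometry=geom30,
                        stride=2,
                        P=ish.ParameterField.uniform(geom30, -2.5),
                        Q=ish.ParameterField.uniform(geom30, DEFAULT_Q,
                                                     name="Q"))
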
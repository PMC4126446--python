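import dataclasses

import numpy as np
import pytest

from lobulesim import engine, io_cli


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def seven_lobule_config():
    return io_cli.make_fixture("seven_lobule")


@pytest.fixture(scope="session")
def small_config():
    """A fast 2x2 configuration for engine-level tests."""
    cfg = engine.SimulationConfig(
        geometry=engine.GeometryConfig(n_rows=2, n_cols=2, hex_side=6.0,
                                       cell_diameter=1.0,
                                       septum_thickness=0.3),
        injury=dataclasses.replace(engine.InjuryConfig(), radius=2.5),
        run=engine.RunConfig(n_steps=40, seed=7, replicates=1,
                             measure_elastography=False),
    )
    return cfg


@pytest.fixture
def small_state(small_config):
    return engine.initialize(small_config, seed=7)
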
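import numpy as np
import pytest

import stripquant as sq


@pytest.fixture(scope="session")
def geometry():
    return sq.StripGeometry()


@pytest.fixture(scope="session")
def kinetics():
    return sq.KineticsParams()


@pytest.fixture(scope="session")
def config(geometry, kinetics):
    return sq.config_for(geometry, kinetics)


@pytest.fixture(scope="session")
def small_geometry():
    """A reduced cartridge for fast per-operation tests."""
    return sq.StripGeometry(image_height_px=60, image_width_px=160,
                            membrane_rows=(14, 46), membrane_cols=(12, 148),
                            test_line_center=80, control_line_center=112,
                            line_width_px=12)


@pytest.fixture(scope="session")
def clean_stack(geometry, kinetics):
    """A defect-free acquisition covering flow and line development."""
    return sq.generate_stack(geometry, kinetics, duration_s=360, seed=42)


@pytest.fixture(scope="session")
def clean_flow(clean_stack, config):
    return sq.analyze_flow(clean_stack, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
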
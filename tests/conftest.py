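import numpy as np
import pytest

from chiralquant.simulate import MatrixSpec, StudyDesign, example_panel


@pytest.fixture(scope="session")
def panel():
    """Small representative analyte panel with deuterated internal standards."""
    return example_panel()


@pytest.fixture
def analytes(panel):
    return panel[0]


@pytest.fixture
def istds(panel):
    return panel[1]


@pytest.fixture
def river_water(analytes):
    """River-water matrix: 80% recovery and 10% suppression for analytes,
    clean behaviour (defaults) for the internal standards."""
    channels = [c for a in analytes for c, _, _ in a.channels()]
    return MatrixSpec(
        matrix_id="river_water",
        recovery_fraction={c: 0.8 for c in channels},
        suppression_percent=10.0,
    )


@pytest.fixture
def design():
    return StudyDesign(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
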
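import numpy as np
import pandas as pd
import pytest

from cosanftirm.spectra import SpectrumSet
from cosanftirm.synth import default_model


@pytest.fixture
def small_grid():
    """Coarse full-range grid, 2 cm^-1 spacing (the synthetic default)."""
    return np.arange(800.0, 4000.0 + 1e-9, 2.0)


@pytest.fixture
def two_group_model():
    """Low-noise control-vs-treated model for end-to-end tests."""
    return default_model(seed=123, noise_sd=0.005)


def make_set(wavenumbers, rows, cell_line="GIC7", treatment="control"):
    """Assemble a SpectrumSet with auto-numbered sample ids."""
    rows = np.atleast_2d(np.asarray(rows, float))
    labels = pd.DataFrame({
        "cell_line": [cell_line] * rows.shape[0],
        "treatment": [treatment] * rows.shape[0],
        "sample_id": [f"s{i}" for i in range(rows.shape[0])],
    })
    return SpectrumSet(wavenumbers, rows, labels)
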
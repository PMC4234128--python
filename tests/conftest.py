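import numpy as np
import pandas as pd
import pytest

import gfresponse as gf
from gfresponse.io import CUBE_COLUMNS


@pytest.fixture(scope="session")
def zero_noise_panel():
    """Small noiseless panel: planted classes are exactly recoverable."""
    return gf.generate_panel(n_cell_lines=4, n_ligands=2, seed=11, sigma=0.0)


@pytest.fixture(scope="session")
def noisy_panel():
    """Small panel at the default noise level."""
    return gf.generate_panel(n_cell_lines=8, n_ligands=5, seed=7)


@pytest.fixture(scope="session")
def noisy_responses(noisy_panel):
    return gf.compute_fold_changes(noisy_panel.cube)


@pytest.fixture()
def tiny_cube():
    """Hand-built cube: controls {2.0, 2.0}, levels 2.0/2.5/2.3 at 10/30/90 min."""
    rows = [
        ("A", "control", np.nan, 0, "pERK", 1, 2.0),
        ("A", "control", np.nan, 0, "pERK", 2, 2.0),
        ("A", "EGF", 100.0, 10, "pERK", 1, 2.0),
        ("A", "EGF", 100.0, 30, "pERK", 1, 2.5),
        ("A", "EGF", 100.0, 90, "pERK", 1, 2.3),
    ]
    return gf.ResponseCube(pd.DataFrame(rows, columns=CUBE_COLUMNS))
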
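import numpy as np
import pytest

import scramfit as sf


@pytest.fixture
def ideal_params():
    """Ideal dithionite assay: symmetric NBD, full-pool reduction, no noise."""
    return sf.DithioniteAssayParams(F0_target=50.0, Fmax_target=100.0, noise_sd=0.0)


@pytest.fixture
def t_grid():
    return np.arange(0.0, 650.5, 0.5)


@pytest.fixture
def protein_free_population():
    radii = sf.sample_radii(500, 100.8, 32.8, seed=11)
    return sf.assign_scramblases(radii, ppr=0.0, M=80_800.0, seed=12)


@pytest.fixture
def linear_calibration():
    """Exact pyranine calibration matching the simulator's forward map."""
    ph = np.array([6.0, 6.5, 7.0, 7.5, 8.0])
    return sf.PyranineCalibration().fit(ph, 100.0 * ph - 400.0)
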
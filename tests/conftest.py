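import numpy as np
import pytest

from mbspec import PreprocessConfig
from mbspec.spectra import Spectrum
from mbspec import synth


@pytest.fixture(scope="session")
def pp_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture(scope="session")
def fingerprint_grid() -> np.ndarray:
    return np.arange(800.0, 1801.0)


@pytest.fixture(scope="session")
def default_cohort():
    """Default-size simulated cohort (4/21/5/14 x 3 replicates, seed 1)
    with the carbonyl-band dynamics signature injected at magnitude 5."""
    return synth.synth_cohort(
        noise=synth.NoiseModel(seed=1),
        signature=(synth.SIGNATURE_BAND, 5.0),
    )


@pytest.fixture(scope="session")
def processed_cohort(default_cohort, pp_config):
    from mbspec.preprocess import preprocess_set

    return preprocess_set(default_cohort, pp_config)


@pytest.fixture(scope="session")
def noiseless_group_means():
    """Noiseless per-group forward-model spectra on the canonical grid."""
    return {
        g: synth.synth_spectrum(
            synth.make_group_profile(g), synth.NOISELESS, sample_id=f"mean_{g}"
        )
        for g in ("control", "classic", "desmoplastic", "anaplastic")
    }


def gaussian_spectrum(center=1300.0, sigma=8.0, amplitude=1.0, ramp=0.0,
                      grid=None, **kwargs) -> Spectrum:
    """Single Gaussian band, optionally on a linear ramp."""
    if grid is None:
        grid = np.arange(800.0, 1801.0)
    y = amplitude * np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    y = y + ramp * (grid - grid[0])
    return Spectrum(grid, y, sample_id="gauss", **kwargs)
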
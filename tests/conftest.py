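import numpy as np
import pytest

from voct import simulate
from voct.spectra import VibrationalSpectrum


@pytest.fixture(scope="session")
def human_noiseless() -> VibrationalSpectrum:
    """Default human profile evaluated without noise."""
    return simulate.generate_spectrum(simulate.human_profile(noise_sd=0.0), seed=0)


@pytest.fixture(scope="session")
def porcine_noiseless() -> VibrationalSpectrum:
    return simulate.generate_spectrum(
        simulate.porcine_profile(noise_sd=0.0, grid=simulate.HUMAN_GRID), seed=0
    )


@pytest.fixture(scope="session")
def species_cohort_small():
    """A small (10 + 10) human/porcine cohort for localization tests."""
    return simulate.generate_species_cohort(10, 10, seed=7)


def make_spectrum(displacements, state="speaker_normalized", **meta):
    d = np.asarray(displacements, dtype=float)
    f = 50.0 + 10.0 * np.arange(d.size)
    return VibrationalSpectrum(f, d, normalization_state=state, **meta)
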
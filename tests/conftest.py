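import numpy as np
import pytest

from osmacnet.msio import Spectrum
from osmacnet.synthetic_data import GeneratorParams, generate_study


def make_spectrum(
    spectrum_id="s",
    precursor_mz=500.0,
    rt=1.0,
    peaks=((100.0, 1000.0), (200.0, 2000.0)),
    extract_id=None,
):
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor_mz,
        rt=rt,
        mz=mz,
        intensity=inten,
        extract_id=extract_id,
    )


def random_spectrum(rng, spectrum_id, max_peaks=6, mz_range=(100.0, 500.0)):
    n = int(rng.integers(1, max_peaks + 1))
    mz = np.sort(rng.uniform(*mz_range, n))
    inten = rng.uniform(1e3, 1e5, n)
    return Spectrum(
        spectrum_id=spectrum_id,
        precursor_mz=float(rng.uniform(400, 600)),
        rt=float(rng.uniform(0, 8)),
        mz=mz,
        intensity=inten,
    )


@pytest.fixture(scope="session")
def default_study():
    """Full synthetic study at the default study conditions (noise CV 0.1)."""
    return generate_study(GeneratorParams(seed=11))


@pytest.fixture(scope="session")
def zero_noise_study():
    """Study with zero intensity noise and jitter SDs at 1/4 of the tolerances."""
    return generate_study(
        GeneratorParams(
            seed=11,
            intensity_noise_cv=0.0,
            rt_jitter_sd_min=0.05,
            precursor_jitter_sd_da=0.0025,
        )
    )
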
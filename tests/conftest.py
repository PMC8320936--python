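import numpy as np
import pytest
from hypothesis import settings

import doctvib as dv

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def source():
    return dv.make_source(850.0, 55.0, 1024)


@pytest.fixture(scope="session")
def single_reflector_phantom():
    return dv.SamplePhantom(reflectors=(dv.Reflector(300.0, 0.2, "mirror"),))


@pytest.fixture(scope="session")
def three_reflector_phantom():
    return dv.default_phantom()


def reconstruct(frame, source, window="hann", background="envelope"):
    """Standard chain: background, k-linearize, apodize, FFT."""
    bg = source.envelope if background == "envelope" else None
    frame = dv.subtract_background(frame, background=bg)
    frame = dv.k_linearize(frame)
    frame = dv.apodize(frame, window)
    return dv.to_ascans(frame)


@pytest.fixture(scope="session")
def band_center_k(source):
    """Central wavenumber of the source grid (rad/nm) — the phase reference."""
    k = 2 * np.pi / source.wavelength_nm
    return 0.5 * (k[0] + k[-1])
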
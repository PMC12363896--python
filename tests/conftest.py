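import numpy as np
import pytest

from eemshift import EEM, Spectrum, WavelengthGrid


def grid(lo, hi, step):
    return WavelengthGrid(np.arange(lo, hi + step / 2, step), step_hint=step)


def gaussian_spectrum(center=826.5, sigma=25.0, lo=700.0, hi=950.0, step=0.5,
                      amplitude=1000.0, kind="emission"):
    g = grid(lo, hi, step)
    vals = amplitude * np.exp(-((g.values - center) ** 2) / (2 * sigma ** 2))
    return Spectrum(g, vals, kind)


def separable_eem(ex_lo=760.0, ex_hi=820.0, ex_step=10.0,
                  em_lo=700.0, em_hi=950.0, em_step=1.0,
                  envelope_center=792.0, band_center=826.5):
    """Rank-one EEM: Gaussian excitation envelope x Gaussian emission band."""
    exg, emg = grid(ex_lo, ex_hi, ex_step), grid(em_lo, em_hi, em_step)
    h = np.exp(-((exg.values - envelope_center) ** 2) / (2 * 20.0 ** 2))
    g = np.exp(-((emg.values - band_center) ** 2) / (2 * 25.0 ** 2))
    return EEM(exg, emg, 1000.0 * np.outer(h, g))


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def small_eem():
    return separable_eem()
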
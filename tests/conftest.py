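import numpy as np
import pytest

from cdspectra import Spectrum
from cdspectra import synth


def random_spectrum(rng: np.random.Generator, averaged: bool = False) -> Spectrum:
    """A random but well-formed spectrum on a 0.1-nm-printable grid."""
    n = int(rng.integers(5, 40))
    high = float(rng.integers(240, 280))
    step = float(rng.choice([0.5, 1.0, 2.0]))
    wl = high - step * np.arange(n)
    n_avg = int(rng.integers(2, 6)) if averaged else 1
    sd = np.abs(rng.normal(0, 0.3, n)) + 1e-6 if averaged else None
    return Spectrum(
        wavelengths=wl,
        cd=rng.normal(0, 8, n),
        ht=np.abs(rng.normal(400, 80, n)),
        cd_smoothed=rng.normal(0, 8, n),
        sd=sd,
        units="mdeg",
        meta={"sample": f"random-{rng.integers(1e6)}", "instrument": "fixtureCD"},
        n_averaged=n_avg,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20180)


@pytest.fixture
def helix():
    return synth.preset_spectrum("helix", name="helix standard")


@pytest.fixture
def helix_with_ht(helix):
    return synth.make_ht_profile(helix, base=300.0, knee=200.0, slope=40.0)


@pytest.fixture
def melt_series():
    """Seeded 17-point two-state melt, Tm 55 C, width 3 C, 1% noise."""
    return synth.demo_melt_series(seed=11)
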
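import numpy as np
import pytest

from pbsdyn.kinetics import IRFModel
from pbsdyn.simulate import (
    Band,
    SurfaceSpec,
    TetrapyrroleSpec,
    default_ta_axes,
    make_surface,
    make_tetrapyrrole,
    make_toy_rod,
    ta_surface_spec,
)


@pytest.fixture(scope="session")
def toy_rod():
    """Synthetic bottom trimer: three beta-82-like bilins around a linker."""
    return make_toy_rod()


@pytest.fixture()
def flat_bilin():
    return make_tetrapyrrole(TetrapyrroleSpec(0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def ta_axes():
    return default_ta_axes(120, 60)


@pytest.fixture(scope="session")
def noiseless_two_exp_surface():
    """Sequential 5 ps -> 200 ps surface, no noise, small IRF."""
    from pbsdyn.kinetics import sequential_scheme

    spec = SurfaceSpec(
        scheme=sequential_scheme([5.0, 200.0]),
        bands=((Band(630.0, 10.0, -1.0),), (Band(665.0, 10.0, -1.0),)),
        irf=IRFModel(t0=0.0, fwhm=0.2),
        noise_sigma=0.0,
    )
    times = np.linspace(-2.0, 1200.0, 240)
    wavelengths = np.linspace(550.0, 720.0, 50)
    return make_surface(spec, times, wavelengths), spec


@pytest.fixture(scope="session")
def noisy_rod_surface(ta_axes):
    """Rod-scheme transient-absorption surface at 1% noise, fixed seed."""
    times, wavelengths = ta_axes
    spec = ta_surface_spec(noise_sigma=0.01, seed=7)
    return make_surface(spec, times, wavelengths), spec
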
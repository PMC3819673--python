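import numpy as np
import pytest

from gjlock import StimulusProtocol, build_lattice
from gjlock.hexnet import NetworkParams
from gjlock.stack import ImageStack
from gjlock.synthgen import MovieSpec, PhotophysicsModel, render_movie


@pytest.fixture
def carrier():
    """Free-running carrier protocol for pure-trace tests (no prestim)."""
    return StimulusProtocol(frequency_hz=0.5, command_amplitude_mv=35.0,
                            onset_s=0.0, duration_s=np.inf, prestim_s=0.0)


@pytest.fixture
def protocol():
    """Standard imaging protocol: 10 s prestim, 0.5 Hz 35 mV carrier."""
    return StimulusProtocol(frequency_hz=0.5, command_amplitude_mv=35.0,
                            onset_s=10.0, duration_s=52.0, prestim_s=10.0)


@pytest.fixture
def small_lattice():
    return build_lattice(9, 5)


@pytest.fixture
def times():
    """60 s at 10 Hz (20 samples per 0.5 Hz cycle)."""
    return np.arange(600) / 10.0


def make_movie(lattice, g_j_ns, n_cycles=5, noise="none", seed=1,
               pixel_size_um=3.0, schedule=None, duration_s=None, f0_mean=1000.0,
               bleach_tau_s=300.0):
    """Small synthetic movie centred on the lattice with a 20 um margin."""
    protocol = StimulusProtocol(frequency_hz=0.5, command_amplitude_mv=35.0,
                                onset_s=10.0, duration_s=2.0 * (n_cycles + 1),
                                prestim_s=10.0)
    span = lattice.positions.max(axis=0) - lattice.positions.min(axis=0)
    shape = (int(np.ceil((span[1] + 40) / pixel_size_um)),
             int(np.ceil((span[0] + 40) / pixel_size_um)))
    spec = MovieSpec(lattice=lattice, protocol=protocol, shape=shape,
                     pixel_size_um=pixel_size_um, schedule=schedule,
                     duration_s=duration_s, seed=seed)
    params = NetworkParams(g_j_ns=g_j_ns)
    photo = PhotophysicsModel(noise=noise, f0_mean=f0_mean, bleach_tau_s=bleach_tau_s)
    stack, truth = render_movie(spec, params, photo)
    return stack, truth, protocol, params


@pytest.fixture
def movie_factory():
    return make_movie


def random_stack(rng, n=20, h=7, w=9, frame_rate=10.0):
    return ImageStack(frames=rng.uniform(0, 100, size=(n, h, w)), frame_rate=frame_rate)
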
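import numpy as np
import pandas as pd
import pytest

from dendrospt.geometry import DendriteGeometry, Synapse, SynapseMap
from dendrospt.simulate import SimulationParams


@pytest.fixture
def straight_geometry() -> DendriteGeometry:
    """A 12 μm straight dendrite along +x, 2 μm wide."""
    return DendriteGeometry(origin=(0.0, 0.0), axis=(1.0, 0.0), length=12.0, half_width=1.0)


@pytest.fixture
def wide_geometry() -> DendriteGeometry:
    """A geometry large enough that reflections are effectively never hit."""
    return DendriteGeometry(origin=(-100.0, -100.0), axis=(1.0, 0.0), length=200.0, half_width=100.0)


@pytest.fixture
def two_synapse_map() -> SynapseMap:
    """Two inhibitory synapses 3 μm apart on the axis."""
    return SynapseMap(
        synapses=[
            Synapse(0, "inhibitory", (3.0, 0.0), 0.2),
            Synapse(1, "inhibitory", (6.0, 0.0), 0.2),
        ]
    )


@pytest.fixture
def free_params() -> SimulationParams:
    """Noise-free, blink-free, trap-free isotropic diffusion."""
    return SimulationParams(
        D_long=0.05,
        D_trans=0.05,
        loc_noise_sd=0.0,
        n_frames=200,
        seed=0,
    )


def make_traj(frames, xs, ys, track_id=0) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "track_id": track_id,
            "frame": np.asarray(frames, dtype=int),
            "x_um": np.asarray(xs, dtype=float),
            "y_um": np.asarray(ys, dtype=float),
        }
    )


@pytest.fixture
def traj_factory():
    return make_traj
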
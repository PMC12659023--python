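import numpy as np
import pytest

from poreflux import ParticleTable, SpeciesSpec, SyntheticSpec, Trajectory, generate


@pytest.fixture
def two_particle_traj():
    """3 frames, 2 particles, hand-written coordinates in a 100 Å box."""
    coords = np.array(
        [
            [[10.0, 10.0, 50.0], [20.0, 20.0, 60.0]],
            [[10.5, 10.0, 51.0], [20.0, 20.5, 59.0]],
            [[11.0, 10.0, 52.0], [20.0, 21.0, 58.0]],
        ]
    )
    box = np.tile([100.0, 100.0, 100.0], (3, 1))
    return Trajectory(coords=coords, box=box, times=np.array([0.0, 20.0, 40.0]))


@pytest.fixture
def ion_pair_table():
    return ParticleTable(
        ids=np.array([1, 2]),
        species=np.array(["cation", "anion"], dtype=object),
        charge=np.array([1.0, -1.0]),
    )


@pytest.fixture
def drift_spec():
    """50+50 electrolyte with ±0.01 Å/ps drift in a 50×50×100 box."""
    return SyntheticSpec(
        box=(50.0, 50.0, 100.0),
        species=(
            SpeciesSpec("K", "cation", 50, 1.0, v=0.01, diffusion=0.04),
            SpeciesSpec("Cl", "anion", 50, -1.0, v=-0.01, diffusion=0.04),
        ),
        frame_interval=20.0,
        duration=2000.0,
        seed=7,
    )


@pytest.fixture
def drift_run(drift_spec):
    return generate(drift_spec)
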
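import numpy as np
import pytest
from hypothesis import settings

import icekpore as ik

settings.register_profile("ci", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def base_geometry() -> ik.PoreGeometry:
    """The reference cavity-decorated pore: R=10, L=30, s=9, w=12, h=10 Å."""
    return ik.PoreGeometry(R=10.0, L=30.0, s=9.0, w=12.0, h=10.0, epsilon_S=1.0)


@pytest.fixture
def model_electrolyte() -> ik.ElectrolyteSpec:
    """The symmetric dipolar model fluid at 2 M, 250 K."""
    return ik.ElectrolyteSpec(
        c0=2.0, valence=1, epsilon_L=83.2, eta=0.35, mu=4.4e3, T=250.0
    )


@pytest.fixture
def kcl_1m() -> ik.ElectrolyteSpec:
    """1 M KCl in water at room temperature."""
    return ik.ElectrolyteSpec(
        c0=1.0, valence=1, epsilon_L=78.0, eta=0.89, mu=4.4e3, T=298.0
    )


def make_frame(positions, charge=None, mass=None, species=None, time=0.0,
               box=(100.0, 100.0, 100.0)):
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    return ik.TrajectoryFrame(
        time=time,
        box=np.asarray(box, dtype=float),
        ids=np.arange(1, n + 1),
        species=np.asarray(species if species is not None else ["ION"] * n,
                           dtype=object),
        charge=np.asarray(charge if charge is not None else np.ones(n), dtype=float),
        mass=np.asarray(mass if mass is not None else np.full(n, 40.0), dtype=float),
        positions=positions,
    )


@pytest.fixture
def frame_factory():
    return make_frame
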
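import numpy as np
import pytest

from mbdcs import OscillatorSet
from mbdcs.oscillators import DampingParams


def random_rotation(seed: int) -> np.ndarray:
    """Haar-ish random proper rotation matrix."""
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


@pytest.fixture
def undamped() -> DampingParams:
    return DampingParams.undamped()


@pytest.fixture
def dimer() -> OscillatorSet:
    """Two identical strongly coupled oscillators, 8 Bohr apart."""
    return OscillatorSet.from_parameters(
        positions=[[0.0, 0.0, 0.0], [0.0, 0.0, 8.0]],
        alpha=10.0, omega=0.5, r_vdw=2.5,
    )


@pytest.fixture
def trimer() -> OscillatorSet:
    """Scalene triangle of unequal oscillators (no special symmetry)."""
    return OscillatorSet.from_parameters(
        positions=[[0.0, 0.0, 0.0], [0.0, 1.0, 7.0], [0.0, 6.5, 1.5]],
        alpha=[8.0, 12.0, 6.0], omega=[0.6, 0.45, 0.7], r_vdw=[2.5, 3.0, 2.2],
    )
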
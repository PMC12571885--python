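import numpy as np
import pytest

from irmd import Geometry
from irmd.oracle import Bond, SurrogateMolecule


@pytest.fixture
def harmonic_diatomic():
    """Charged harmonic diatomic: k = 1 eV/Å², r0 = 1 Å, masses 1 amu,
    charges ±0.2 e — the closed-form workhorse (stretch at ≈737.5 cm⁻¹)."""
    g = Geometry(("H", "H"), [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], masses=[1.0, 1.0])
    return SurrogateMolecule(
        g,
        [Bond(0, 1, "harmonic", r0=1.0, k=1.0)],
        charges=np.array([0.2, -0.2]),
        name="harmonic_diatomic",
    )


@pytest.fixture
def morse_diatomic():
    """Morse diatomic with the same curvature at the minimum
    (k = 2 D_e a² = 1 eV/Å²) but a shallow 1 eV well, so thermal red-shifts
    are large enough to resolve."""
    g = Geometry(("H", "H"), [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]], masses=[1.0, 1.0])
    return SurrogateMolecule(
        g,
        [Bond(0, 1, "morse", r0=1.0, d_e=1.0, a=float(np.sqrt(0.5)))],
        charges=np.array([0.2, -0.2]),
        name="morse_diatomic",
    )


@pytest.fixture
def bent_triatomic():
    """Bent three-atom molecule (O-H-ish parameters) with harmonic bonds,
    minimized by construction: both bonds at r0, angle at θ0."""
    theta0 = np.deg2rad(104.0)
    r0 = 1.0
    pos = np.array(
        [
            [0.0, 0.0, 0.0],
            [r0, 0.0, 0.0],
            [r0 - r0 * np.cos(theta0), r0 * np.sin(theta0), 0.0],
        ]
    )
    g = Geometry(("O", "H", "H"), pos)  # apex is atom 1
    from irmd.oracle import Angle

    return SurrogateMolecule(
        g,
        [Bond(0, 1, "harmonic", r0=r0, k=30.0), Bond(1, 2, "harmonic", r0=r0, k=30.0)],
        angles=[Angle(0, 1, 2, k_theta=3.0, theta0=theta0)],
        charges=np.array([-0.3, 0.2, 0.1]),
        name="bent_triatomic",
    )
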
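"""Domain types: geometries, labelled samples, trajectories, spectra.

All arrays are float64 numpy arrays in the package's internal units
(Å, fs, eV, amu, Debye; see :mod:`irmd.units`).  Geometries are gas-phase
Cartesian coordinates — there is no periodic cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .units import ATOMIC_MASSES


class StructuralError(ValueError):
    """Inconsistent structure data (atom counts, shapes, ordering)."""


@dataclass
class Geometry:
    """A molecular configuration: element symbols plus Cartesian positions.

    Parameters
    ----------
    symbols
        Element symbols, one per atom (H/C/N/O for the bundled surrogates;
        any symbol with a supplied mass is accepted).
    positions
        (N, 3) Cartesian coordinates in Å.
    velocities
        Optional (N, 3) velocities in Å/fs.
    masses
        Optional per-atom masses in amu; resolved from ``symbols`` when
        omitted.
    """

    symbols: tuple[str, ...]
    positions: np.ndarray
    velocities: Optional[np.ndarray] = None
    masses: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.symbols = tuple(str(s) for s in self.symbols)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.symbols)
        if self.positions.shape != (n, 3):
            raise StructuralError(
                f"positions shape {self.positions.shape} does not match "
                f"{n} atoms"
            )
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            if self.velocities.shape != (n, 3):
                raise StructuralError("velocities shape mismatch")
        if self.masses is None:
            try:
                self.masses = np.array(
                    [ATOMIC_MASSES[s] for s in self.symbols], dtype=float
                )
            except KeyError as exc:
                raise StructuralError(
                    f"no tabulated mass for element {exc}; pass masses="
                ) from exc
        else:
            self.masses = np.asarray(self.masses, dtype=float)
            if self.masses.shape != (n,):
                raise StructuralError("masses shape mismatch")
        if np.any(self.masses <= 0):
            raise StructuralError("masses must be strictly positive")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    def center_of_mass(self) -> np.ndarray:
        m = self.masses
        return (m[:, None] * self.positions).sum(axis=0) / m.sum()

    def with_positions(self, positions: np.ndarray) -> "Geometry":
        return replace(self, positions=np.asarray(positions, dtype=float))

    def with_velocities(self, velocities: Optional[np.ndarray]) -> "Geometry":
        return replace(
            self,
            velocities=None if velocities is None else np.asarray(velocities, float),
        )

    def copy(self) -> "Geometry":
        return Geometry(
            self.symbols,
            self.positions.copy(),
            None if self.velocities is None else self.velocities.copy(),
            self.masses.copy(),
        )

    def kinetic_energy(self) -> float:
        """Kinetic energy in eV (0 if no velocities)."""
        from .units import KINETIC_TO_EV

        if self.velocities is None:
            return 0.0
        return float(
            0.5 * KINETIC_TO_EV * (self.masses * (self.velocities**2).sum(axis=1)).sum()
        )

    def kinetic_temperature(self) -> float:
        """Instantaneous kinetic temperature (K) over all 3N degrees of freedom."""
        from .units import KB

        return 2.0 * self.kinetic_energy() / (3 * self.n_atoms * KB)

    def content_hash(self) -> str:
        """Hash of symbols+positions, for duplicate detection."""
        import hashlib

        h = hashlib.sha256()
        h.update(" ".join(self.symbols).encode())
        h.update(np.round(self.positions, 10).tobytes())
        return h.hexdigest()


@dataclass
class LabeledSample:
    """A geometry with (possibly partial) labels.

    Absent labels are ``None`` — never zero-filled.  Energies in eV, forces
    in eV/Å, dipole in Debye.
    """

    geometry: Geometry
    energy: Optional[float] = None
    forces: Optional[np.ndarray] = None
    dipole: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.energy is not None:
            self.energy = float(self.energy)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != (self.geometry.n_atoms, 3):
                raise StructuralError("forces shape does not match atom count")
        if self.dipole is not None:
            self.dipole = np.asarray(self.dipole, dtype=float)
            if self.dipole.shape != (3,):
                raise StructuralError("dipole must be a 3-vector")


@dataclass
class Trajectory:
    """A time-ordered sequence of geometries at fixed recording interval.

    ``dt`` is the interval between *recorded* frames in fs (integrator step
    × recording stride).  Optional per-frame dipoles (Debye) and potential
    energies (eV).  ``aborted`` marks runs terminated by the committee
    sanity check.
    """

    frames: list[Geometry]
    dt: float
    dipoles: Optional[np.ndarray] = None
    energies: Optional[np.ndarray] = None
    aborted: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("trajectory dt must be positive")
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        ref = self.frames[0].symbols
        for i, f in enumerate(self.frames):
            if f.symbols != ref:
                raise StructuralError(f"frame {i} has different atoms/ordering")
        if self.dipoles is not None:
            self.dipoles = np.asarray(self.dipoles, dtype=float)
            if self.dipoles.shape != (len(self.frames), 3):
                raise StructuralError("dipoles shape mismatch")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.shape != (len(self.frames),):
                raise StructuralError("energies shape mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Time span between first and last recorded frame, fs."""
        return (self.n_frames - 1) * self.dt


@dataclass
class Spectrum:
    """Intensity on a strictly ascending wavenumber grid (cm⁻¹)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.wavenumbers.shape != self.intensities.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1-D")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly ascending")

    @property
    def n_points(self) -> int:
        return self.wavenumbers.size

    def peak_position(self) -> float:
        """Wavenumber of the intensity maximum."""
        return float(self.wavenumbers[int(np.argmax(self.intensities))])


# --------------------------------------------------------------------------
# Calculator contract
# --------------------------------------------------------------------------


class ForceUncertaintyAbort(RuntimeError):
    """Raised by a committee calculator when the relative force error
    exceeds its abort threshold; MD catches it and returns a truncated,
    flagged trajectory."""

    def __init__(self, message: str, relative_error: float):
        super().__init__(message)
        self.relative_error = relative_error


class Calculator:
    """Minimal single-point calculator contract.

    Subclasses implement :meth:`calculate` returning
    ``(energy eV, forces eV/Å, dipole Debye or None)``.
    """

    def calculate(self, geometry: Geometry):
        raise NotImplementedError


class _ModelCalculator(Calculator):
    """Adapts an object with ``predict(geometry) -> (E, F)`` to Calculator."""

    def __init__(self, model):
        self.model = model

    def calculate(self, geometry: Geometry):
        energy, forces = self.model.predict(geometry)
        return energy, forces, None


def as_calculator(obj) -> Calculator:
    """Coerce oracles, fitted models or committees to the Calculator contract."""
    if isinstance(obj, Calculator):
        return obj
    if hasattr(obj, "calculate"):
        return obj
    if hasattr(obj, "predict"):
        return _ModelCalculator(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a calculator")


def validate_same_composition(samples: Sequence[LabeledSample]) -> tuple[str, ...]:
    """Return the shared symbol tuple, or raise if compositions differ."""
    ref = samples[0].geometry.symbols
    for s in samples[1:]:
        if s.geometry.symbols != ref:
            raise StructuralError("samples mix different compositions/orderings")
    return ref
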
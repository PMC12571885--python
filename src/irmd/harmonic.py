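"""Normal-mode analysis: finite-difference Hessians, harmonic frequencies,
stick IR spectra and normal-mode sampling of initial training geometries.

The Hessian is built from central differences of analytic forces and
symmetrized; frequencies come from the eigendecomposition of the
mass-weighted Hessian, ν̃ = sqrt(λ)/(2πc), with negative eigenvalues
(imaginary modes) reported as negative wavenumbers.  Translations and
rotations are classified by a rigid-mode threshold of 5 cm⁻¹ — well below
any bonded-mode frequency of the surrogates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, List, Optional, Sequence

import numpy as np

from .core import Calculator, Geometry, Spectrum, as_calculator
from .units import KB, frequency_to_wavenumber

#: |ν̃| below this (cm⁻¹) classifies a mode as translation/rotation.
RIGID_MODE_THRESHOLD = 5.0


class UnminimizedGeometryError(RuntimeError):
    """Sampling was asked to start from a non-stationary geometry."""


@dataclass
class NormalModes:
    """Eigenmodes of the mass-weighted Hessian.

    ``frequencies`` are signed wavenumbers (cm⁻¹, 3N of them, ascending in
    eigenvalue; imaginary modes negative); ``modes[:, m]`` is the
    orthonormal eigenvector of mode m in mass-weighted coordinates;
    ``reduced_masses`` in amu.
    """

    frequencies: np.ndarray
    modes: np.ndarray
    reduced_masses: np.ndarray
    masses: np.ndarray

    @property
    def n_modes(self) -> int:
        return self.frequencies.size

    def rigid_mask(self, threshold: float = RIGID_MODE_THRESHOLD) -> np.ndarray:
        return np.abs(self.frequencies) < threshold

    def non_rigid_indices(self, threshold: float = RIGID_MODE_THRESHOLD) -> np.ndarray:
        return np.flatnonzero(~self.rigid_mask(threshold))

    def cartesian_displacement(self, m: int) -> np.ndarray:
        """(N, 3) Cartesian displacement per unit mass-weighted coordinate
        (Å·√amu) of mode ``m``."""
        n = self.masses.size
        disp = self.modes[:, m].reshape(n, 3) / np.sqrt(self.masses)[:, None]
        return disp


def hessian(calculator, geometry: Geometry, h: float = 1e-3) -> np.ndarray:
    """Symmetrized 3N×3N Hessian (eV/Å²) from central differences of forces."""
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    calc = as_calculator(calculator)
    n = geometry.n_atoms
    hess = np.zeros((3 * n, 3 * n))
    pos = geometry.positions
    for i in range(n):
        for c in range(3):
            p = pos.copy()
            p[i, c] += h
            _, f_plus, *_ = calc.calculate(geometry.with_positions(p))
            p[i, c] -= 2 * h
            _, f_minus, *_ = calc.calculate(geometry.with_positions(p))
            # H = d²E/dx² = -dF/dx
            hess[3 * i + c, :] = -((np.asarray(f_plus) - np.asarray(f_minus)).ravel()) / (
                2 * h
            )
    return 0.5 * (hess + hess.T)


def normal_modes(hess: np.ndarray, masses: np.ndarray) -> NormalModes:
    """Diagonalize the mass-weighted Hessian.

    Returns all 3N modes; use :meth:`NormalModes.non_rigid_indices` to drop
    translations/rotations.
    """
    hess = np.asarray(hess, dtype=float)
    if not np.all(np.isfinite(hess)):
        raise ValueError("Hessian contains non-finite entries")
    masses = np.asarray(masses, dtype=float)
    n = masses.size
    if hess.shape != (3 * n, 3 * n):
        raise ValueError("Hessian shape does not match the mass vector")
    inv_sqrt_m = np.repeat(1.0 / np.sqrt(masses), 3)
    mw = hess * np.outer(inv_sqrt_m, inv_sqrt_m)
    evals, evecs = np.linalg.eigh(0.5 * (mw + mw.T))
    freqs = np.array([frequency_to_wavenumber(lam) for lam in evals])
    # reduced mass of mode m: 1 / Σ_i |cartesian displacement|² (unit-norm
    # mass-weighted eigenvector)
    disp_sq = (evecs**2) * (inv_sqrt_m**2)[:, None]
    reduced = 1.0 / disp_sq.sum(axis=0)
    return NormalModes(frequencies=freqs, modes=evecs, reduced_masses=reduced, masses=masses)


def analyze(calculator, geometry: Geometry, h: float = 1e-3) -> NormalModes:
    """Convenience: Hessian + normal modes in one call."""
    return normal_modes(hessian(calculator, geometry, h=h), geometry.masses)


def harmonic_ir(
    dipole_fn: Callable[[Geometry], np.ndarray],
    geometry: Geometry,
    modes: NormalModes,
    dq: float = 1e-3,
    threshold: float = RIGID_MODE_THRESHOLD,
) -> Spectrum:
    """Double-harmonic stick spectrum.

    The intensity of mode m is |dμ/dQ_m|², with the dipole derivative taken
    by central differences along the mass-weighted mode with step ``dq``
    (Å·√amu).  Rigid modes are excluded; degenerate frequencies are merged
    by summing intensities.
    """
    if dq <= 0:
        raise ValueError("dipole-derivative step dq must be positive")
    sticks = {}
    for m in modes.non_rigid_indices(threshold):
        disp = modes.cartesian_displacement(m)
        mu_plus = np.asarray(dipole_fn(geometry.with_positions(geometry.positions + dq * disp)))
        mu_minus = np.asarray(dipole_fn(geometry.with_positions(geometry.positions - dq * disp)))
        dmu = (mu_plus - mu_minus) / (2 * dq)
        nu = float(modes.frequencies[m])
        sticks[round(nu, 6)] = sticks.get(round(nu, 6), 0.0) + float(dmu @ dmu)
    if not sticks:
        return Spectrum(np.array([0.0, 1.0]), np.zeros(2))
    wn = np.array(sorted(sticks))
    return Spectrum(wn, np.array([sticks[w] for w in wn]))


def normal_mode_sample(
    geometry: Geometry,
    modes: NormalModes,
    frames_per_mode: int = 10,
    t_ref: float = 300.0,
    n_phases: int = 30,
    calculator: Optional[Calculator] = None,
    force_tol: float = 1e-3,
    allow_unminimized: bool = False,
    threshold: float = RIGID_MODE_THRESHOLD,
) -> List[Geometry]:
    """Sample geometries along each non-rigid normal mode.

    Each mode is traced through a sinusoidal cycle of ``n_phases`` phases
    with amplitude A chosen so the maximum harmonic potential energy along
    the mode equals k_B·t_ref (½ λ A² = k_B T); the first
    ``frames_per_mode`` phases are returned, so the output has
    (non-rigid modes) × frames_per_mode geometries.
    """
    if frames_per_mode < 1:
        raise ValueError("frames_per_mode must be >= 1")
    if frames_per_mode > n_phases:
        raise ValueError("frames_per_mode cannot exceed the number of phases")
    if calculator is not None:
        _, forces, *_ = as_calculator(calculator).calculate(geometry)
        fmax = float(np.abs(forces).max())
        if fmax > force_tol:
            if not allow_unminimized:
                raise UnminimizedGeometryError(
                    f"max |F| = {fmax:.2e} eV/Å exceeds {force_tol:g}; pass "
                    "allow_unminimized=True to override"
                )
            warnings.warn("sampling from an unminimized geometry", stacklevel=2)
    out: List[Geometry] = []
    kt = KB * t_ref
    for m in modes.non_rigid_indices(threshold):
        nu = modes.frequencies[m]
        # λ back from ν̃ (same conversion both ways, sign-safe)
        from .units import FORCE_TO_ACC, OMEGA_TO_CM

        lam = (abs(nu) / OMEGA_TO_CM) ** 2 / FORCE_TO_ACC  # eV/(Å²·amu)
        amplitude = np.sqrt(2.0 * kt / lam)
        disp = modes.cartesian_displacement(m)
        for k in range(1, frames_per_mode + 1):
            phase = 2.0 * np.pi * k / n_phases
            out.append(
                geometry.with_positions(
                    geometry.positions + amplitude * np.sin(phase) * disp
                )
            )
    return out
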
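"""Unit system and physical constants.

Internal units throughout the package: length in Å, time in fs, energy in
eV, mass in amu, charge in elementary charges, dipole moment in Debye,
spectroscopic frequency in cm⁻¹ (wavenumber).  Every conversion factor is
derived here, once, from SI (CODATA 2018) definitions; no other module
defines its own constants.
"""

import math

# SI values of the internal base units (CODATA 2018 exact/recommended).
EV_SI = 1.602176634e-19  # J per eV (exact)
AMU_SI = 1.66053906660e-27  # kg per amu
ANGSTROM_SI = 1.0e-10  # m per Å
FEMTOSECOND_SI = 1.0e-15  # s per fs
SPEED_OF_LIGHT_SI = 299792458.0  # m/s (exact)

#: Boltzmann constant, eV/K (exact: 1.380649e-23 J/K / EV_SI).
KB = 1.380649e-23 / EV_SI

#: Speed of light in cm/fs — converts frequency (fs⁻¹) to wavenumber (cm⁻¹).
C_CM_FS = SPEED_OF_LIGHT_SI * 100.0 * FEMTOSECOND_SI  # ≈ 2.99792458e-5

#: Acceleration from force: multiply (eV/Å)/amu by this to get Å/fs².
FORCE_TO_ACC = (EV_SI / (ANGSTROM_SI * AMU_SI)) * (FEMTOSECOND_SI**2 / ANGSTROM_SI)

#: Kinetic energy: multiply amu·(Å/fs)² by this to get eV.  (= 1/FORCE_TO_ACC)
KINETIC_TO_EV = 1.0 / FORCE_TO_ACC

#: Dipole: multiply e·Å by this to get Debye (1 D = 1e-21/c C·m).
E_ANGSTROM_TO_DEBYE = (EV_SI / 1.0) * ANGSTROM_SI / (1.0e-21 / SPEED_OF_LIGHT_SI)
# note EV_SI numerically equals the elementary charge in C

#: Angular frequency (rad/fs) to wavenumber (cm⁻¹): ν̃ = ω / (2πc).
OMEGA_TO_CM = 1.0 / (2.0 * math.pi * C_CM_FS)


def frequency_to_wavenumber(omega_sq: float) -> float:
    """Signed wavenumber from a mass-weighted Hessian eigenvalue.

    ``omega_sq`` is in eV/(Å²·amu).  Non-negative eigenvalues map to
    ν̃ = sqrt(λ·FORCE_TO_ACC)/(2πc) in cm⁻¹; negative (imaginary-mode)
    eigenvalues are reported as negative wavenumbers of the same magnitude.
    """
    omega = math.sqrt(abs(omega_sq) * FORCE_TO_ACC)
    nu = omega * OMEGA_TO_CM
    return nu if omega_sq >= 0 else -nu


#: Standard atomic weights (amu) for the elements the surrogates use.
ATOMIC_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999}

#: Nominal valences used by the surrogate-molecule generator.
VALENCES = {"H": 1, "C": 4, "N": 3, "O": 2}
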
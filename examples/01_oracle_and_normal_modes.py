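"""Build a surrogate molecule, check its analytic forces, and compute its
harmonic vibrational spectrum.

Run:  python examples/01_oracle_and_normal_modes.py
"""

import numpy as np

from irmd import analyze, finite_difference_check, harmonic_ir, make_surrogate_suite
from irmd.oracle import OracleCalculator, dipole_moment, evaluate

# A small deterministic suite of anharmonic H/C/N/O molecules; each has a
# locally minimized reference geometry, Morse bonds and point charges.
mol = make_surrogate_suite(n_molecules=1, size_range=(4, 4), seed=7)[0]
print(f"molecule: {mol.name}  atoms: {''.join(mol.geometry.symbols)}")

s = evaluate(mol, mol.geometry)
print(f"reference energy      : {s.energy:.6f} eV (0 at the minimum)")
print(f"max |force|           : {np.abs(s.forces).max():.2e} eV/Å (< 1e-3 tolerance)")
print(f"dipole moment         : {np.linalg.norm(s.dipole):.3f} Debye")

dev = finite_difference_check(mol, mol.geometry, h=1e-4)
print(f"analytic-vs-FD forces : {dev:.2e} eV/Å max deviation")

# Mass-weighted Hessian -> normal modes; 3N-6 genuine vibrations, the rest
# are translations/rotations near 0 cm^-1.
modes = analyze(OracleCalculator(mol), mol.geometry)
vib = modes.frequencies[modes.non_rigid_indices()]
print(f"vibrational modes     : {len(vib)} of {modes.n_modes}")
print("frequencies (cm^-1)   :", " ".join(f"{v:.1f}" for v in vib))

# Double-harmonic stick spectrum: intensity of mode m is |dmu/dQ_m|^2.
sticks = harmonic_ir(lambda g: dipole_moment(mol, g), mol.geometry, modes)
for w, inten in zip(sticks.wavenumbers, sticks.intensities):
    print(f"  stick at {w:8.1f} cm^-1  intensity {inten:.4e} (D/Å·√amu)²")
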
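"""Hessians, normal modes, harmonic stick spectra and mode sampling."""

import numpy as np
import pytest

from irmd import Geometry
from irmd.harmonic import (
    analyze,
    harmonic_ir,
    hessian,
    normal_mode_sample,
    normal_modes,
    UnminimizedGeometryError,
)
from irmd.oracle import (
    Bond,
    OracleCalculator,
    SurrogateMolecule,
    dipole_moment,
    evaluate,
    make_surrogate_suite,
)
from irmd.units import FORCE_TO_ACC, KB, OMEGA_TO_CM

DIATOMIC_STRETCH = np.sqrt(2.0 * FORCE_TO_ACC) * OMEGA_TO_CM  # ≈ 737.47 cm⁻¹


class TestHessian:
    def test_harmonic_diatomic_stretch_block(self, harmonic_diatomic):
        h = hessian(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        # bond along x: d²E/dx² = ±k = ±1 eV/Å²
        assert h[0, 0] == pytest.approx(1.0, abs=1e-5)
        assert h[0, 3] == pytest.approx(-1.0, abs=1e-5)
        assert h[3, 3] == pytest.approx(1.0, abs=1e-5)

    @pytest.mark.parametrize("fixture,bound", [("harmonic_diatomic", 1e-6),
                                               ("bent_triatomic", 1e-4)])
    def test_symmetry_before_symmetrization(self, fixture, bound, request):
        """Raw finite-difference asymmetry is at truncation level: ~1e-9
        for the unit-stiffness diatomic, ~1e-5 for stiff bonded terms."""
        mol = request.getfixturevalue(fixture)
        calc = OracleCalculator(mol)
        g = mol.geometry
        n = g.n_atoms
        raw = np.zeros((3 * n, 3 * n))
        for i in range(n):
            for c in range(3):
                p = g.positions.copy()
                p[i, c] += 1e-3
                _, fp, _ = calc.calculate(g.with_positions(p))
                p[i, c] -= 2e-3
                _, fm, _ = calc.calculate(g.with_positions(p))
                raw[3 * i + c] = -(fp - fm).ravel() / 2e-3
        assert np.abs(raw - raw.T).max() < bound

    def test_nonpositive_step_rejected(self, harmonic_diatomic):
        with pytest.raises(ValueError):
            hessian(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry, h=0)


class TestNormalModes:
    def test_diatomic_stretch_frequency_closed_form(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        non_rigid = modes.non_rigid_indices()
        assert non_rigid.size == 1
        assert modes.frequencies[non_rigid[0]] == pytest.approx(
            DIATOMIC_STRETCH, abs=0.1
        )
        # inverse-square-displacement convention: equal-mass diatomic -> m
        assert modes.reduced_masses[non_rigid[0]] == pytest.approx(1.0, abs=1e-6)

    def test_mode_counting_nonlinear_triatomic(self, bent_triatomic):
        modes = analyze(OracleCalculator(bent_triatomic), bent_triatomic.geometry)
        assert modes.non_rigid_indices().size == 3
        assert modes.rigid_mask().sum() == 6

    def test_modes_orthonormal(self, bent_triatomic):
        modes = analyze(OracleCalculator(bent_triatomic), bent_triatomic.geometry)
        gram = modes.modes.T @ modes.modes
        np.testing.assert_allclose(gram, np.eye(9), atol=1e-8)

    def test_zero_hessian_gives_zero_frequencies(self):
        nm = normal_modes(np.zeros((6, 6)), np.array([1.0, 12.0]))
        np.testing.assert_allclose(nm.frequencies, 0.0, atol=1e-12)

    def test_nonfinite_hessian_rejected(self):
        h = np.zeros((6, 6))
        h[0, 0] = np.nan
        with pytest.raises(ValueError):
            normal_modes(h, np.ones(2))

    def test_frequencies_rotation_invariant(self, bent_triatomic):
        from scipy.spatial.transform import Rotation

        calc = OracleCalculator(bent_triatomic)
        ref = analyze(calc, bent_triatomic.geometry)
        R = Rotation.from_euler("zyx", [31.0, -57.0, 12.0], degrees=True).as_matrix()
        rot_geom = bent_triatomic.geometry.with_positions(
            bent_triatomic.geometry.positions @ R.T
        )
        rot = analyze(calc_rot := _RotatedOracle(bent_triatomic, R), rot_geom)
        keep_ref = ref.non_rigid_indices()
        keep_rot = rot.non_rigid_indices()
        np.testing.assert_allclose(
            rot.frequencies[keep_rot], ref.frequencies[keep_ref], atol=0.1
        )


class _RotatedOracle:
    """Oracle for the same molecule expressed in a rotated frame."""

    def __init__(self, mol, R):
        self.mol, self.R = mol, R

    def calculate(self, geometry):
        back = geometry.with_positions(geometry.positions @ self.R)
        s = evaluate(self.mol, back)
        return s.energy, s.forces @ self.R.T, s.dipole @ self.R.T


class TestHarmonicIR:
    def test_zero_charges_silent(self, harmonic_diatomic):
        mol = SurrogateMolecule(
            harmonic_diatomic.geometry,
            [Bond(0, 1, "harmonic", r0=1.0, k=1.0)],
            charges=np.zeros(2),
            name="neutral",
        )
        modes = analyze(OracleCalculator(mol), mol.geometry)
        spec = harmonic_ir(lambda g: dipole_moment(mol, g), mol.geometry, modes)
        assert np.allclose(spec.intensities, 0.0, atol=1e-16)

    def test_charged_diatomic_single_stick_quadratic_in_charge(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        spec = harmonic_ir(
            lambda g: dipole_moment(harmonic_diatomic, g),
            harmonic_diatomic.geometry,
            modes,
        )
        assert spec.n_points == 1
        assert spec.wavenumbers[0] == pytest.approx(DIATOMIC_STRETCH, abs=0.1)
        assert spec.intensities[0] > 0

        doubled = SurrogateMolecule(
            harmonic_diatomic.geometry,
            harmonic_diatomic.bonds,
            charges=2.0 * harmonic_diatomic.charges,
            name="doubled",
        )
        spec2 = harmonic_ir(
            lambda g: dipole_moment(doubled, g), doubled.geometry, modes
        )
        np.testing.assert_allclose(spec2.wavenumbers, spec.wavenumbers)
        np.testing.assert_allclose(spec2.intensities, 4.0 * spec.intensities, rtol=1e-6)

    def test_nonpositive_dq_rejected(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        with pytest.raises(ValueError):
            harmonic_ir(
                lambda g: dipole_moment(harmonic_diatomic, g),
                harmonic_diatomic.geometry,
                modes,
                dq=0.0,
            )


class TestNormalModeSampling:
    def test_sample_counts(self, bent_triatomic):
        modes = analyze(OracleCalculator(bent_triatomic), bent_triatomic.geometry)
        geoms = normal_mode_sample(bent_triatomic.geometry, modes, frames_per_mode=10)
        assert len(geoms) == 30  # 3 non-rigid modes × 10 frames

    def test_single_frame_displaces_along_mode(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        (g,) = normal_mode_sample(harmonic_diatomic.geometry, modes, frames_per_mode=1)
        disp = (g.positions - harmonic_diatomic.geometry.positions).ravel()
        m = modes.non_rigid_indices()[0]
        mode_dir = modes.cartesian_displacement(m).ravel()
        cosine = abs(disp @ mode_dir) / (
            np.linalg.norm(disp) * np.linalg.norm(mode_dir)
        )
        assert cosine == pytest.approx(1.0, abs=1e-8)

    def test_sampled_energies_bounded_by_thermal_amplitude(self):
        t_ref = 300.0
        for mol in make_surrogate_suite(4, (2, 5), seed=6):
            modes = analyze(OracleCalculator(mol), mol.geometry)
            geoms = normal_mode_sample(mol.geometry, modes, frames_per_mode=10, t_ref=t_ref)
            for g in geoms:
                energy = evaluate(mol, g).energy
                assert energy <= 1.10 * KB * t_ref  # 10% anharmonicity slack

    def test_unminimized_geometry_guard_overridable(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        stretched = harmonic_diatomic.geometry.with_positions(
            [[0, 0, 0], [1.3, 0, 0]]
        )
        with pytest.raises(UnminimizedGeometryError):
            normal_mode_sample(
                stretched, modes, calculator=OracleCalculator(harmonic_diatomic)
            )
        with pytest.warns(UserWarning):
            normal_mode_sample(
                stretched,
                modes,
                calculator=OracleCalculator(harmonic_diatomic),
                allow_unminimized=True,
            )

    def test_zero_frames_rejected(self, harmonic_diatomic):
        modes = analyze(OracleCalculator(harmonic_diatomic), harmonic_diatomic.geometry)
        with pytest.raises(ValueError):
            normal_mode_sample(harmonic_diatomic.geometry, modes, frames_per_mode=0)
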
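"""Reference potential, committee statistics, and the dipole model."""

import numpy as np
import pytest

from irmd import Geometry, MDSettings, init_velocities, run_md
from irmd.core import ForceUncertaintyAbort, LabeledSample
from irmd.models import (
    ChargeDipoleModel,
    Committee,
    CommitteeCalculator,
    Hyperparams,
    KernelPotential,
    ModelError,
    committee_predict,
    fit_committee,
    fit_dipole_model,
    fit_reference_model,
    frame_uncertainty,
    pair_descriptor,
    relative_force_error,
)
from irmd.oracle import (
    Bond,
    OracleCalculator,
    SurrogateMolecule,
    evaluate,
    make_surrogate_suite,
)
from irmd.active_learning import initial_dataset


def _md_samples(mol, n_steps=4000, record_every=10, temperature=300.0, seed=0):
    calc = OracleCalculator(mol)
    g = init_velocities(mol.geometry, temperature, seed=seed)
    traj = run_md(
        calc, g,
        MDSettings(n_steps=n_steps, record_every=record_every, temperature=temperature),
    )
    return [evaluate(mol, f.with_velocities(None)) for f in traj.frames]


class _FixedForceModel:
    """Test stub returning a constant force field."""

    def __init__(self, energy, forces):
        self.energy, self.forces = energy, np.asarray(forces, dtype=float)

    def predict(self, geometry):
        return self.energy, self.forces.copy()


class TestPairDescriptor:
    def test_permutation_invariance(self):
        g1 = Geometry(("H", "H", "O"), [[0, 0, 0], [2, 0, 0], [1, 1, 0]])
        g2 = Geometry(("H", "H", "O"), [[2, 0, 0], [0, 0, 0], [1, 1, 0]])
        np.testing.assert_allclose(pair_descriptor(g1), pair_descriptor(g2), atol=1e-14)

    def test_gradient_matches_finite_differences(self):
        g = Geometry(("C", "O", "H"), [[0, 0, 0], [1.3, 0.1, 0], [0.4, 1.0, 0.2]])
        feats, grad = pair_descriptor(g, with_gradient=True)
        h = 1e-6
        for i in range(3):
            for c in range(3):
                p = g.positions.copy()
                p[i, c] += h
                fp = pair_descriptor(g.with_positions(p))
                p[i, c] -= 2 * h
                fm = pair_descriptor(g.with_positions(p))
                np.testing.assert_allclose(grad[:, i, c], (fp - fm) / (2 * h), atol=1e-6)


class TestKernelPotential:
    def test_diatomic_energy_rmse_under_10_meV(self):
        mol = make_surrogate_suite(1, (2, 2), seed=20)[0]
        samples = _md_samples(mol)
        model = fit_reference_model(samples[:200])
        held_out = samples[200:250]
        errs = [model.predict(s.geometry)[0] - s.energy for s in held_out]
        assert np.sqrt(np.mean(np.square(errs))) < 0.010

    def test_training_point_reproduced_at_tiny_ridge(self, bent_triatomic):
        samples = initial_dataset([bent_triatomic])[0][::3]  # well separated
        model = fit_reference_model(samples, Hyperparams(ridge=1e-12, linear=0.0))
        s = samples[3]
        assert model.predict(s.geometry)[0] == pytest.approx(s.energy, abs=1e-8)

    def test_too_few_samples_rejected(self, harmonic_diatomic):
        samples = initial_dataset([harmonic_diatomic])[0][:3]
        with pytest.raises(ModelError):
            fit_reference_model(samples)

    def test_predicted_forces_match_energy_gradient(self, bent_triatomic):
        samples = initial_dataset([bent_triatomic])[0]
        model = fit_reference_model(samples)
        g = samples[7].geometry
        _, forces = model.predict(g)
        h = 1e-5
        for i in range(3):
            for c in range(3):
                p = g.positions.copy()
                p[i, c] += h
                ep, _ = model.predict(g.with_positions(p))
                p[i, c] -= 2 * h
                em, _ = model.predict(g.with_positions(p))
                assert forces[i, c] == pytest.approx(-(ep - em) / (2 * h), abs=1e-5)

    def test_heldout_error_decreases_with_training_size(self):
        """Median learning curve over 5 shuffles: RMSE non-increasing as
        the training set doubles 25 → 50 → 100 → 200."""
        mol = make_surrogate_suite(1, (3, 3), seed=21)[0]
        pool = []
        for t_idx, T in enumerate((300.0, 500.0, 700.0)):
            pool += _md_samples(mol, n_steps=3000, temperature=T, seed=t_idx)[1:]
        rng = np.random.default_rng(0)
        curves = []
        for _ in range(5):
            idx = rng.permutation(len(pool))
            test = [pool[i] for i in idx[:60]]
            train = [pool[i] for i in idx[60:]]
            row = []
            for n in (25, 50, 100, 200):
                m = fit_reference_model(train[:n])
                row.append(
                    np.sqrt(np.mean([(m.predict(s.geometry)[0] - s.energy) ** 2 for s in test]))
                )
            curves.append(row)
        median = np.median(np.array(curves), axis=0)
        assert all(np.diff(median) <= 0)


class TestCommitteeStatistics:
    def test_identical_members_zero_std(self, harmonic_diatomic):
        m = _FixedForceModel(1.0, [[0.1, 0, 0], [-0.1, 0, 0]])
        com = Committee(members=[m, m, m])
        _, _, std = committee_predict(com, harmonic_diatomic.geometry)
        np.testing.assert_allclose(std, 0.0, atol=1e-15)
        assert relative_force_error(com, harmonic_diatomic.geometry) == pytest.approx(0.0, abs=1e-14)
        assert frame_uncertainty(com, harmonic_diatomic.geometry) == pytest.approx(0.0, abs=1e-14)

    def test_opposite_forces_two_point_std(self, harmonic_diatomic):
        f = np.array([[0.3, -0.2, 0.1], [-0.3, 0.2, -0.1]])
        com = Committee(members=[_FixedForceModel(0.0, f), _FixedForceModel(0.0, -f)])
        mean_e, mean_f, std = committee_predict(com, harmonic_diatomic.geometry)
        np.testing.assert_allclose(mean_f, 0.0, atol=1e-15)
        np.testing.assert_allclose(std, np.abs(f), atol=1e-15)

    def test_single_member_uncertainty_rejected(self, harmonic_diatomic):
        com = Committee(members=[_FixedForceModel(0.0, np.zeros((2, 3)))])
        with pytest.raises(ModelError):
            committee_predict(com, harmonic_diatomic.geometry)

    def test_relative_error_eps_dominated_limit(self, harmonic_diatomic):
        """Zero mean forces with variance v → statistic = sqrt(v)/eps."""
        f = np.full((2, 3), 0.01)
        com = Committee(members=[_FixedForceModel(0.0, f), _FixedForceModel(0.0, -f)])
        eps = 0.05
        expected = 0.01 / eps  # std = |f| componentwise, rms mean force = 0
        assert relative_force_error(com, harmonic_diatomic.geometry, eps=eps) == pytest.approx(
            expected
        )

    def test_frame_uncertainty_norm_arithmetic(self, harmonic_diatomic):
        f = np.array([[3e-3, 4e-3, 0.0], [0.0, 0.0, 0.0]])
        com = Committee(members=[_FixedForceModel(0.0, f), _FixedForceModel(0.0, -f)])
        # per-atom std = |f|; norm of atom 0 = 5e-3
        assert frame_uncertainty(com, harmonic_diatomic.geometry) == pytest.approx(5e-3)

    def test_abort_raised_above_threshold(self, harmonic_diatomic):
        f = np.full((2, 3), 1.0)
        com = Committee(members=[_FixedForceModel(0.0, f), _FixedForceModel(0.0, -f)])
        calc = CommitteeCalculator(com, abort_threshold=0.5)
        with pytest.raises(ForceUncertaintyAbort):
            calc.calculate(harmonic_diatomic.geometry)
        assert calc.last_abort_geometry is harmonic_diatomic.geometry

    def test_committee_members_agree_on_training_data(self, bent_triatomic):
        samples = initial_dataset([bent_triatomic])[0]
        com = fit_committee(samples, n_members=3, seed_base=5)
        for s in samples[::7]:
            energies = [m.predict(s.geometry)[0] for m in com.members]
            assert np.ptp(energies) < 5e-3  # eV

    def test_uncertainty_grows_off_manifold(self):
        """Stretching every bond to twice its length moves the structure
        far outside the training manifold; the committee's disagreement
        there exceeds its training-configuration value (median over a
        small suite)."""
        ratios = []
        for mol in make_surrogate_suite(6, (2, 4), seed=4):
            samples = initial_dataset([mol])[0]
            com = fit_committee(samples, n_members=3, seed_base=0)
            train_u = np.median([frame_uncertainty(com, s.geometry) for s in samples])
            g = mol.geometry
            stretched = g.with_positions(
                g.center_of_mass() + 2.0 * (g.positions - g.center_of_mass())
            )
            ratios.append(frame_uncertainty(com, stretched) / (train_u + 1e-12))
        assert np.median(ratios) > 1.0

    def test_retraining_deterministic(self, bent_triatomic):
        samples = initial_dataset([bent_triatomic])[0]
        a = fit_committee(samples, n_members=3, seed_base=9)
        b = fit_committee(samples, n_members=3, seed_base=9)
        g = samples[1].geometry
        for ma, mb in zip(a.members, b.members):
            np.testing.assert_array_equal(ma.predict(g)[1], mb.predict(g)[1])


class TestCheckpointing:
    def test_round_trip_reproduces_predictions(self, bent_triatomic, tmp_path):
        samples = initial_dataset([bent_triatomic])[0]
        model = fit_reference_model(samples, seed=3, diversify=True)
        model.save(tmp_path / "m.json")
        back = KernelPotential.load(tmp_path / "m.json")
        g = samples[5].geometry.with_positions(samples[5].geometry.positions * 1.2)
        e1, f1 = model.predict(g)
        e2, f2 = back.predict(g)
        assert e2 == pytest.approx(e1, abs=1e-12)
        np.testing.assert_allclose(f2, f1, atol=1e-12)

    def test_unfitted_model_refuses_checkpoint(self):
        with pytest.raises(ModelError):
            KernelPotential().to_dict()


class TestDipoleModel:
    def test_fixed_charge_recovery_under_20_mdebye(self):
        g = Geometry(("C", "N"), [[0, 0, 0], [1.2, 0, 0]])
        mol = SurrogateMolecule(
            g, [Bond(0, 1, "harmonic", r0=1.2, k=25.0)],
            charges=np.array([0.25, -0.25]), name="cn",
        )
        samples = _md_samples(mol, seed=9)
        model = fit_dipole_model(samples[:300])
        errs = [np.abs(model.predict(s.geometry) - s.dipole).mean() for s in samples[300:]]
        assert np.mean(errs) < 0.020  # Debye

    def test_translation_invariance(self):
        g = Geometry(("C", "N"), [[0, 0, 0], [1.2, 0, 0]])
        mol = SurrogateMolecule(
            g, [Bond(0, 1, "harmonic", r0=1.2, k=25.0)],
            charges=np.array([0.25, -0.25]), name="cn",
        )
        samples = _md_samples(mol, n_steps=1000, seed=10)
        model = fit_dipole_model(samples)
        test_g = samples[-1].geometry
        shifted = test_g.with_positions(test_g.positions + np.array([9.0, -4.0, 2.5]))
        np.testing.assert_allclose(
            model.predict(shifted), model.predict(test_g), atol=1e-10
        )

    def test_predicted_charges_sum_to_zero(self, bent_triatomic):
        samples = [evaluate(bent_triatomic, g.geometry) for g in initial_dataset([bent_triatomic])[0]]
        model = fit_dipole_model(samples)
        q = model.predict_charges(samples[0].geometry)
        assert q.sum() == pytest.approx(0.0, abs=1e-12)

    def test_missing_dipoles_rejected(self, bent_triatomic):
        samples = [
            LabeledSample(s.geometry, energy=s.energy)
            for s in initial_dataset([bent_triatomic])[0]
        ]
        with pytest.raises(ModelError):
            fit_dipole_model(samples)
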
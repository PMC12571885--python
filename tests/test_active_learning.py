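"""Active-learning loop: dataset bookkeeping, acquisition counts, split
semantics, retraining determinism and the harmonic-MAE validation metric."""

import numpy as np
import pytest

from irmd.active_learning import (
    ALState,
    ActiveLearningError,
    acquire,
    harmonic_mae,
    initial_dataset,
    retrain,
    run_active_learning,
    split_dataset,
)
from irmd.config import RunConfig
from irmd.harmonic import analyze, normal_modes
from irmd.oracle import OracleCalculator, make_surrogate_suite
from irmd.models import fit_committee


@pytest.fixture(scope="module")
def small_suite():
    return make_surrogate_suite(2, (2, 3), seed=30)


class TestInitialDataset:
    def test_counts_follow_mode_arithmetic(self, bent_triatomic, harmonic_diatomic):
        data = initial_dataset([bent_triatomic, harmonic_diatomic])
        assert len(data[0]) == 30  # 3 non-rigid modes × 10
        assert len(data[1]) == 10  # one stretch mode

    def test_all_samples_fully_labelled(self, bent_triatomic):
        for s in initial_dataset([bent_triatomic])[0]:
            assert s.energy is not None and s.forces is not None and s.dipole is not None

    def test_zero_frames_rejected(self, bent_triatomic):
        with pytest.raises(ValueError):
            initial_dataset([bent_triatomic], frames_per_mode=0)


class TestSplit:
    def test_80_20_counts(self, bent_triatomic):
        data = {0: initial_dataset([bent_triatomic])[0]}  # 30 samples
        train, test = split_dataset(data, ratio=0.8, seed=1)
        assert len(train[0]) == 24 and len(test[0]) == 6

    def test_deterministic_and_disjoint(self, bent_triatomic):
        data = {0: initial_dataset([bent_triatomic])[0]}
        t1, v1 = split_dataset(data, seed=2)
        t2, v2 = split_dataset(data, seed=2)
        assert [id(s) for s in t1[0]] == [id(s) for s in t2[0]]
        assert not ({id(s) for s in t1[0]} & {id(s) for s in v1[0]})

    def test_degenerate_ratio_rejected(self, bent_triatomic):
        data = {0: initial_dataset([bent_triatomic])[0]}
        with pytest.raises(ValueError):
            split_dataset(data, ratio=1.0)

    def test_tiny_bucket_rejected(self, bent_triatomic):
        data = {0: initial_dataset([bent_triatomic])[0][:3]}
        with pytest.raises(ActiveLearningError):
            split_dataset(data)


def _prepared_state(molecules, seed=1, explore_ps=0.1, abort_threshold=1e6):
    # a permissive abort threshold keeps yields deterministic in count tests
    cfg = RunConfig(
        n_molecules=len(molecules), size_range=(2, 3), explore_ps=explore_ps,
        max_iterations=3, seed=seed, record_every=10,
    )
    cfg.abort_threshold = abort_threshold
    state = ALState(molecules=molecules, config=cfg)
    state.dataset = initial_dataset(molecules)
    for samples in state.dataset.values():
        for s in samples:
            state.seen_hashes.add(s.geometry.content_hash())
    state.train, state.test = split_dataset(state.dataset, seed=seed)
    retrain(state, seed_base=seed)
    return state


class TestAcquire:
    def test_default_yield_fifteen_per_molecule(self, small_suite):
        state = _prepared_state(small_suite)
        new = acquire(state)
        for idx in range(len(small_suite)):
            assert len(new[idx]) == 15  # 5 per temperature × 3 temperatures

    def test_unfitted_committee_rejected(self, small_suite):
        cfg = RunConfig(n_molecules=2, size_range=(2, 3), seed=0)
        state = ALState(molecules=small_suite, config=cfg)
        with pytest.raises(ActiveLearningError):
            acquire(state)

    def test_no_duplicate_labelling(self, small_suite):
        state = _prepared_state(small_suite, seed=3)
        new = acquire(state)
        hashes = [s.geometry.content_hash() for v in new.values() for s in v]
        assert len(hashes) == len(set(hashes))

    def test_aborted_run_still_contributes_the_abort_frame(self, small_suite):
        """A run that trips the sanity check at its first step offers the
        abort-triggering structure itself as the candidate."""
        state = _prepared_state(small_suite, seed=11, abort_threshold=-1.0)
        new = acquire(state)
        for idx in new:
            assert 1 <= len(new[idx]) <= 3  # one abort frame per temperature

    def test_restarts_updated_with_velocities(self, small_suite):
        state = _prepared_state(small_suite, seed=4)
        acquire(state)
        for (idx, T), frame in state.restarts.items():
            assert frame.velocities is not None


class TestRetrain:
    def test_same_seed_same_committee(self, small_suite):
        state = _prepared_state(small_suite, seed=5)
        a = retrain(state, seed_base=77)
        pa = [m.predict(state.dataset[0][0].geometry) for m in a[0].members]
        b = retrain(state, seed_base=77)
        pb = [m.predict(state.dataset[0][0].geometry) for m in b[0].members]
        for (ea, fa), (eb, fb) in zip(pa, pb):
            assert ea == eb
            np.testing.assert_array_equal(fa, fb)

    def test_member_count_default_three(self, small_suite):
        state = _prepared_state(small_suite, seed=6)
        assert all(c.size == 3 for c in state.committees.values())

    def test_different_seed_base_changes_non_primary_members(self, small_suite):
        state = _prepared_state(small_suite, seed=7)
        a = retrain(state, seed_base=1)
        fa = a[0].members[1].predict(
            small_suite[0].geometry.with_positions(small_suite[0].geometry.positions * 1.5)
        )[1]
        b = retrain(state, seed_base=2)
        fb = b[0].members[1].predict(
            small_suite[0].geometry.with_positions(small_suite[0].geometry.positions * 1.5)
        )[1]
        assert not np.allclose(fa, fb)


class TestHarmonicMAE:
    def test_oracle_as_model_is_exact(self, small_suite):
        mae, rmse = harmonic_mae(
            {i: OracleCalculator(m) for i, m in enumerate(small_suite)}, small_suite
        )
        assert mae == pytest.approx(0.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-6)

    def test_constant_shift_arithmetic(self, bent_triatomic):
        """A model whose Hessian scales the oracle's by (1+δ)² shifts every
        frequency by the same factor; MAE/RMSE follow exactly."""

        class Scaled:
            def __init__(self, mol, factor):
                self.calc = OracleCalculator(mol)
                self.factor = factor

            def calculate(self, geometry):
                e, f, mu = self.calc.calculate(geometry)
                return self.factor * e, self.factor * f, mu

        oracle_modes = analyze(OracleCalculator(bent_triatomic), bent_triatomic.geometry)
        keep = oracle_modes.non_rigid_indices()
        freqs = np.abs(oracle_modes.frequencies[keep])
        factor = 1.02
        mae, rmse = harmonic_mae(Scaled(bent_triatomic, factor**2), [bent_triatomic])
        expected = (factor - 1.0) * freqs
        assert mae == pytest.approx(expected.mean(), rel=1e-3)
        assert rmse == pytest.approx(np.sqrt((expected**2).mean()), rel=1e-3)


class TestRunActiveLearning:
    def test_bookkeeping_three_iterations(self, small_suite):
        cfg = RunConfig(
            n_molecules=2, size_range=(2, 3), explore_ps=0.1, max_iterations=3,
            mae_threshold_cm1=1e-6, seed=8, record_every=10,
        )
        state = run_active_learning(small_suite, cfg)
        assert len(state.metrics) == 3
        sizes = [m["dataset_size"] for m in state.metrics]
        assert sizes == sorted(sizes) and sizes[-1] > sizes[0]
        acquired = [m["acquired"] for m in state.metrics]
        assert acquired[0] == 0 and all(a > 0 for a in acquired[1:])
        # dataset size = initial + Σ acquired
        assert sizes[-1] == sizes[0] + sum(acquired)

    def test_metrics_written_to_workdir(self, small_suite, tmp_path):
        cfg = RunConfig(
            n_molecules=2, size_range=(2, 3), explore_ps=0.1, max_iterations=2,
            mae_threshold_cm1=1e-6, seed=9, record_every=10,
            workdir=str(tmp_path / "run"),
        )
        run_active_learning(small_suite, cfg)
        lines = (tmp_path / "run" / "metrics.jsonl").read_text().splitlines()
        assert len(lines) == 2
        assert (tmp_path / "run" / "iter_02" / "dataset.extxyz").exists()

    def test_threshold_stops_immediately_for_easy_target(self, harmonic_diatomic):
        """A generous threshold is met by the iteration-1 model on a
        diatomic, so the loop stops after one record."""
        cfg = RunConfig(
            n_molecules=1, size_range=(2, 2), explore_ps=0.1, max_iterations=5,
            mae_threshold_cm1=500.0, seed=10, record_every=10,
        )
        state = run_active_learning([harmonic_diatomic], cfg)
        assert len(state.metrics) == 1
        assert state.metrics[0]["converged"]
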
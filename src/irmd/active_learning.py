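"""Committee-uncertainty active learning of the surrogate potential.

One iteration: explore with committee-driven MD at three temperatures
(continuing each molecule's stored restart state), rank recorded frames by
the committee's force-uncertainty score, oracle-label the top five per
temperature (15 per molecule), split the grown dataset 80:20, retrain all
committee members from scratch with fresh seeds, and evaluate the
harmonic-frequency MAE of the first member against the oracle.  The loop
stops when that MAE falls below 5 cm⁻¹ or after a maximum number of
iterations (default 40).

Iteration 1 trains and evaluates on the initial normal-mode dataset alone;
acquisition starts with iteration 2, so the metrics history has exactly one
record per iteration and the first record describes the initial model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import RunConfig
from .core import Geometry, LabeledSample, as_calculator
from .dynamics import MDSettings, init_velocities, run_md
from .harmonic import RIGID_MODE_THRESHOLD, analyze, hessian, normal_mode_sample, normal_modes
from .models import (
    Committee,
    CommitteeCalculator,
    Hyperparams,
    fit_committee,
    frame_uncertainty,
)
from .oracle import OracleCalculator, SurrogateMolecule, evaluate

Dataset = Dict[int, List[LabeledSample]]


class ActiveLearningError(RuntimeError):
    pass


def initial_dataset(
    molecules: Sequence[SurrogateMolecule],
    frames_per_mode: int = 10,
    t_ref: float = 300.0,
) -> Dataset:
    """Oracle-labelled normal-mode samples: per molecule, the first 10
    geometries along each non-rigid normal mode (amplitude set by k_B·300 K)."""
    if frames_per_mode < 1:
        raise ValueError("frames_per_mode must be >= 1")
    dataset: Dataset = {}
    for idx, mol in enumerate(molecules):
        modes = analyze(OracleCalculator(mol), mol.geometry)
        geoms = normal_mode_sample(
            mol.geometry, modes, frames_per_mode=frames_per_mode, t_ref=t_ref,
            calculator=OracleCalculator(mol),
        )
        dataset[idx] = [evaluate(mol, g) for g in geoms]
    return dataset


def split_dataset(
    dataset: Dataset, ratio: float = 0.8, seed: int = 0
) -> Tuple[Dataset, Dataset]:
    """Per-molecule stratified random split (deterministic for fixed seed)."""
    if not 0 < ratio < 1:
        raise ValueError("split ratio must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train: Dataset = {}
    test: Dataset = {}
    for idx in sorted(dataset):
        samples = dataset[idx]
        if len(samples) < 5:
            raise ActiveLearningError(
                f"molecule {idx} has only {len(samples)} samples; need >= 5"
            )
        perm = rng.permutation(len(samples))
        n_train = int(round(ratio * len(samples)))
        n_train = min(max(n_train, 1), len(samples) - 1)  # both sides non-empty
        train[idx] = [samples[int(i)] for i in perm[:n_train]]
        test[idx] = [samples[int(i)] for i in perm[n_train:]]
    return train, test


@dataclass
class ALState:
    """Mutable loop state: dataset, committees, restart frames, metrics."""

    molecules: Sequence[SurrogateMolecule]
    config: RunConfig
    iteration: int = 0
    dataset: Dataset = field(default_factory=dict)
    train: Dataset = field(default_factory=dict)
    test: Dataset = field(default_factory=dict)
    committees: Dict[int, Committee] = field(default_factory=dict)
    restarts: Dict[Tuple[int, float], Geometry] = field(default_factory=dict)
    rngs: Dict[Tuple[int, float], np.random.Generator] = field(default_factory=dict)
    metrics: List[dict] = field(default_factory=list)
    seen_hashes: set = field(default_factory=set)

    @property
    def dataset_size(self) -> int:
        return sum(len(v) for v in self.dataset.values())


def _restart_key_rng(state: ALState, idx: int, temperature: float):
    key = (idx, temperature)
    if key not in state.rngs:
        # one independent, reproducible stream per (molecule, temperature)
        state.rngs[key] = np.random.default_rng(
            (state.config.seed, idx, int(temperature))
        )
    return key, state.rngs[key]


def acquire(
    state: ALState,
    per_t: Optional[int] = None,
    temperatures: Optional[Sequence[float]] = None,
    explore_ps: Optional[float] = None,
) -> Dataset:
    """One acquisition round: per molecule and temperature, continue the
    stored exploration trajectory under the committee (sanity abort armed),
    rank recorded frames by force-uncertainty, oracle-label the top
    ``per_t`` (ties break toward the earlier frame).

    Yields per_t × |temperatures| new samples per molecule when no abort
    occurs; an aborted run contributes the frames recorded before the abort
    and its restart state is re-seeded with fresh velocities.
    """
    cfg = state.config
    per_t = cfg.per_temperature if per_t is None else per_t
    temperatures = cfg.temperatures if temperatures is None else temperatures
    explore_ps = cfg.explore_ps if explore_ps is None else explore_ps
    n_steps = int(round(1000.0 * explore_ps / cfg.timestep_fs))
    new: Dataset = {}
    for idx, mol in enumerate(state.molecules):
        committee = state.committees.get(idx)
        if committee is None:
            raise ActiveLearningError("committee must be fitted before acquisition")
        calc = CommitteeCalculator(
            committee, abort_threshold=cfg.abort_threshold, force_source="primary"
        )
        new[idx] = []
        for T in temperatures:
            key, rng = _restart_key_rng(state, idx, T)
            start = state.restarts.get(key)
            if start is None or start.velocities is None:
                start = init_velocities(mol.geometry, T, rng=rng)
            calc.last_abort_geometry = None
            traj = run_md(
                calc,
                start,
                MDSettings(dt=cfg.timestep_fs, friction=cfg.friction, temperature=T,
                           n_steps=n_steps, record_every=cfg.record_every),
                rng=rng,
            )
            candidates = traj.frames[1:]  # frame 0 duplicates the restart point
            if traj.aborted and calc.last_abort_geometry is not None:
                # the structure that tripped the sanity check is the most
                # uncertain one seen — make it a candidate too
                candidates = candidates + [calc.last_abort_geometry]
            scores = np.array([frame_uncertainty(committee, g) for g in candidates])
            order = np.argsort(-scores, kind="stable")  # ties -> earlier frame
            picked = 0
            for j in order:
                if picked >= per_t:
                    break
                g = candidates[int(j)].with_velocities(None)
                h = g.content_hash()
                if h in state.seen_hashes:
                    continue
                state.seen_hashes.add(h)
                new[idx].append(evaluate(mol, g))
                picked += 1
            if traj.aborted:
                # discard the unreliable tail state; fresh velocities next time
                last_valid = traj.frames[-1]
                state.restarts[key] = init_velocities(
                    last_valid.with_velocities(None), T, rng=rng
                )
            else:
                state.restarts[key] = traj.frames[-1]
    return new


def retrain(
    state: ALState,
    seed_base: int,
    hyperparams: Optional[Hyperparams] = None,
) -> Dict[int, Committee]:
    """Discard all members and fit fresh per-molecule committees from
    scratch on the current training split (member seeds seed_base+{0..M−1})."""
    committees = {}
    for idx in sorted(state.train):
        committees[idx] = fit_committee(
            state.train[idx],
            n_members=state.config.committee_size,
            seed_base=seed_base,
            hyperparams=hyperparams,
        )
    state.committees = committees
    return committees


def harmonic_mae(
    models,
    molecules: Sequence[SurrogateMolecule],
    h: float = 1e-3,
    threshold: float = RIGID_MODE_THRESHOLD,
) -> Tuple[float, float]:
    """Harmonic-frequency MAE and RMSE (cm⁻¹) of a model vs the oracle.

    ``models`` is one calculator-like object, or a per-molecule sequence /
    dict of them.  Frequencies are compared at the oracle minimum, rigid
    modes excluded (by oracle mode count), imaginary entries entering via
    absolute value, pooled over all non-rigid modes of all molecules.
    """
    errors = []
    for idx, mol in enumerate(molecules):
        if isinstance(models, dict):
            model = models[idx]
        elif isinstance(models, (list, tuple)):
            model = models[idx]
        else:
            model = models
        oracle_modes = analyze(OracleCalculator(mol), mol.geometry, h=h)
        keep = oracle_modes.non_rigid_indices(threshold)
        ref = np.sort(np.abs(oracle_modes.frequencies[keep]))
        model_hess = hessian(as_calculator(model), mol.geometry, h=h)
        model_freqs = np.sort(np.abs(normal_modes(model_hess, mol.geometry.masses).frequencies))
        pred = model_freqs[-ref.size:] if ref.size else np.array([])
        errors.extend(np.abs(pred - ref).tolist())
    errors = np.array(errors)
    if errors.size == 0:
        return 0.0, 0.0
    return float(errors.mean()), float(np.sqrt((errors**2).mean()))


def run_active_learning(
    molecules: Sequence[SurrogateMolecule],
    config: RunConfig,
    hyperparams: Optional[Hyperparams] = None,
) -> ALState:
    """Run the full loop; returns the final state with one metrics record
    per completed iteration.

    Metrics per iteration: dataset size, newly acquired count, harmonic
    MAE/RMSE (cm⁻¹, first committee member) and whether the stopping
    threshold was met.  With ``config.workdir`` set, per-iteration metrics
    stream to ``metrics.jsonl`` and dataset snapshots to extended-XYZ.
    """
    state = ALState(molecules=molecules, config=config)
    state.dataset = initial_dataset(
        molecules, frames_per_mode=config.frames_per_mode, t_ref=config.sample_t_ref
    )
    for samples in state.dataset.values():
        for s in samples:
            state.seen_hashes.add(s.geometry.content_hash())

    workdir = Path(config.workdir) if config.workdir else None
    if workdir:
        workdir.mkdir(parents=True, exist_ok=True)

    for iteration in range(1, config.max_iterations + 1):
        state.iteration = iteration
        acquired = 0
        if iteration > 1:
            new = acquire(state)
            for idx, samples in new.items():
                state.dataset[idx].extend(samples)
                acquired += len(samples)
        state.train, state.test = split_dataset(
            state.dataset, ratio=config.split_ratio,
            seed=config.seed * 1000 + iteration,
        )
        retrain(state, seed_base=config.seed * 100 + iteration * 10, hyperparams=hyperparams)
        first_members = {idx: c.members[0] for idx, c in state.committees.items()}
        mae, rmse = harmonic_mae(first_members, molecules)
        record = {
            "iteration": iteration,
            "dataset_size": state.dataset_size,
            "acquired": acquired,
            "harmonic_mae_cm1": mae,
            "harmonic_rmse_cm1": rmse,
            "converged": mae < config.mae_threshold_cm1,
        }
        state.metrics.append(record)
        if workdir:
            with open(workdir / "metrics.jsonl", "a") as fh:
                fh.write(json.dumps(record) + "\n")
            from .io import write_extxyz

            snap = [s for samples in state.dataset.values() for s in samples]
            it_dir = workdir / f"iter_{iteration:02d}"
            it_dir.mkdir(exist_ok=True)
            write_extxyz(snap, it_dir / "dataset.extxyz")
        if mae < config.mae_threshold_cm1:
            break
    return state
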
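"""Clustering-based held-out test-set construction.

Protocol: a 300 K MD trajectory per molecule, uniform subsampling of 2000
frames, a 2-body MBTR-style descriptor (Gaussian-broadened histograms of
inverse pairwise distances per element-pair channel), k-means with 5
clusters in feature space, and 4 randomly drawn structures per cluster —
20 per molecule.  At desk scale the trajectory length and subsample count
shrink proportionally without changing the selection counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.cluster import KMeans

from .core import Geometry, LabeledSample, Trajectory
from .dynamics import MDSettings, init_velocities, run_md
from .oracle import OracleCalculator, SurrogateMolecule, evaluate


@dataclass
class DescriptorConfig:
    """2-body descriptor channels and broadening.

    ``grid`` spans inverse distances (Å⁻¹) with ``n_bins`` centers;
    ``broadening`` is the Gaussian width in the same 1/r units.
    """

    elements: Tuple[str, ...] = ("H", "C", "N", "O")
    grid_min: float = 0.1
    grid_max: float = 2.0
    n_bins: int = 24
    broadening: float = 0.05

    def __post_init__(self) -> None:
        if self.n_bins < 8:
            raise ValueError("n_bins must be >= 8")
        if self.broadening <= 0:
            raise ValueError("broadening must be positive")
        if self.grid_max <= self.grid_min:
            raise ValueError("grid_max must exceed grid_min")

    @property
    def channels(self) -> List[Tuple[str, str]]:
        e = self.elements
        return [(e[i], e[j]) for i in range(len(e)) for j in range(i, len(e))]

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.n_bins)


def subsample_uniform(trajectory: Trajectory, n: int) -> List[Geometry]:
    """Evenly spaced frames including the first and last."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > trajectory.n_frames:
        raise ValueError(
            f"cannot draw {n} frames from a {trajectory.n_frames}-frame trajectory"
        )
    if n == 1:
        return [trajectory.frames[0]]
    idx = np.round(np.linspace(0, trajectory.n_frames - 1, n)).astype(int)
    return [trajectory.frames[int(i)] for i in idx]


def descriptor(geometry: Geometry, config: Optional[DescriptorConfig] = None) -> np.ndarray:
    """Fixed-length 2-body feature vector, invariant to rotations,
    translations and like-atom permutations."""
    cfg = config or DescriptorConfig()
    for s in geometry.symbols:
        if s not in cfg.elements:
            raise ValueError(f"element {s} is not covered by the descriptor channels")
    pos = geometry.positions
    grid = cfg.grid
    out = np.zeros((len(cfg.channels), cfg.n_bins))
    chan_index = {frozenset(c) if len(set(c)) > 1 else frozenset([c[0]]): i
                  for i, c in enumerate(cfg.channels)}
    n = geometry.n_atoms
    for i in range(n):
        for j in range(i + 1, n):
            r = float(np.linalg.norm(pos[i] - pos[j]))
            if r < 1e-6:
                raise ValueError(f"atoms {i} and {j} overlap")
            key = frozenset((geometry.symbols[i], geometry.symbols[j]))
            c = chan_index[key]
            out[c] += np.exp(-0.5 * ((grid - 1.0 / r) / cfg.broadening) ** 2)
    return out.ravel()


def kmeans_select(
    features: np.ndarray,
    k: int = 5,
    per_cluster: int = 4,
    seed: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """k-means-stratified random selection.

    Clusters the feature rows with k-means (k-means++ init, fixed seed) and
    draws ``per_cluster`` members uniformly without replacement from each
    cluster (all members when a cluster is smaller).  Returns
    ``(selected indices, cluster labels for all rows)``.
    """
    features = np.asarray(features, dtype=float)
    if features.shape[0] < k:
        raise ValueError(f"need at least k={k} samples, got {features.shape[0]}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, max_iter=300,
                random_state=seed)
    labels = km.fit_predict(features)
    rng = np.random.default_rng(seed)
    chosen: List[int] = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        take = min(per_cluster, members.size)
        if take < per_cluster:
            import warnings

            warnings.warn(
                f"cluster {c} has only {members.size} members (< {per_cluster})",
                stacklevel=2,
            )
        chosen.extend(rng.choice(members, size=take, replace=False).tolist())
    return np.array(sorted(chosen), dtype=int), labels


@dataclass
class TestSetProvenance:
    """Per-molecule record of which frames were selected and why."""

    frame_indices: Dict[str, List[int]] = field(default_factory=dict)
    cluster_labels: Dict[str, List[int]] = field(default_factory=dict)


def build_test_set(
    molecules: Sequence[SurrogateMolecule],
    calculators: Optional[Sequence] = None,
    md_ps: float = 100.0,
    n_sub: int = 2000,
    k: int = 5,
    per_cluster: int = 4,
    temperature: float = 300.0,
    dt: float = 0.5,
    friction: float = 0.01,
    record_every: int = 10,
    seed: int = 0,
    descriptor_config: Optional[DescriptorConfig] = None,
) -> Tuple[List[LabeledSample], TestSetProvenance]:
    """Held-out test dataset: per molecule, MD → uniform subsample →
    descriptor → k-means selection → oracle labelling.

    ``calculators`` defaults to each molecule's own oracle (the stand-in
    for driving the MD with the first committee member).  With the default
    k = 5, per_cluster = 4 the yield is 20 structures per molecule.
    """
    prov = TestSetProvenance()
    dataset: List[LabeledSample] = []
    rng = np.random.default_rng(seed)
    for m_idx, mol in enumerate(molecules):
        calc = (
            calculators[m_idx] if calculators is not None else OracleCalculator(mol)
        )
        mol_seed = int(rng.integers(2**31 - 1))
        n_steps = int(round(1000.0 * md_ps / dt))
        start = init_velocities(mol.geometry, temperature, seed=mol_seed)
        traj = run_md(
            calc,
            start,
            MDSettings(dt=dt, friction=friction, temperature=temperature,
                       n_steps=n_steps, seed=mol_seed, record_every=record_every),
        )
        frames = subsample_uniform(traj, min(n_sub, traj.n_frames))
        feats = np.array([descriptor(g, descriptor_config) for g in frames])
        sel, labels = kmeans_select(feats, k=k, per_cluster=per_cluster, seed=mol_seed)
        prov.frame_indices[mol.name] = [int(i) for i in sel]
        prov.cluster_labels[mol.name] = [int(labels[i]) for i in sel]
        for i in sel:
            dataset.append(evaluate(mol, frames[int(i)].with_velocities(None)))
    return dataset, prov
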
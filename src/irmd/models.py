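"""Surrogate potential and dipole models with committee uncertainty.

The reference potential is kernel ridge regression of the total energy on a
permutation-invariant descriptor (per element-pair class, the sorted
inverse interatomic distances), with forces obtained from the analytic
chain-rule gradient of the Gaussian kernel.  It is deterministic given the
training set, hyperparameters and bootstrap seed, which is exactly what the
active-learning loop needs; externally trained potentials can be plugged in
through the same ``fit``/``predict`` contract.

Committee (query-by-ensemble) uncertainty: a deterministic kernel fit has
no weight-initialization randomness to vary, so each non-primary member
carries a seeded randomized-prior function (a random linear tail in
feature space) that the fit cancels on the training data and that takes
over in extrapolation — giving the seed-only diversity of network
ensembles: members agree in-distribution and disagree away from it.  The
committee exposes the relative-force-error sanity statistic that aborts
unreliable MD, and the per-frame acquisition score that ranks candidate
structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import (
    Geometry,
    LabeledSample,
    Calculator,
    ForceUncertaintyAbort,
    validate_same_composition,
)

MIN_TRAINING_SAMPLES = 5


class ModelError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# Pair descriptor with analytic gradient
# --------------------------------------------------------------------------


def _pair_classes(symbols: Sequence[str]) -> List[Tuple[int, int]]:
    """All atom pairs (i < j), ordered by element-pair class then index, so
    the feature layout is fixed for a given composition."""
    pairs = [(i, j) for i in range(len(symbols)) for j in range(i + 1, len(symbols))]
    return sorted(pairs, key=lambda p: (tuple(sorted((symbols[p[0]], symbols[p[1]]))), p))


def pair_descriptor(geometry: Geometry, with_gradient: bool = False):
    """Sorted inverse distances per element-pair class.

    Returns the feature vector, and optionally its gradient d(features)/dx
    of shape (n_features, N, 3).  Sorting happens within each element-pair
    class; the gradient follows the sort permutation (valid almost
    everywhere, which suffices for smooth regression targets).
    """
    symbols = geometry.symbols
    pos = geometry.positions
    pairs = _pair_classes(symbols)
    feats = np.empty(len(pairs))
    raw = []
    for idx, (i, j) in enumerate(pairs):
        rij = pos[i] - pos[j]
        r = np.linalg.norm(rij)
        if r < 1e-10:
            raise ModelError(f"atoms {i},{j} coincide")
        feats[idx] = 1.0 / r
        raw.append((i, j, r, rij))
    # sort descending within each class
    order = np.arange(len(pairs))
    cls = [tuple(sorted((symbols[i], symbols[j]))) for i, j in pairs]
    start = 0
    for end in range(1, len(pairs) + 1):
        if end == len(pairs) or cls[end] != cls[start]:
            seg = order[start:end]
            seg_sorted = seg[np.argsort(-feats[seg], kind="stable")]
            order[start:end] = seg_sorted
            start = end
    feats = feats[order]
    if not with_gradient:
        return feats
    grad = np.zeros((len(pairs), geometry.n_atoms, 3))
    for out_idx, src_idx in enumerate(order):
        i, j, r, rij = raw[src_idx]
        g = -rij / r**3  # d(1/r)/d r_i
        grad[out_idx, i] = g
        grad[out_idx, j] = -g
    return feats, grad


# --------------------------------------------------------------------------
# Kernel ridge potential
# --------------------------------------------------------------------------


@dataclass
class Hyperparams:
    """Reference-model hyperparameters.

    ``sigma`` is the Gaussian kernel length scale in descriptor units
    (``None`` → median pairwise training distance); ``ridge`` the Tikhonov
    regularizer on the kernel matrix.  The ridge default sits above the
    noise floor that temporally correlated (near-duplicate) MD frames
    induce in the kernel matrix; much smaller values let those rows drive
    the coefficients to noise-amplifying magnitudes.
    """

    sigma: Optional[float] = None
    ridge: float = 1e-6
    #: weight of the additive linear (in centred features) kernel term;
    #: gives the model a smooth trend instead of flatlining off-manifold
    #: and lets it represent the members' random prior functions exactly.
    linear: float = 0.01
    #: randomized-prior scale (eV per squared unit feature).  Non-primary
    #: committee members add a seeded random *quadratic* function of the
    #: centred features to their prediction (and subtract it from the fit
    #: target).  Its gradient vanishes at the data centroid and grows with
    #: distance, so members agree in-distribution and disagree
    #: progressively off-manifold — the seed-only diversity of
    #: neural-network ensembles, realized for a deterministic kernel fit.
    #: The primary (validation) member carries no prior.
    prior_scale: float = 1.0


class PotentialModel:
    """Interface: ``fit(samples)`` then ``predict(geometry) -> (E, F)``."""

    def fit(self, samples: Sequence[LabeledSample]) -> "PotentialModel":
        raise NotImplementedError

    def predict(self, geometry: Geometry) -> Tuple[float, np.ndarray]:
        raise NotImplementedError


class KernelPotential(PotentialModel):
    """Gaussian-kernel ridge regression of total energies with analytic
    force predictions."""

    def __init__(
        self,
        hyperparams: Optional[Hyperparams] = None,
        prior_seed: Optional[int] = None,
    ):
        self.hp = hyperparams or Hyperparams()
        self.prior_seed = prior_seed
        self._fitted = False

    def fit(self, samples: Sequence[LabeledSample]) -> "KernelPotential":
        if len(samples) < MIN_TRAINING_SAMPLES:
            raise ModelError(
                f"need at least {MIN_TRAINING_SAMPLES} training samples, got {len(samples)}"
            )
        self.symbols = validate_same_composition(samples)
        if any(s.energy is None for s in samples):
            raise ModelError("all training samples must carry energies")
        X = np.array([pair_descriptor(s.geometry) for s in samples])
        y = np.array([s.energy for s in samples], dtype=float)
        self.y_mean = float(y.mean())
        sigma = self.hp.sigma
        if sigma is None:
            d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            med = float(np.median(np.sqrt(d2[np.triu_indices(len(X), 1)])))
            sigma = med if med > 1e-12 else 1.0
        self.sigma = sigma
        self.x_center = X.mean(axis=0)
        # randomized prior: a fixed random quadratic added to the
        # prediction and subtracted from the fit target, so it is nearly
        # invisible on the data and grows quadratically off it
        if self.prior_seed is not None and self.hp.prior_scale > 0:
            G = np.random.default_rng(self.prior_seed).normal(
                0.0, self.hp.prior_scale, size=(X.shape[1], X.shape[1])
            )
            self.prior_q = 0.5 * (G + G.T)
        else:
            self.prior_q = None
        K = self._kernel(X, X)
        K_reg = K + self.hp.ridge * np.eye(len(X))
        target = y - self.y_mean
        if self.prior_q is not None:
            Xc = X - self.x_center
            target = target - 0.5 * np.einsum("nd,de,ne->n", Xc, self.prior_q, Xc)
        try:
            self.alpha = np.linalg.solve(K_reg, target)
        except np.linalg.LinAlgError as exc:
            raise ModelError(
                "singular kernel system — duplicate structures? try a larger ridge"
            ) from exc
        self.X_train = X
        self._fitted = True
        return self

    def _kernel(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
        k = np.exp(-0.5 * d2 / self.sigma**2)
        if self.hp.linear:
            k = k + self.hp.linear * (A - self.x_center) @ (B - self.x_center).T
        return k

    def predict(self, geometry: Geometry) -> Tuple[float, np.ndarray]:
        if not self._fitted:
            raise ModelError("model is not fitted")
        if geometry.symbols != self.symbols:
            raise ModelError("geometry composition differs from the training set")
        feats, grad = pair_descriptor(geometry, with_gradient=True)
        diff = feats[None, :] - self.X_train  # (n, D)
        k = np.exp(-0.5 * (diff**2).sum(-1) / self.sigma**2)  # (n,)
        # dE/df_j = Σ_n α_n [k_n (x_nj − f_j)/σ² + c (x_nj − x̄_j)]
        dE_df = ((self.alpha * k)[:, None] * (-diff)).sum(0) / self.sigma**2  # (D,)
        energy = self.y_mean + float(self.alpha @ k)
        if self.hp.linear:
            xc = self.X_train - self.x_center
            energy += self.hp.linear * float(self.alpha @ (xc @ (feats - self.x_center)))
            dE_df = dE_df + self.hp.linear * (self.alpha @ xc)
        if self.prior_q is not None:
            fc = feats - self.x_center
            qf = self.prior_q @ fc
            energy += 0.5 * float(fc @ qf)
            dE_df = dE_df + qf
        dE_dx = np.einsum("d,dnc->nc", dE_df, grad)
        return energy, -dE_dx


    # -- checkpointing ------------------------------------------------------

    def to_dict(self) -> dict:
        """Serializable checkpoint: descriptor config, kernel weights,
        hyperparameters, prior, plus a content hash of the training
        descriptors for provenance."""
        import hashlib

        if not self._fitted:
            raise ModelError("cannot checkpoint an unfitted model")
        return {
            "symbols": list(self.symbols),
            "hyperparams": {"sigma": self.sigma, "ridge": self.hp.ridge,
                            "linear": self.hp.linear,
                            "prior_scale": self.hp.prior_scale},
            "prior_seed": self.prior_seed,
            "y_mean": self.y_mean,
            "x_center": self.x_center.tolist(),
            "alpha": self.alpha.tolist(),
            "x_train": self.X_train.tolist(),
            "train_hash": hashlib.sha256(
                np.round(self.X_train, 12).tobytes()
            ).hexdigest(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KernelPotential":
        hp = Hyperparams(sigma=d["hyperparams"]["sigma"],
                         ridge=d["hyperparams"]["ridge"],
                         linear=d["hyperparams"]["linear"],
                         prior_scale=d["hyperparams"]["prior_scale"])
        model = cls(hp, prior_seed=d["prior_seed"])
        model.symbols = tuple(d["symbols"])
        model.sigma = d["hyperparams"]["sigma"]
        model.y_mean = d["y_mean"]
        model.x_center = np.array(d["x_center"])
        model.alpha = np.array(d["alpha"])
        model.X_train = np.array(d["x_train"])
        if model.prior_seed is not None and hp.prior_scale > 0:
            G = np.random.default_rng(model.prior_seed).normal(
                0.0, hp.prior_scale, size=(model.X_train.shape[1],) * 2
            )
            model.prior_q = 0.5 * (G + G.T)
        else:
            model.prior_q = None
        model._fitted = True
        return model

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path) -> "KernelPotential":
        import json
        from pathlib import Path

        return cls.from_dict(json.loads(Path(path).read_text()))


def fit_reference_model(
    samples: Sequence[LabeledSample],
    hyperparams: Optional[Hyperparams] = None,
    seed: int = 0,
    diversify: bool = False,
) -> KernelPotential:
    """Fit one reference potential.

    All models train on the full sample set.  With ``diversify=True`` the
    model carries a seeded randomized-prior tail — invisible on the
    training data, dominant in extrapolation — which is what makes
    committee members disagree where data is absent; without it the fit is
    the prior-free primary / validation configuration.
    """
    if len(samples) < MIN_TRAINING_SAMPLES:
        raise ModelError(
            f"need at least {MIN_TRAINING_SAMPLES} training samples, got {len(samples)}"
        )
    prior_seed = seed if diversify else None
    return KernelPotential(hyperparams, prior_seed=prior_seed).fit(list(samples))


# --------------------------------------------------------------------------
# Committee
# --------------------------------------------------------------------------


@dataclass
class Committee:
    """M independently fitted potentials sharing one predict contract."""

    members: List[PotentialModel]
    member_seeds: List[int] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def fit_committee(
    samples: Sequence[LabeledSample],
    n_members: int = 3,
    seed_base: int = 0,
    hyperparams: Optional[Hyperparams] = None,
) -> Committee:
    """Fit a fresh committee with member seeds ``seed_base + m``.

    Every member trains on the full sample set; members differ only in
    their seeded randomized-prior tails (member 0, the primary model used
    for validation metrics, carries none).  This mirrors seed-only
    ensemble diversity: identical in-distribution behaviour, divergent
    extrapolation.
    """
    seeds = [seed_base + m for m in range(n_members)]
    members = [
        fit_reference_model(samples, hyperparams, seed=s, diversify=(m > 0))
        for m, s in enumerate(seeds)
    ]
    return Committee(members=members, member_seeds=seeds)


def committee_predict(
    committee: Committee, geometry: Geometry
) -> Tuple[float, np.ndarray, np.ndarray]:
    """Mean energy, mean forces and the per-atom component-wise force
    standard deviation (population, across members)."""
    if committee.size < 2:
        raise ModelError("committee uncertainty needs at least 2 members")
    energies, forces = [], []
    for m in committee.members:
        e, f = m.predict(geometry)
        energies.append(e)
        forces.append(f)
    F = np.array(forces)  # (M, N, 3)
    return float(np.mean(energies)), F.mean(axis=0), F.std(axis=0, ddof=0)


def relative_force_error(
    committee: Committee, geometry: Geometry, eps: float = 0.1
) -> float:
    """Root of the mean force variance normalized by the RMS force
    magnitude, regularized by ``eps`` (eV/Å) against division by zero."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    _, mean_f, std_f = committee_predict(committee, geometry)
    num = float(np.sqrt((std_f**2).mean()))
    rms_force = float(np.sqrt((mean_f**2).sum(axis=1).mean()))
    return num / (rms_force + eps)


def frame_uncertainty(committee: Committee, geometry: Geometry) -> float:
    """Acquisition score: max over atoms of the Euclidean norm of the
    per-atom force standard-deviation vector (eV/Å)."""
    _, _, std_f = committee_predict(committee, geometry)
    return float(np.linalg.norm(std_f, axis=1).max())


class CommitteeCalculator(Calculator):
    """Committee-averaged forces for MD, with the relative-force-error
    sanity abort (threshold 0.5 by default) and an optional dipole model."""

    def __init__(
        self,
        committee: Committee,
        dipole_model: Optional["DipoleModel"] = None,
        abort_threshold: Optional[float] = 0.5,
        eps: float = 0.1,
        force_source: str = "mean",
    ):
        if force_source not in ("mean", "primary"):
            raise ValueError("force_source must be 'mean' or 'primary'")
        self.committee = committee
        self.dipole_model = dipole_model
        self.abort_threshold = abort_threshold
        self.eps = eps
        #: 'mean' drives MD with committee-averaged forces (production
        #: protocol); 'primary' drives with member 0 while the full
        #: committee still feeds the uncertainty statistics (exploration
        #: protocol — keeps the prior members' extrapolation tails out of
        #: the dynamics)
        self.force_source = force_source
        #: geometry that last triggered the sanity abort (it is by
        #: construction a maximally uncertain structure, so acquisition may
        #: want to label it)
        self.last_abort_geometry: Optional[Geometry] = None

    def calculate(self, geometry: Geometry):
        preds = [m.predict(geometry) for m in self.committee.members]
        F = np.array([f for _, f in preds])
        std_f = F.std(axis=0, ddof=0)
        if self.force_source == "primary":
            energy, forces = preds[0]
        else:
            energy = float(np.mean([e for e, _ in preds]))
            forces = F.mean(axis=0)
        if self.abort_threshold is not None:
            num = float(np.sqrt((std_f**2).mean()))
            rms = float(np.sqrt((forces**2).sum(axis=1).mean()))
            rel = num / (rms + self.eps)
            if rel > self.abort_threshold:
                self.last_abort_geometry = geometry
                raise ForceUncertaintyAbort(
                    f"relative force error {rel:.3f} exceeds "
                    f"{self.abort_threshold}", rel
                )
        mu = None
        if self.dipole_model is not None:
            mu = self.dipole_model.predict(geometry)
        return energy, forces, mu


# --------------------------------------------------------------------------
# Dipole model
# --------------------------------------------------------------------------


def _atom_features(geometry: Geometry) -> np.ndarray:
    """Per-atom local descriptor: one-hot element block times
    [1, Σ 1/r to H, Σ 1/r to C, Σ 1/r to N, Σ 1/r to O]."""
    elements = ("H", "C", "N", "O")
    n = geometry.n_atoms
    pos = geometry.positions
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    inv = 1.0 / d
    feats = np.zeros((n, len(elements) * (len(elements) + 1)))
    for i, sym in enumerate(geometry.symbols):
        e_idx = elements.index(sym)
        block = np.empty(len(elements) + 1)
        block[0] = 1.0
        for k, other in enumerate(elements):
            mask = np.array([s == other for s in geometry.symbols])
            block[1 + k] = inv[i, mask].sum()
        feats[i, e_idx * (len(elements) + 1) : (e_idx + 1) * (len(elements) + 1)] = block
    return feats


class DipoleModel:
    """Interface: ``fit(samples)`` then ``predict(geometry) -> μ (Debye)``."""

    def fit(self, samples: Sequence[LabeledSample]) -> "DipoleModel":
        raise NotImplementedError

    def predict(self, geometry: Geometry) -> np.ndarray:
        raise NotImplementedError


class ChargeDipoleModel(DipoleModel):
    """Reference dipole model: ridge-regressed per-atom effective charges.

    Charges are linear in per-atom local descriptors and recentred to sum
    exactly to zero, so the predicted dipole μ = Σ q̂_i (r_i − R_COM) is
    rigorously translation invariant.
    """

    def __init__(self, ridge: float = 1e-8):
        self.ridge = ridge
        self._fitted = False

    def fit(self, samples: Sequence[LabeledSample]) -> "ChargeDipoleModel":
        if any(s.dipole is None for s in samples):
            raise ModelError("all samples must carry dipole labels")
        if len(samples) == 0:
            raise ModelError("empty training set")
        from .units import E_ANGSTROM_TO_DEBYE

        rows, targets = [], []
        for s in samples:
            g = s.geometry
            phi = _atom_features(g)  # (N, D)
            rel = g.positions - g.center_of_mass()  # (N, 3)
            phi_c = phi - phi.mean(axis=0, keepdims=True)  # recentring absorbed here
            for c in range(3):
                rows.append(E_ANGSTROM_TO_DEBYE * (phi_c * rel[:, c : c + 1]).sum(axis=0))
                targets.append(s.dipole[c])
        A = np.array(rows)
        b = np.array(targets)
        AtA = A.T @ A + self.ridge * np.eye(A.shape[1])
        self.w = np.linalg.solve(AtA, A.T @ b)
        self._fitted = True
        return self

    def predict_charges(self, geometry: Geometry) -> np.ndarray:
        if not self._fitted:
            raise ModelError("dipole model is not fitted")
        q = _atom_features(geometry) @ self.w
        return q - q.mean()

    def predict(self, geometry: Geometry) -> np.ndarray:
        from .units import E_ANGSTROM_TO_DEBYE

        q = self.predict_charges(geometry)
        rel = geometry.positions - geometry.center_of_mass()
        return E_ANGSTROM_TO_DEBYE * (q[:, None] * rel).sum(axis=0)


def fit_dipole_model(
    samples: Sequence[LabeledSample],
    ridge: float = 1e-8,
    seed: int = 0,
) -> ChargeDipoleModel:
    """Fit the reference charge-regression dipole model (deterministic; the
    seed argument is accepted for contract symmetry with the potential)."""
    return ChargeDipoleModel(ridge=ridge).fit(samples)
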
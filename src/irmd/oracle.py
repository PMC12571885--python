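"""Analytic molecular oracle: a bonded anharmonic force field with a
point-charge dipole surface.

This module plays the role a quantum-chemistry code plays in a real
workflow: it supplies exact reference energies (eV), forces (eV/Å) and
dipole moments (Debye) for any configuration of a
:class:`SurrogateMolecule`, and generates randomized-but-plausible H/C/N/O
molecules with locally minimized reference geometries.  Morse bonds are the
default so the potential energy surface is genuinely anharmonic — the
property the MD-based spectra are meant to capture; harmonic bonds are
retained for closed-form tests.

Energy model::

    E = Σ_bonds V(r) + Σ_angles ½ k_θ (θ − θ0)²
    V_harmonic(r) = ½ k (r − r0)²
    V_morse(r)    = D_e (1 − exp(−a (r − r0)))²

Dipole model: fixed per-atom point charges (summing to zero) referenced to
the centre of mass, μ = Σ_i q_i (r_i − R_COM), converted e·Å → Debye.
Fixed charges give non-trivial IR activity but no charge flux; see the
methods note for what that excludes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .core import Calculator, Geometry, LabeledSample
from .units import ATOMIC_MASSES, E_ANGSTROM_TO_DEBYE, VALENCES


class OracleError(RuntimeError):
    """Evaluation failure (e.g. coincident bonded atoms)."""


class GenerationError(RuntimeError):
    """Surrogate-molecule generation failure (e.g. impossible valences)."""


@dataclass
class Bond:
    i: int
    j: int
    style: Literal["harmonic", "morse"]
    r0: float  # Å
    k: Optional[float] = None  # eV/Å², harmonic
    d_e: Optional[float] = None  # eV, Morse well depth
    a: Optional[float] = None  # Å⁻¹, Morse width

    def __post_init__(self) -> None:
        if self.r0 <= 0:
            raise ValueError("bond r0 must be positive")
        if self.style == "harmonic":
            if self.k is None or self.k <= 0:
                raise ValueError("harmonic bond requires k > 0")
        elif self.style == "morse":
            if self.d_e is None or self.d_e <= 0 or self.a is None or self.a <= 0:
                raise ValueError("Morse bond requires D_e > 0 and a > 0")
        else:
            raise ValueError(f"unknown bond style {self.style!r}")

    @property
    def force_constant(self) -> float:
        """Curvature at the minimum, eV/Å² (2 D_e a² for Morse)."""
        if self.style == "harmonic":
            return float(self.k)
        return 2.0 * self.d_e * self.a**2


@dataclass
class Angle:
    i: int  # terminal
    j: int  # apex
    k: int  # terminal
    k_theta: float  # eV/rad²
    theta0: float  # rad

    def __post_init__(self) -> None:
        if self.k_theta <= 0:
            raise ValueError("angle force constant must be positive")


@dataclass
class SurrogateMolecule:
    """Reference geometry plus bonded-term and charge parameters."""

    geometry: Geometry
    bonds: List[Bond]
    angles: List[Angle] = field(default_factory=list)
    charges: np.ndarray = field(default=None)  # type: ignore[assignment]
    name: str = "surrogate"

    def __post_init__(self) -> None:
        n = self.geometry.n_atoms
        if self.charges is None:
            self.charges = np.zeros(n)
        self.charges = np.asarray(self.charges, dtype=float)
        if self.charges.shape != (n,):
            raise ValueError("charges shape mismatch")
        # zero net charge, enforced exactly
        self.charges = self.charges - self.charges.mean()
        if not self._connected():
            raise GenerationError(f"{self.name}: bond graph is not connected")

    def _connected(self) -> bool:
        n = self.geometry.n_atoms
        if n == 1:
            return True
        adj = {i: set() for i in range(n)}
        for b in self.bonds:
            adj[b.i].add(b.j)
            adj[b.j].add(b.i)
        seen = {0}
        stack = [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == n

    @property
    def n_atoms(self) -> int:
        return self.geometry.n_atoms

    # -- serialization (one plain-text file per molecule) -------------------

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "symbols": list(self.geometry.symbols),
            "positions": self.geometry.positions.tolist(),
            "charges": self.charges.tolist(),
            "bonds": [
                {
                    "i": b.i,
                    "j": b.j,
                    "style": b.style,
                    "r0": b.r0,
                    "k": b.k,
                    "d_e": b.d_e,
                    "a": b.a,
                }
                for b in self.bonds
            ],
            "angles": [
                {"i": a.i, "j": a.j, "k": a.k, "k_theta": a.k_theta, "theta0": a.theta0}
                for a in self.angles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateMolecule":
        return cls(
            geometry=Geometry(tuple(d["symbols"]), np.array(d["positions"])),
            bonds=[Bond(**b) for b in d["bonds"]],
            angles=[Angle(**a) for a in d["angles"]],
            charges=np.array(d["charges"]),
            name=d.get("name", "surrogate"),
        )

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "SurrogateMolecule":
        return cls.from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# Evaluation
# --------------------------------------------------------------------------


def _energy_gradient(mol: SurrogateMolecule, positions: np.ndarray):
    """Total energy and dE/dx (not forces) for positions (N, 3)."""
    energy = 0.0
    grad = np.zeros_like(positions)
    for b in mol.bonds:
        rij = positions[b.i] - positions[b.j]
        r = float(np.linalg.norm(rij))
        if r < 1e-10:
            raise OracleError(
                f"{mol.name}: bonded atoms {b.i},{b.j} coincide (r = 0)"
            )
        u = rij / r
        if b.style == "harmonic":
            dr = r - b.r0
            energy += 0.5 * b.k * dr * dr
            dv = b.k * dr
        else:
            e = math.exp(-b.a * (r - b.r0))
            energy += b.d_e * (1.0 - e) ** 2
            dv = 2.0 * b.d_e * b.a * e * (1.0 - e)
        grad[b.i] += dv * u
        grad[b.j] -= dv * u
    for ang in mol.angles:
        u = positions[ang.i] - positions[ang.j]
        v = positions[ang.k] - positions[ang.j]
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-10 or nv < 1e-10:
            raise OracleError(f"{mol.name}: degenerate angle at atom {ang.j}")
        uh, vh = u / nu, v / nv
        cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
        sin_t = math.sqrt(max(1.0 - cos_t * cos_t, 1e-14))
        theta = math.acos(cos_t)
        dtheta = theta - ang.theta0
        energy += 0.5 * ang.k_theta * dtheta * dtheta
        coeff = ang.k_theta * dtheta
        dth_di = (cos_t * uh - vh) / (nu * sin_t)
        dth_dk = (cos_t * vh - uh) / (nv * sin_t)
        grad[ang.i] += coeff * dth_di
        grad[ang.k] += coeff * dth_dk
        grad[ang.j] -= coeff * (dth_di + dth_dk)
    return energy, grad


def dipole_moment(mol: SurrogateMolecule, geometry: Geometry) -> np.ndarray:
    """Point-charge dipole in Debye, referenced to the centre of mass."""
    rel = geometry.positions - geometry.center_of_mass()
    return E_ANGSTROM_TO_DEBYE * (mol.charges[:, None] * rel).sum(axis=0)


def evaluate(mol: SurrogateMolecule, geometry: Geometry) -> LabeledSample:
    """Exact energy, analytic forces and point-charge dipole for a geometry."""
    if geometry.symbols != mol.geometry.symbols:
        raise OracleError("geometry atom ordering does not match the molecule")
    energy, grad = _energy_gradient(mol, geometry.positions)
    return LabeledSample(
        geometry,
        energy=energy,
        forces=-grad,
        dipole=dipole_moment(mol, geometry),
    )


def finite_difference_check(
    mol: SurrogateMolecule, geometry: Geometry, h: float = 1e-4
) -> float:
    """Max |analytic − central-difference| force deviation, eV/Å."""
    if h <= 0:
        raise ValueError("finite-difference step h must be positive")
    analytic = evaluate(mol, geometry).forces
    pos = geometry.positions
    worst = 0.0
    for i in range(geometry.n_atoms):
        for c in range(3):
            p = pos.copy()
            p[i, c] += h
            e_plus, _ = _energy_gradient(mol, p)
            p[i, c] -= 2 * h
            e_minus, _ = _energy_gradient(mol, p)
            fd_force = -(e_plus - e_minus) / (2 * h)
            worst = max(worst, abs(fd_force - analytic[i, c]))
    return worst


class OracleCalculator(Calculator):
    """Calculator facade over a surrogate molecule (provides dipoles)."""

    def __init__(self, mol: SurrogateMolecule):
        self.mol = mol
        self._masses = mol.geometry.masses
        self._mtot = float(self._masses.sum())

    def calculate(self, geometry: Geometry):
        s = evaluate(self.mol, geometry)
        return s.energy, s.forces, s.dipole

    def calculate_raw(self, positions):
        """Positions-only fast path for tight MD loops (fixed atom order)."""
        energy, grad = _energy_gradient(self.mol, positions)
        com = (self._masses[:, None] * positions).sum(axis=0) / self._mtot
        mu = E_ANGSTROM_TO_DEBYE * (
            self.mol.charges[:, None] * (positions - com)
        ).sum(axis=0)
        return energy, -grad, mu


# --------------------------------------------------------------------------
# Reference-geometry minimization
# --------------------------------------------------------------------------

FORCE_TOL = 1e-3  # eV/Å, max-component convergence target


def minimize_geometry(
    mol: SurrogateMolecule, geometry: Optional[Geometry] = None, force_tol: float = FORCE_TOL
) -> Geometry:
    """Locally minimize a geometry on the oracle surface (L-BFGS with
    analytic gradients) until max |F| < ``force_tol``."""
    g = geometry if geometry is not None else mol.geometry
    x0 = g.positions.ravel().copy()

    def fun(x):
        e, grad = _energy_gradient(mol, x.reshape(-1, 3))
        return e, grad.ravel()

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 2000, "gtol": force_tol * 1e-2, "ftol": 1e-14})
    pos = res.x.reshape(-1, 3)
    _, grad = _energy_gradient(mol, pos)
    if np.abs(grad).max() > force_tol:
        raise GenerationError(
            f"{mol.name}: minimization stalled at max|F| = {np.abs(grad).max():.2e}"
        )
    return g.with_positions(pos)


# --------------------------------------------------------------------------
# Surrogate-suite generation
# --------------------------------------------------------------------------

# Equilibrium bond-length table (Å): typical single-bond values, jittered.
_R0 = {  # keys sorted alphabetically
    ("C", "C"): 1.52, ("C", "N"): 1.45, ("C", "O"): 1.42,
    ("N", "N"): 1.45, ("N", "O"): 1.40, ("O", "O"): 1.45,
    ("C", "H"): 1.09, ("H", "N"): 1.01, ("H", "O"): 0.96, ("H", "H"): 0.74,
}


def _r0_for(a: str, b: str, rng: np.random.Generator) -> float:
    base = _R0[tuple(sorted((a, b)))]
    return base * (1.0 + rng.uniform(-0.03, 0.03))


def _embed(symbols, bonds_ij, r0s, rng) -> np.ndarray:
    """Random spatial embedding: place each atom near its parent at the
    equilibrium bond distance, in a random direction."""
    n = len(symbols)
    pos = np.zeros((n, 3))
    placed = {0}
    parent = {}
    for (i, j) in bonds_ij:
        hi, lo = max(i, j), min(i, j)
        parent.setdefault(hi, lo)
    for idx in range(1, n):
        p = parent.get(idx, 0)
        for _ in range(60):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            cand = pos[p] + r0s[idx] * d
            if all(np.linalg.norm(cand - pos[q]) > 0.7 for q in placed if q != p):
                pos[idx] = cand
                break
        else:
            pos[idx] = pos[p] + r0s[idx] * d
        placed.add(idx)
    return pos


def make_surrogate_molecule(
    n_atoms: int,
    seed: int,
    name: str = "surrogate",
    bond_style: Literal["morse", "harmonic"] = "morse",
    ring_probability: float = 0.15,
) -> SurrogateMolecule:
    """Generate one random, chemically plausible H/C/N/O surrogate.

    A random tree over the atoms respecting nominal valences, an occasional
    ring closure, randomized bond/angle/charge parameters within documented
    ranges, and a locally minimized reference geometry.
    """
    if n_atoms < 2 or n_atoms > 12:
        raise GenerationError("surrogates support 2–12 atoms")
    rng = np.random.default_rng(seed)
    for attempt in range(12):
        try:
            return _try_make(n_atoms, rng, name, bond_style, ring_probability)
        except GenerationError:
            if attempt == 11:
                raise
    raise GenerationError("unreachable")  # pragma: no cover


def _try_make(n_atoms, rng, name, bond_style, ring_probability) -> SurrogateMolecule:
    heavy = ["C", "N", "O"]
    symbols = []
    free = []  # remaining valence
    # first atom heavy when more than a diatomic is requested, so the tree
    # can always grow
    first = rng.choice(heavy) if n_atoms > 2 else rng.choice(heavy + ["H"])
    symbols.append(str(first))
    free.append(VALENCES[symbols[0]])
    bonds_ij: list[tuple[int, int]] = []
    for idx in range(1, n_atoms):
        open_sites = [i for i in range(idx) if free[i] > 0]
        if not open_sites:
            raise GenerationError("no open valence to attach the next atom")
        parent = int(rng.choice(open_sites))
        remaining = n_atoms - idx - 1
        # keep enough open valence to finish the molecule: attaching symbol
        # `s` changes the total free valence by VALENCES[s] - 2
        candidates = [
            s
            for s in heavy + ["H", "H"]  # H twice: organic H:heavy ratio
            if remaining == 0 or sum(free) - 2 + VALENCES[s] >= 1
        ]
        if not candidates:
            raise GenerationError("impossible valence request")
        sym = str(rng.choice(candidates))
        symbols.append(sym)
        free.append(VALENCES[sym] - 1)
        free[parent] -= 1
        bonds_ij.append((parent, idx))
    # occasional ring closure between non-adjacent open-valence atoms
    if rng.random() < ring_probability:
        adjacent = {frozenset(b) for b in bonds_ij}
        open_pairs = [
            (i, j)
            for i in range(n_atoms)
            for j in range(i + 1, n_atoms)
            if free[i] > 0 and free[j] > 0 and frozenset((i, j)) not in adjacent
            and symbols[i] != "H" and symbols[j] != "H"
        ]
        if open_pairs:
            i, j = open_pairs[int(rng.integers(len(open_pairs)))]
            bonds_ij.append((i, j))
            free[i] -= 1
            free[j] -= 1

    r0_by_atom = {0: 0.0}
    bonds: list[Bond] = []
    for (i, j) in bonds_ij:
        r0 = _r0_for(symbols[i], symbols[j], rng)
        r0_by_atom[max(i, j)] = r0
        k = float(rng.uniform(15.0, 45.0))  # eV/Å² — stretch curvature range
        if bond_style == "harmonic":
            bonds.append(Bond(i, j, "harmonic", r0=r0, k=k))
        else:
            d_e = float(rng.uniform(3.0, 6.0))  # eV — typical bond energies
            a = math.sqrt(k / (2.0 * d_e))
            bonds.append(Bond(i, j, "morse", r0=r0, d_e=d_e, a=a))

    # angles: every bonded pair sharing an apex
    neighbors = {i: [] for i in range(n_atoms)}
    for (i, j) in bonds_ij:
        neighbors[i].append(j)
        neighbors[j].append(i)
    angles: list[Angle] = []
    for apex in range(n_atoms):
        nb = sorted(neighbors[apex])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                theta0 = math.radians(float(rng.uniform(104.0, 120.0)))
                k_theta = float(rng.uniform(2.0, 6.0))  # eV/rad²
                angles.append(Angle(nb[x], apex, nb[y], k_theta=k_theta, theta0=theta0))

    # Bond-increment charges: each bond moves charge toward the more
    # electronegative partner, so Σq = 0 exactly, magnitudes are plausible
    # (~0.05–0.3 e) and symmetry-equivalent atoms get identical charges —
    # which keeps the dipole surface learnable from structure.
    chi = {"H": 2.20, "C": 2.55, "N": 3.04, "O": 3.44}  # Pauling
    scale = float(rng.uniform(0.12, 0.22))  # e per electronegativity unit
    charges = np.zeros(n_atoms)
    for (i, j) in bonds_ij:
        dq = scale * (chi[symbols[j]] - chi[symbols[i]])
        charges[i] += dq
        charges[j] -= dq

    r0s = [r0_by_atom.get(i, 1.0) for i in range(n_atoms)]
    positions = _embed(symbols, bonds_ij, r0s, rng)
    mol = SurrogateMolecule(
        geometry=Geometry(tuple(symbols), positions),
        bonds=bonds,
        angles=angles,
        charges=charges,
        name=name,
    )
    geom_min = minimize_geometry(mol)
    # reject embeddings that collapsed non-bonded atoms onto each other
    d = geom_min.positions[:, None, :] - geom_min.positions[None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, np.inf)
    if dist.min() < 0.5:
        raise GenerationError("minimized geometry has clashing atoms")
    mol.geometry = geom_min
    return mol


def make_surrogate_suite(
    n_molecules: int,
    size_range: Tuple[int, int] = (2, 6),
    seed: int = 0,
    bond_style: Literal["morse", "harmonic"] = "morse",
) -> List[SurrogateMolecule]:
    """Generate a deterministic suite of surrogate molecules.

    Stands in for a study set of small organic molecules; sizes are drawn
    uniformly from ``size_range`` (2–12 atoms supported).
    """
    if n_molecules < 1:
        raise GenerationError("need at least one molecule")
    lo, hi = size_range
    if lo < 2 or hi > 12 or lo > hi:
        raise GenerationError("size_range must lie within [2, 12]")
    rng = np.random.default_rng(seed)
    mols = []
    for m in range(n_molecules):
        n_atoms = int(rng.integers(lo, hi + 1))
        mol_seed = int(rng.integers(2**31 - 1))
        mols.append(
            make_surrogate_molecule(
                n_atoms, seed=mol_seed, name=f"surrogate_{m:02d}", bond_style=bond_style
            )
        )
    return mols
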
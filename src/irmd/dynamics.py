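"""Langevin molecular dynamics (BAOAB splitting) for oracle exploration and
committee-model production runs.

The integrator is the BAOAB split of Langevin dynamics: half kick (B), half
drift (A), Ornstein–Uhlenbeck velocity refresh (O), half drift (A), half
kick (B).  With zero friction the O step is the identity and the scheme
reduces to velocity Verlet, so microcanonical energy conservation can be
used as a correctness oracle.  Friction is in fs⁻¹ — note that some MD
engines quote the same numeric value in different time units, which changes
line widths in derived spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import (
    Calculator,
    ForceUncertaintyAbort,
    Geometry,
    Trajectory,
    as_calculator,
)
from .units import FORCE_TO_ACC, KB


@dataclass
class MDSettings:
    """Langevin MD parameters.

    dt in fs (default 0.5), friction in fs⁻¹ (default 0.01), temperature in
    K, ``record_every`` in integrator steps.
    """

    dt: float = 0.5
    friction: float = 0.01
    temperature: float = 300.0
    n_steps: int = 1000
    seed: int = 0
    record_every: int = 1
    #: project out rigid-body rotation and COM drift every step — the
    #: gas-phase vibrational-spectroscopy convention that isolates internal
    #: motion (a free rotor otherwise superimposes broad rotational wings
    #: on the vibrational lines of light molecules)
    remove_rotation: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.temperature < 0:
            raise ValueError("temperature must be non-negative")
        if self.n_steps < 0 or self.record_every < 1:
            raise ValueError("n_steps >= 0 and record_every >= 1 required")


def remove_rigid_motion(positions: np.ndarray, velocities: np.ndarray,
                        masses: np.ndarray) -> np.ndarray:
    """Subtract centre-of-mass velocity and rigid-body rotation.

    The angular velocity solves I ω = L about the COM (pseudo-inverse, so
    linear molecules are handled); the returned velocities contain internal
    motion only.
    """
    m = masses[:, None]
    com = (m * positions).sum(axis=0) / masses.sum()
    r = positions - com
    v = velocities - (m * velocities).sum(axis=0) / masses.sum()
    L = (m * np.cross(r, v)).sum(axis=0)
    r2 = (r**2).sum(axis=1)
    inertia = (masses[:, None, None] * (r2[:, None, None] * np.eye(3)
               - r[:, :, None] * r[:, None, :])).sum(axis=0)
    omega = np.linalg.pinv(inertia, rcond=1e-10) @ L
    return v - np.cross(omega, r)


def init_velocities(
    geometry: Geometry,
    temperature: float,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Geometry:
    """Maxwell–Boltzmann velocities at ``temperature`` with the centre-of-
    mass momentum removed; deterministic for a fixed seed."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = geometry.n_atoms
    if temperature == 0:
        return geometry.with_velocities(np.zeros((n, 3)))
    sigma = np.sqrt(KB * temperature * FORCE_TO_ACC / geometry.masses)  # Å/fs
    v = rng.normal(size=(n, 3)) * sigma[:, None]
    p = (geometry.masses[:, None] * v).sum(axis=0)
    v -= p / geometry.masses.sum()
    return geometry.with_velocities(v)


def run_md(
    calculator,
    geometry: Geometry,
    settings: MDSettings,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Integrate Langevin dynamics; returns a trajectory whose frames carry
    velocities (so runs are continuable) plus per-frame potential energies
    and, when the calculator provides them, dipoles.

    A :class:`ForceUncertaintyAbort` raised by the calculator terminates the
    run and returns the frames recorded so far, flagged ``aborted``.
    """
    calc = as_calculator(calculator)
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    g = geometry
    if g.velocities is None:
        g = init_velocities(g, settings.temperature, rng=rng)

    masses = g.masses[:, None]
    dt = settings.dt
    c1 = float(np.exp(-settings.friction * dt))
    thermal_v2 = KB * settings.temperature * FORCE_TO_ACC / g.masses  # (Å/fs)²
    c2 = np.sqrt(np.maximum(0.0, (1.0 - c1 * c1)) * thermal_v2)[:, None]

    pos = g.positions.copy()
    vel = g.velocities.copy()
    if settings.remove_rotation:
        vel = remove_rigid_motion(pos, vel, g.masses)
        g = g.with_velocities(vel)

    # positions-only fast path for tight loops, when the calculator has one
    raw = getattr(calc, "calculate_raw", None)
    if raw is None:
        def raw(p):
            return calc.calculate(Geometry(g.symbols, p, None, g.masses))

    recorded = [(pos.copy(), vel.copy())]
    energies = []
    dipoles = []
    has_dipoles = True
    aborted = False

    def record(e, mu):
        nonlocal has_dipoles
        recorded.append((pos.copy(), vel.copy()))
        energies.append(e)
        if mu is None:
            has_dipoles = False
        else:
            dipoles.append(np.asarray(mu, dtype=float))

    try:
        e0, forces, mu0 = raw(pos)
    except ForceUncertaintyAbort:
        return Trajectory([g.copy()], dt=dt * settings.record_every, aborted=True)
    energies.insert(0, e0)
    if mu0 is None:
        has_dipoles = False
    else:
        dipoles.append(np.asarray(mu0, dtype=float))
    acc = FORCE_TO_ACC * forces / masses

    try:
        for step in range(1, settings.n_steps + 1):
            vel = vel + 0.5 * dt * acc                 # B
            pos = pos + 0.5 * dt * vel                 # A
            if settings.friction > 0:                  # O
                vel = c1 * vel + c2 * rng.normal(size=vel.shape)
                if settings.remove_rotation:
                    vel = remove_rigid_motion(pos, vel, g.masses)
            pos = pos + 0.5 * dt * vel                 # A
            e, forces, mu = raw(pos)
            acc = FORCE_TO_ACC * forces / masses
            vel = vel + 0.5 * dt * acc                 # B
            if step % settings.record_every == 0:
                record(e, mu)
    except ForceUncertaintyAbort:
        aborted = True

    frames = [Geometry(g.symbols, p, v, g.masses) for p, v in recorded]
    return Trajectory(
        frames,
        dt=dt * settings.record_every,
        dipoles=np.array(dipoles) if (has_dipoles and dipoles) else None,
        energies=np.array(energies),
        aborted=aborted,
    )


def continue_md(
    traj: Trajectory,
    calculator,
    settings: MDSettings,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Continue a trajectory from its final frame (geometry + velocities).

    The returned trajectory concatenates the input with the new segment,
    excluding the duplicated junction frame.  Continuing an aborted run is
    refused — re-seed velocities explicitly instead.
    """
    if traj.aborted:
        raise ValueError("cannot continue an aborted trajectory; re-seed velocities")
    last = traj.frames[-1]
    if last.velocities is None:
        raise ValueError("final frame carries no velocities")
    if settings.dt * settings.record_every != traj.dt:
        raise ValueError("continuation must use the same recording interval")
    new = run_md(calculator, last, settings, rng=rng)

    def cat(a, b):
        if a is None or b is None:
            return None
        return np.concatenate([a, b[1:]])

    return Trajectory(
        traj.frames + new.frames[1:],
        dt=traj.dt,
        dipoles=cat(traj.dipoles, new.dipoles),
        energies=cat(traj.energies, new.energies),
        aborted=new.aborted,
    )


def production_run(
    calculator,
    geometry: Geometry,
    temperature: float = 300.0,
    thermalize_ps: float = 5.0,
    production_ps: float = 50.0,
    dt: float = 0.5,
    friction: float = 0.01,
    seed: int = 0,
    remove_rotation: bool = False,
) -> Trajectory:
    """Thermalize then record a production trajectory for IR work.

    Defaults follow the standard protocol: 5 ps thermalization discarded,
    50 ps production at 0.5 fs with Langevin friction 0.01 fs⁻¹.  Only the
    production segment is returned.
    """
    rng = np.random.default_rng(seed)
    n_therm = int(round(1000.0 * thermalize_ps / dt))
    n_prod = int(round(1000.0 * production_ps / dt))
    therm = run_md(
        calculator,
        init_velocities(geometry, temperature, rng=rng),
        MDSettings(dt=dt, friction=friction, temperature=temperature,
                   n_steps=n_therm, record_every=max(n_therm, 1),
                   remove_rotation=remove_rotation),
        rng=rng,
    )
    if therm.aborted:
        raise ForceUncertaintyAbort("aborted during thermalization", float("nan"))
    return run_md(
        calculator,
        therm.frames[-1],
        MDSettings(dt=dt, friction=friction, temperature=temperature,
                   n_steps=n_prod, record_every=1,
                   remove_rotation=remove_rotation),
        rng=rng,
    )
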
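"""IR spectra from MD dipole time series.

The absorption spectrum is proportional to the Fourier transform of the
autocorrelation function (ACF) of the dipole time derivative,

    I(ω) ∝ ∫ ⟨μ̇(τ)·μ̇(τ+t)⟩_τ e^{−iωt} dt.

The ACF is computed by FFT (Wiener–Khinchin) with the biased 1/N
normalization, truncated at a maximum correlation depth (default 1000 fs),
tapered with a Hann window and zero-padded before the final transform.
Intensities are in arbitrary units; no quantum correction factor is
applied to the classical ACF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import Spectrum, Trajectory
from .units import C_CM_FS


@dataclass
class DipoleSeries:
    """Per-frame dipole 3-vectors (Debye) at fixed sampling interval dt (fs)."""

    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3:
            raise ValueError("dipole series must have shape (n, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) * self.dt


def dipole_derivative(series: DipoleSeries) -> DipoleSeries:
    """Central-difference time derivative (Debye/fs); endpoints dropped, so
    the result has N − 2 frames."""
    if series.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    v = series.values
    return DipoleSeries((v[2:] - v[:-2]) / (2.0 * series.dt), series.dt)


def autocorrelation(
    signal, dt: Optional[float] = None, max_depth: float = 1000.0
) -> np.ndarray:
    """FFT-based (Wiener–Khinchin) biased ACF of a vector time series.

    ``signal`` is a DipoleSeries or an (N, d) array with sampling interval
    ``dt``.  Returns C(t_k) = (1/N) Σ_τ x(τ)·x(τ+t_k), components summed,
    for lags t_k = k·dt up to (but excluding) ``max_depth``.
    """
    if isinstance(signal, DipoleSeries):
        values, dt = signal.values, signal.dt
    else:
        values = np.asarray(signal, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        if dt is None:
            raise ValueError("dt is required for raw-array input")
    n = values.shape[0]
    n_lags = int(round(max_depth / dt))
    if n_lags < 1 or n_lags > n:
        raise ValueError(
            f"correlation depth {max_depth} fs needs {n_lags} lags but the "
            f"series has only {n} frames"
        )
    n_fft = 1
    while n_fft < 2 * n:
        n_fft *= 2
    acf = np.zeros(n_lags)
    for c in range(values.shape[1]):
        f = np.fft.rfft(values[:, c], n_fft)
        acf += np.fft.irfft(f * np.conj(f), n_fft)[:n_lags]
    return acf / n


def autocorrelation_direct(values: np.ndarray, n_lags: int) -> np.ndarray:
    """O(N²) lag-sum ACF — the independent cross-check for the FFT path."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    n = values.shape[0]
    out = np.zeros(n_lags)
    for k in range(n_lags):
        out[k] = (values[: n - k] * values[k:]).sum() / n
    return out


def spectrum_from_acf(
    acf: np.ndarray, dt: float, pad_to: Optional[int] = None
) -> Spectrum:
    """Hann-windowed, zero-padded Fourier transform of a one-sided ACF.

    The default ``pad_to`` is the next power of two ≥ 16× the ACF length —
    cosmetic grid refinement only.  The frequency axis is returned in cm⁻¹.
    """
    acf = np.asarray(acf, dtype=float)
    n = acf.size
    if pad_to is None:
        pad_to = 1
        while pad_to < 16 * n:
            pad_to *= 2
    if pad_to < n:
        raise ValueError("pad_to must be at least the ACF length")
    # half-Hann taper: 1 at lag 0 decaying to 0 at the correlation depth
    window = 0.5 * (1.0 + np.cos(np.pi * np.arange(n) / n))
    padded = np.zeros(pad_to)
    padded[:n] = acf * window
    intens = np.abs(np.fft.rfft(padded))
    freqs_fs = np.fft.rfftfreq(pad_to, d=dt)  # fs⁻¹
    return Spectrum(wavenumber_grid(freqs_fs), intens)


def wavenumber_grid(freqs_fs: np.ndarray) -> np.ndarray:
    """Frequency (fs⁻¹) → wavenumber (cm⁻¹)."""
    return np.asarray(freqs_fs) / C_CM_FS


def ir_spectrum(
    trajectory: Trajectory,
    max_depth: float = 1000.0,
    pad_to: Optional[int] = None,
) -> Spectrum:
    """Full pipeline on a production trajectory carrying per-frame dipoles:
    dipole derivative → Wiener–Khinchin ACF → windowed/padded transform."""
    if trajectory.dipoles is None:
        raise ValueError("trajectory carries no dipoles")
    series = DipoleSeries(trajectory.dipoles, trajectory.dt)
    dmu = dipole_derivative(series)
    acf = autocorrelation(dmu, max_depth=max_depth)
    return spectrum_from_acf(acf, dt=series.dt, pad_to=pad_to)


def average_spectra(spectra: Sequence[Spectrum]) -> Tuple[Spectrum, Spectrum]:
    """Pointwise mean and sample standard deviation over spectra that share
    one grid (regrid first otherwise)."""
    if len(spectra) < 2:
        raise ValueError("averaging needs at least 2 spectra")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.n_points != grid.size or not np.allclose(s.wavenumbers, grid):
            raise ValueError("spectra are on different grids; regrid first")
    stack = np.array([s.intensities for s in spectra])
    return (
        Spectrum(grid, stack.mean(axis=0)),
        Spectrum(grid, stack.std(axis=0, ddof=1)),
    )


def predict_ir(
    calculator,
    geometry,
    temperature: float = 300.0,
    n_trajectories: int = 3,
    seed: int = 0,
    thermalize_ps: float = 5.0,
    production_ps: float = 50.0,
    dt: float = 0.5,
    friction: float = 0.01,
    max_depth: float = 1000.0,
    remove_rotation: bool = False,
) -> Tuple[Spectrum, Spectrum, List[Spectrum]]:
    """Production IR prediction: independent Langevin trajectories with
    seeds ``seed + {0, 1, …}``, one spectrum each, averaged with a
    standard-deviation band (default: three trajectories).

    The calculator must provide dipoles (an oracle, or a committee
    calculator with a dipole model).  ``remove_rotation`` projects rigid
    rotation out of the dynamics — the convention for clean vibrational
    lines on light molecules, whose free rotation otherwise superimposes
    broad low-frequency wings.
    """
    from .dynamics import production_run

    spectra = []
    for t in range(n_trajectories):
        traj = production_run(
            calculator,
            geometry,
            temperature=temperature,
            thermalize_ps=thermalize_ps,
            production_ps=production_ps,
            dt=dt,
            friction=friction,
            seed=seed + t,
            remove_rotation=remove_rotation,
        )
        spectra.append(ir_spectrum(traj, max_depth=max_depth))
    mean, std = average_spectra(spectra)
    return mean, std, spectra
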
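"""Spectral preprocessing and similarity metrics.

Two spectra are compared after mapping them onto a common wavenumber grid
by linear interpolation, optionally after asymmetric-least-squares (ALS)
baseline correction of the experimental input.  Similarity is quantified by

* Pearson's correlation coefficient (PCC) on the raw regridded intensities
  (the statistic is scale invariant, so no normalization is applied), and
* the 1-D Wasserstein (optimal transport) distance between the spectra
  treated as unit-mass distributions over the wavenumber axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.stats import wasserstein_distance

from .core import Spectrum


@dataclass
class SimilarityReport:
    """PCC (dimensionless, in [−1, 1]), Wasserstein distance (cm⁻¹) and
    the common grid both metrics were evaluated on."""

    pcc: float
    wd: float
    grid: np.ndarray

    def to_dict(self) -> dict:
        return {"pcc": self.pcc, "wd": self.wd,
                "grid_min": float(self.grid[0]), "grid_max": float(self.grid[-1]),
                "grid_points": int(self.grid.size)}


def baseline_correct(
    spectrum: Spectrum,
    lam: float = 1e5,
    p: float = 0.01,
    n_iter: int = 10,
) -> Spectrum:
    """Asymmetric-least-squares baseline removal.

    Iteratively reweighted smoothing: the baseline z minimizes
    Σ w_i (y_i − z_i)² + λ Σ (Δ²z)², with asymmetry weights w_i = p where
    y > z and 1 − p elsewhere, so peaks barely pull the baseline up.  The
    baseline is subtracted and negative residuals are clipped at zero.
    Defaults λ = 1e5, p = 0.01.
    """
    y = spectrum.intensities
    n = y.size
    if n < 10:
        raise ValueError("baseline correction needs at least 10 points")
    d = sparse.diags([1.0, -2.0, 1.0], [0, -1, -2], shape=(n, n - 2))
    dtd = lam * (d @ d.T)
    w = np.ones(n)
    z = y.copy()
    for _ in range(n_iter):
        W = sparse.diags(w)
        z = spsolve((W + dtd).tocsc(), w * y)
        w = np.where(y > z, p, 1.0 - p)
    corrected = np.clip(y - z, 0.0, None)
    return Spectrum(spectrum.wavenumbers, corrected)


def regrid(spectrum: Spectrum, target: np.ndarray) -> Spectrum:
    """Linear interpolation onto ``target``; points outside the source
    support become 0 with a warning."""
    target = np.asarray(target, dtype=float)
    lo, hi = spectrum.wavenumbers[0], spectrum.wavenumbers[-1]
    if target[-1] < lo or target[0] > hi:
        raise ValueError("target grid does not overlap the spectrum support")
    outside = (target < lo) | (target > hi)
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} target points outside the spectrum "
            "support were set to 0", stacklevel=2,
        )
    vals = np.interp(target, spectrum.wavenumbers, spectrum.intensities,
                     left=0.0, right=0.0)
    return Spectrum(target, vals)


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson's correlation coefficient between two intensity vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("inputs must be equal-length vectors of >= 2 points")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum()) * np.sqrt((yc**2).sum())
    if denom == 0:
        raise ValueError("PCC undefined for constant input")
    return float((xc * yc).sum() / denom)


def wasserstein(
    x_grid: np.ndarray, x_int: np.ndarray, y_grid: np.ndarray, y_int: np.ndarray
) -> float:
    """1-D optimal-transport distance (cm⁻¹) between the two spectra
    normalized to unit mass over the wavenumber axis."""
    x_int = np.asarray(x_int, dtype=float)
    y_int = np.asarray(y_int, dtype=float)
    if np.any(x_int < 0) or np.any(y_int < 0):
        raise ValueError("intensities must be non-negative")
    if x_int.sum() <= 0 or y_int.sum() <= 0:
        raise ValueError("spectrum has zero total mass")
    return float(wasserstein_distance(x_grid, y_grid, x_int, y_int))


def compare_spectra(
    a: Spectrum,
    b: Spectrum,
    do_baseline: bool = False,
    baseline_on: str = "b",
    lam: float = 1e5,
    p: float = 0.01,
) -> SimilarityReport:
    """Compare spectrum ``a`` against reference ``b`` on ``b``'s grid.

    ``do_baseline`` applies ALS baseline correction to the input designated
    experimental (``baseline_on``: 'a', 'b' or 'both') before regridding.
    """
    if do_baseline:
        if baseline_on in ("a", "both"):
            a = baseline_correct(a, lam=lam, p=p)
        if baseline_on in ("b", "both"):
            b = baseline_correct(b, lam=lam, p=p)
    a_on_b = regrid(a, b.wavenumbers)
    return SimilarityReport(
        pcc=pcc(a_on_b.intensities, b.intensities),
        wd=wasserstein(a_on_b.wavenumbers, a_on_b.intensities,
                       b.wavenumbers, b.intensities),
        grid=b.wavenumbers,
    )
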
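"""Spectral conditioning: cropping, baseline, normalization, smoothing.

ATR-FTIR absorbance traces carry a broad baseline (crystal contact,
scattering) and a multiplicative pathlength factor that varies with contact
pressure. Before peak heights, similarity scores or PCA mean anything, each
trace is cropped to an analysis window, baseline-corrected with asymmetric
least squares (ALS) and normalized (standard normal variate, SNV, by
default).

Named analysis windows (cm^-1):

========== ============ ===========================================
preset     window       use
========== ============ ===========================================
full       400-4000     family-level standard comparison
mid_ir     500-4000     general mid-IR inspection
carrageenan 800-1240    carrageenan diagnostic band table
pca_red    580-1350     seasonal PCA of red-algal galactans
pca_brown  500-1600     seasonal PCA of brown-algal colloids
========== ============ ===========================================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from scipy.signal import savgol_filter

from .errors import ContractError, DegenerateInputError, RangeError
from .spectra_io import Spectrum

WINDOW_PRESETS: dict[str, tuple[float, float]] = {
    "full": (400.0, 4000.0),
    "mid_ir": (500.0, 4000.0),
    "carrageenan": (800.0, 1240.0),
    "pca_red": (580.0, 1350.0),
    "pca_brown": (500.0, 1600.0),
}


def resolve_window(window: str | tuple[float, float]) -> tuple[float, float]:
    """Accept a preset name or a (lo, hi) pair."""
    if isinstance(window, str):
        try:
            return WINDOW_PRESETS[window]
        except KeyError:
            raise RangeError(f"unknown window preset {window!r}; "
                             f"known: {sorted(WINDOW_PRESETS)}") from None
    lo, hi = float(window[0]), float(window[1])
    if not lo < hi:
        raise RangeError(f"window lo must be < hi, got ({lo}, {hi})")
    return lo, hi


@dataclass(frozen=True)
class PreprocessConfig:
    """Conditioning recipe applied identically to every spectrum in a run.

    Defaults: ALS baseline (lambda=1e5, p=0.01, 10 iterations), SNV
    normalization over the window, Savitzky-Golay 21 points / polyorder 3
    (about 10 cm^-1 at the canonical grid) where smoothing is requested.
    """

    window: tuple[float, float] | str | None = None
    baseline_method: Literal["als", "none"] = "als"
    als_lambda: float = 1e5
    als_p: float = 0.01
    als_niter: int = 10
    normalization: Literal["snv", "max_in_window", "none"] = "snv"
    sg_window_points: int = 21
    sg_polyorder: int = 3

    def __post_init__(self) -> None:
        if self.window is not None:
            resolve_window(self.window)
        if not 0 < self.als_p < 1:
            raise ContractError(f"als_p must lie in (0,1), got {self.als_p}")
        if self.als_lambda <= 0:
            raise ContractError("als_lambda must be positive")
        if self.sg_window_points < 5 or self.sg_window_points % 2 == 0:
            raise ContractError("sg_window_points must be an odd integer >= 5")
        if not 2 <= self.sg_polyorder < self.sg_window_points:
            raise ContractError("need 2 <= sg_polyorder < sg_window_points")


def crop(spectrum: Spectrum, window: str | tuple[float, float]) -> Spectrum:
    """Keep exactly the points with lo <= wavenumber <= hi (closed interval)."""
    lo, hi = resolve_window(window)
    mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
    if mask.sum() < 2:
        raise RangeError(
            f"window [{lo}, {hi}] retains fewer than 2 points of span {spectrum.span}")
    return Spectrum(spectrum.wavenumbers[mask], spectrum.absorbance[mask], spectrum.meta)


def als_baseline(y: np.ndarray, lam: float = 1e5, p: float = 0.01,
                 niter: int = 10) -> np.ndarray:
    """Asymmetric least squares baseline (Eilers & Boelens).

    Minimizes ``sum w_i (y_i - z_i)^2 + lam * sum (Delta^2 z)^2`` with
    asymmetric weights w_i = p where y > z (peaks) and 1-p elsewhere,
    iterated to a fixed point.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    DtD = lam * (D.T @ D)
    w = np.ones(n)
    z = y.copy()
    for _ in range(max(1, niter)):
        W = sparse.diags(w)
        z = spsolve((W + DtD).tocsc(), w * y)
        if not np.all(np.isfinite(z)):
            raise ArithmeticError(f"ALS baseline did not converge within {niter} iterations")
        w = np.where(y > z, p, 1.0 - p)
    return z


def baseline_correct(spectrum: Spectrum, method: Literal["als", "none"] = "als",
                     lam: float = 1e5, p: float = 0.01, niter: int = 10) -> Spectrum:
    """Subtract the estimated baseline from the trace."""
    if method == "none":
        return spectrum
    if method != "als":
        raise ContractError(f"unknown baseline method {method!r}")
    z = als_baseline(spectrum.absorbance, lam=lam, p=p, niter=niter)
    return spectrum.with_absorbance(spectrum.absorbance - z)


def normalize(spectrum: Spectrum,
              method: Literal["snv", "max_in_window", "none"] = "snv",
              window: str | tuple[float, float] | None = None) -> Spectrum:
    """SNV (mean 0, sd 1 over the window) or max-in-window (apex -> 1)."""
    if method == "none":
        return spectrum
    if window is None:
        mask = np.ones(len(spectrum), dtype=bool)
    else:
        lo, hi = resolve_window(window)
        mask = (spectrum.wavenumbers >= lo) & (spectrum.wavenumbers <= hi)
        if mask.sum() < 2:
            raise RangeError(f"normalization window [{lo}, {hi}] is empty")
    y = spectrum.absorbance
    if method == "snv":
        mu = y[mask].mean()
        sd = y[mask].std()
        if sd < 1e-15:
            raise DegenerateInputError("SNV undefined for a constant spectrum")
        return spectrum.with_absorbance((y - mu) / sd)
    if method == "max_in_window":
        peak = y[mask].max()
        if abs(peak) < 1e-15:
            raise DegenerateInputError("max_in_window undefined when the window maximum is 0")
        return spectrum.with_absorbance(y / peak)
    raise ContractError(f"unknown normalization method {method!r}")


def savgol_derivative(spectrum: Spectrum, order: int = 0,
                      window_points: int = 21, polyorder: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing (order 0) or 1st/2nd derivative per cm^-1.

    Requires a uniform grid; resample first if the grid is irregular.
    """
    if order not in (0, 1, 2):
        raise ContractError(f"derivative order must be 0, 1 or 2, got {order}")
    if not spectrum.is_uniform():
        raise ContractError("savgol_derivative requires a uniform grid; "
                            "use resample_to_grid first")
    if window_points > len(spectrum):
        raise ContractError("sg window longer than the spectrum")
    y = savgol_filter(spectrum.absorbance, window_points, polyorder,
                      deriv=order, delta=spectrum.grid_step())
    return spectrum.with_absorbance(y)


def condition(spectrum: Spectrum, config: PreprocessConfig) -> Spectrum:
    """Apply the full recipe: crop -> baseline -> normalize."""
    s = spectrum
    if config.window is not None:
        s = crop(s, config.window)
    s = baseline_correct(s, config.baseline_method, lam=config.als_lambda,
                         p=config.als_p, niter=config.als_niter)
    win = config.window if config.normalization == "max_in_window" else None
    s = normalize(s, config.normalization, window=win)
    return s
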
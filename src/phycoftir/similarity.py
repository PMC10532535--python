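"""Similarity scoring of a sample spectrum against a reference standard.

Commercial instrument software reports a proprietary "match" percentage
between an extract and a purified commercial standard. The open analog
implemented here is the Pearson correlation of the two traces after
identical conditioning (common grid, baseline correction, SNV), clipped at
zero and expressed as a percentage. It is documented as an analog of the
vendor metric, not a replica.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, RangeError
from .preprocess import PreprocessConfig, baseline_correct, crop, normalize, resolve_window
from .spectra_io import Spectrum, SpectrumSet, resample_to_grid

DEFAULT_WINDOW = (400.0, 4000.0)


@dataclass(frozen=True)
class SimilarityResult:
    percent: float
    window: tuple[float, float]
    n_points: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError("percent must lie in [0, 100]")
        if self.n_points < 3:
            raise ValueError("similarity needs at least 3 common points")


def _conditioned_on(spectrum: Spectrum, grid: np.ndarray,
                    preprocess: PreprocessConfig) -> np.ndarray:
    s = resample_to_grid(spectrum, grid)
    # a flat trace carries no band information; catch it before the baseline
    # step reduces it to numerical dust that SNV would amplify into noise
    if s.absorbance.std() < 1e-10 * (1.0 + abs(float(s.absorbance.mean()))):
        raise DegenerateInputError(
            f"spectrum {spectrum.meta.sample_id!r} is constant over the window")
    s = baseline_correct(s, preprocess.baseline_method, lam=preprocess.als_lambda,
                         p=preprocess.als_p, niter=preprocess.als_niter)
    method = preprocess.normalization if preprocess.normalization != "none" else "snv"
    s = normalize(s, method)  # SNV over the whole (already windowed) grid
    return s.absorbance


def similarity_percent(sample: Spectrum, standard: Spectrum,
                       window: str | tuple[float, float] = DEFAULT_WINDOW,
                       preprocess: PreprocessConfig | None = None) -> SimilarityResult:
    """Clipped-Pearson similarity (0-100) on identically conditioned traces.

    The common grid is the sample's grid restricted to the overlap of
    *window* and both spectra's spans; the standard is resampled onto it.
    """
    preprocess = preprocess or PreprocessConfig()
    lo, hi = resolve_window(window)
    lo = max(lo, sample.span[0], standard.span[0])
    hi = min(hi, sample.span[1], standard.span[1])
    if lo >= hi:
        raise RangeError("window does not overlap both spectra")
    grid = crop(sample, (lo, hi)).wavenumbers
    if grid.size < 3:
        raise RangeError("fewer than 3 common points in the window")
    a = _conditioned_on(sample, grid, preprocess)
    b = _conditioned_on(standard, grid, preprocess)
    if a.std() < 1e-15 or b.std() < 1e-15:
        raise DegenerateInputError("constant trace after preprocessing")
    r = float(np.corrcoef(a, b)[0, 1])
    return SimilarityResult(percent=100.0 * max(0.0, r),
                            window=(float(lo), float(hi)), n_points=int(grid.size))


def similarity_batch(samples: SpectrumSet, standard: Spectrum,
                     window: str | tuple[float, float] = DEFAULT_WINDOW,
                     preprocess: PreprocessConfig | None = None) -> pd.DataFrame:
    """Score every member of *samples* against *standard*.

    Returns one row per sample ordered by sample_id, with columns
    sample_id, month, year, percent, window_lo, window_hi, n_points.
    Per-sample failures are re-raised with the sample_id attached.
    """
    rows = []
    for s in sorted(samples, key=lambda s: s.meta.sample_id):
        try:
            res = similarity_percent(s, standard, window, preprocess)
        except Exception as exc:
            raise type(exc)(f"sample {s.meta.sample_id!r}: {exc}") from exc
        rows.append({
            "sample_id": s.meta.sample_id,
            "month": s.meta.month,
            "year": s.meta.year,
            "percent": res.percent,
            "window_lo": res.window[0],
            "window_hi": res.window[1],
            "n_points": res.n_points,
        })
    return pd.DataFrame(rows, columns=["sample_id", "month", "year", "percent",
                                       "window_lo", "window_hi", "n_points"])
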
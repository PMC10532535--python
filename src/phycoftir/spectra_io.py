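"""Spectrum containers and file I/O.

A :class:`Spectrum` is one absorbance trace on a strictly ascending
wavenumber grid, plus sample metadata. Supported on-disk formats are
two-column CSV, a minimal JCAMP-DX subset (``##XYPOINTS`` and uncompressed
AFFN ``##XYDATA``), and a wide-matrix CSV for collections (first column
wavenumber, one column per sample).

Instrument convention: mid-IR ATR spectrometers export on a uniform grid;
the canonical acquisition grid used throughout the package is 0.482 cm^-1
over 400-4000 cm^-1. The library itself accepts any strictly increasing
grid.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, RangeError, SpectrumValidationError

#: Canonical ATR acquisition grid spacing in cm^-1.
CANONICAL_STEP = 0.482
#: Canonical acquisition span in cm^-1.
CANONICAL_SPAN = (400.0, 4000.0)

_WAVENUMBER_BOUNDS = (100.0, 8000.0)

#: Filename metadata pattern: ``<species>_<YYYY>-<MM>_rep<k>``.
_FILENAME_META = re.compile(
    r"^(?P<species>[A-Za-z][A-Za-z0-9.\-]*)_(?P<year>\d{4})-(?P<month>\d{2})_rep(?P<rep>\d+)$"
)

SpectrumFormat = Literal["jcampdx", "csv2col"]


def canonical_grid(lo: float = CANONICAL_SPAN[0], hi: float = CANONICAL_SPAN[1],
                   step: float = CANONICAL_STEP) -> np.ndarray:
    """Uniform wavenumber grid from *lo* towards *hi* at *step* spacing."""
    n = int(np.floor((hi - lo) / step)) + 1
    return lo + step * np.arange(n)


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one measured sample.

    ``role`` separates field samples from commercial reference standards;
    samples are coded by month and year of harvest, recorded in replicates.
    """

    sample_id: str = ""
    species: str | None = None
    month: int | None = None
    year: int | None = None
    replicate: int = 1
    role: Literal["sample", "standard"] = "sample"

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise SpectrumValidationError(f"replicate must be >= 1, got {self.replicate}")
        if self.role not in ("sample", "standard"):
            raise SpectrumValidationError(f"role must be 'sample' or 'standard', got {self.role!r}")
        if self.month is not None and not 1 <= self.month <= 12:
            raise SpectrumValidationError(f"month must be in 1..12, got {self.month}")


def meta_from_filename(stem: str) -> SampleMeta:
    """Parse ``<species>_<YYYY>-<MM>_rep<k>`` file stems; fall back to bare id."""
    m = _FILENAME_META.match(stem)
    if m is None:
        return SampleMeta(sample_id=stem)
    return SampleMeta(
        sample_id=stem,
        species=m.group("species"),
        year=int(m.group("year")),
        month=int(m.group("month")),
        replicate=int(m.group("rep")),
    )


@dataclass(frozen=True)
class Spectrum:
    """One absorbance trace on a strictly ascending wavenumber grid."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if w.ndim != 1 or a.ndim != 1 or w.size != a.size:
            raise SpectrumValidationError("wavenumbers and absorbance must be 1-D and equal length")
        if w.size < 2:
            raise SpectrumValidationError("a spectrum needs at least 2 points")
        if not (np.all(np.isfinite(w)) and np.all(np.isfinite(a))):
            raise SpectrumValidationError("spectrum contains NaN or infinite values")
        if np.any(np.diff(w) <= 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        lo, hi = _WAVENUMBER_BOUNDS
        if w[0] < lo or w[-1] > hi:
            raise SpectrumValidationError(
                f"wavenumbers outside sanity bounds [{lo}, {hi}] cm^-1")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "absorbance", a)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    def grid_step(self) -> float:
        """Mean grid spacing; use :meth:`is_uniform` to check uniformity."""
        return float(np.mean(np.diff(self.wavenumbers)))

    def is_uniform(self, atol: float = 1e-6) -> bool:
        d = np.diff(self.wavenumbers)
        return bool(np.all(np.abs(d - d.mean()) <= atol))

    def with_absorbance(self, absorbance: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers.copy(), np.asarray(absorbance, dtype=float),
                        self.meta)

    def with_meta(self, **kwargs) -> "Spectrum":
        return Spectrum(self.wavenumbers, self.absorbance, replace(self.meta, **kwargs))


def _ascending(w: np.ndarray, a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reverse descending input; reject unordered/duplicated grids."""
    if w.size >= 2 and w[0] > w[-1]:
        w, a = w[::-1].copy(), a[::-1].copy()
    if np.any(np.diff(w) <= 0):
        raise SpectrumValidationError(
            "wavenumbers are not strictly monotonic (duplicates or unordered rows)")
    return w, a


# ---------------------------------------------------------------------------
# two-column CSV


def _read_csv2col(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected two comma-separated columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # single header line auto-detected
                    continue
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value in data row: {line!r}") from None
    if len(rows) < 2:
        raise FormatError(f"{path}: fewer than 2 data rows")
    arr = np.asarray(rows, dtype=float)
    return arr[:, 0], arr[:, 1]


def _write_csv2col(spectrum: Spectrum, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("wavenumber_cm-1,absorbance\n")
        for w, a in zip(spectrum.wavenumbers, spectrum.absorbance):
            fh.write(f"{w:.12g},{a:.12g}\n")


# ---------------------------------------------------------------------------
# minimal JCAMP-DX (XYPOINTS / AFFN XYDATA)

_NUM = r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?"
_NUM_RE = re.compile(_NUM)


def _read_jcampdx(path: Path) -> tuple[np.ndarray, np.ndarray, dict[str, str]]:
    labels: dict[str, str] = {}
    mode: str | None = None
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("$$")[0].rstrip()
            if not line:
                continue
            if line.startswith("##"):
                try:
                    label, value = line[2:].split("=", 1)
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: malformed label line {line!r}")
                label = label.strip().upper().replace(" ", "")
                value = value.strip()
                labels[label] = value
                if label == "XYPOINTS":
                    mode = "xypoints"
                elif label == "XYDATA":
                    if "++" not in value:
                        raise FormatError(
                            f"{path}:{lineno}: unsupported XYDATA variant {value!r}")
                    mode = "xydata"
                elif label == "END":
                    mode = None
            elif mode is not None:
                data_lines.append(line)

    if "XYPOINTS" in labels:
        pairs = _NUM_RE.findall(" ".join(data_lines))
        if len(pairs) < 4 or len(pairs) % 2:
            raise FormatError(f"{path}: XYPOINTS block has an odd or short number list")
        arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
        return arr[:, 0], arr[:, 1], labels

    if "XYDATA" in labels:
        # AFFN (X++(Y..Y)): each line starts with an X value followed by Y values.
        if any(re.search(r"[A-DF-Zа-я%@]", ln) for ln in data_lines):
            raise FormatError(
                f"{path}: compressed JCAMP-DX data (SQZ/DIF/DUP) is not supported")
        xfactor = float(labels.get("XFACTOR", "1"))
        yfactor = float(labels.get("YFACTOR", "1"))
        xs: list[float] = []
        ys: list[float] = []
        line_first_x: list[float] = []
        for ln in data_lines:
            nums = [float(t) for t in _NUM_RE.findall(ln)]
            if len(nums) < 2:
                raise FormatError(f"{path}: XYDATA line with fewer than 2 numbers: {ln!r}")
            line_first_x.append(nums[0] * xfactor)
            ys.extend(nums[1:])
        # reconstruct per-point x from FIRSTX/LASTX/NPOINTS when available
        try:
            firstx = float(labels["FIRSTX"])
            lastx = float(labels["LASTX"])
            npoints = int(labels["NPOINTS"])
        except KeyError:
            raise FormatError(f"{path}: XYDATA requires FIRSTX, LASTX and NPOINTS")
        if npoints != len(ys):
            raise FormatError(
                f"{path}: NPOINTS={npoints} but {len(ys)} ordinates found")
        xs = list(np.linspace(firstx, lastx, npoints))
        return np.asarray(xs), np.asarray(ys) * yfactor, labels

    raise FormatError(f"{path}: no XYDATA or XYPOINTS block found")


def _write_jcampdx(spectrum: Spectrum, path: Path) -> None:
    w, a = spectrum.wavenumbers, spectrum.absorbance
    with open(path, "w") as fh:
        fh.write(f"##TITLE={spectrum.meta.sample_id or path.stem}\n")
        fh.write("##JCAMP-DX=4.24\n")
        fh.write("##DATA TYPE=INFRARED SPECTRUM\n")
        fh.write("##XUNITS=1/CM\n")
        fh.write("##YUNITS=ABSORBANCE\n")
        fh.write(f"##FIRSTX={w[0]:.12g}\n")
        fh.write(f"##LASTX={w[-1]:.12g}\n")
        fh.write(f"##NPOINTS={len(w)}\n")
        fh.write("##XYPOINTS=(XY..XY)\n")
        for x, y in zip(w, a):
            fh.write(f"{x:.12g}, {y:.12g}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# public API


def read_spectrum(path: str | Path, format: SpectrumFormat | None = None,
                  meta: SampleMeta | None = None) -> Spectrum:
    """Read one spectrum from *path*.

    ``format`` defaults by extension (``.jdx``/``.dx`` -> jcampdx, else
    csv2col). Descending files are returned ascending with the absorbance
    co-reversed. Metadata comes from the filename pattern
    ``<species>_<YYYY>-<MM>_rep<k>`` (or JCAMP ``##TITLE``) unless *meta* is
    given explicitly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jcampdx" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv2col"
    if format == "csv2col":
        w, a = _read_csv2col(path)
        labels: dict[str, str] = {}
    elif format == "jcampdx":
        w, a, labels = _read_jcampdx(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    w, a = _ascending(w, a)
    if meta is None:
        meta = meta_from_filename(path.stem)
        title = labels.get("TITLE")
        if title and meta.species is None:
            parsed = meta_from_filename(title)
            meta = parsed if parsed.species is not None else replace(meta, sample_id=meta.sample_id or title)
    return Spectrum(w, a, meta)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   format: SpectrumFormat | None = None) -> None:
    """Write *spectrum* to *path* as csv2col or jcampdx (round-trip safe to 1e-9)."""
    path = Path(path)
    if format is None:
        format = "jcampdx" if path.suffix.lower() in (".jdx", ".dx", ".jcm") else "csv2col"
    if format == "csv2col":
        _write_csv2col(spectrum, path)
    elif format == "jcampdx":
        _write_jcampdx(spectrum, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def resample_to_grid(spectrum: Spectrum, grid: Sequence[float] | np.ndarray) -> Spectrum:
    """Linear interpolation of *spectrum* onto *grid* (no extrapolation).

    Values at grid nodes shared with the source grid are unchanged.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise RangeError("target grid must be 1-D, length >= 2 and strictly increasing")
    lo, hi = spectrum.span
    if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
        raise RangeError(
            f"target grid [{grid[0]}, {grid[-1]}] exceeds spectrum span [{lo}, {hi}]")
    a = np.interp(grid, spectrum.wavenumbers, spectrum.absorbance)
    return Spectrum(grid, a, spectrum.meta)


@dataclass
class SpectrumSet:
    """An ordered collection of spectra, optionally on one common grid."""

    spectra: list[Spectrum]
    common_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.common_grid is not None:
            g = np.asarray(self.common_grid, dtype=float)
            for s in self.spectra:
                if len(s) != g.size or not np.allclose(s.wavenumbers, g, atol=1e-9):
                    raise SpectrumValidationError(
                        f"spectrum {s.meta.sample_id!r} is not on the declared common grid")
            self.common_grid = g

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def sample_ids(self) -> list[str]:
        return [s.meta.sample_id for s in self.spectra]

    def to_matrix(self) -> np.ndarray:
        """samples x wavenumbers matrix; requires a common grid."""
        if self.common_grid is None:
            raise SpectrumValidationError("SpectrumSet has no common grid; resample first")
        return np.vstack([s.absorbance for s in self.spectra])

    def on_common_grid(self, grid: np.ndarray | None = None) -> "SpectrumSet":
        """Resample every member onto *grid* (default: the first member's grid)."""
        if grid is None:
            grid = self.spectra[0].wavenumbers
        grid = np.asarray(grid, dtype=float)
        return SpectrumSet([resample_to_grid(s, grid) for s in self.spectra], grid)


def read_spectrum_set(path: str | Path) -> SpectrumSet:
    """Read a wide-matrix CSV: first column wavenumber, one column per sample."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: wide-matrix CSV needs >= 2 columns")
    w = df.iloc[:, 0].to_numpy(dtype=float)
    order = np.argsort(w)
    w = w[order]
    spectra = []
    for col in df.columns[1:]:
        a = df[col].to_numpy(dtype=float)[order]
        spectra.append(Spectrum(w, a, meta_from_filename(str(col))))
    return SpectrumSet(spectra, w)


def write_spectrum_set(sset: SpectrumSet, path: str | Path) -> None:
    """Write a SpectrumSet (must share a grid) as a wide-matrix CSV."""
    if sset.common_grid is None:
        sset = sset.on_common_grid()
    df = pd.DataFrame({"wavenumber_cm-1": sset.common_grid})
    for s in sset:
        df[s.meta.sample_id] = s.absorbance
    df.to_csv(path, index=False, float_format="%.10g")
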
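"""Peak/shoulder detection, diagnostic band assignment and classification.

The central object is the *band library*: a versioned table of diagnostic
mid-IR bands, each with a code (structural-unit notation: G4S, DA, DA2S,
G/D6S, ...), a search window in cm^-1, the colloid types it indicates, and
whether it usually appears as a shoulder on a stronger band.

``detect_peaks`` finds apex peaks (prominence-filtered local maxima with
parabolic sub-grid refinement) and shoulders (second-derivative minima that
do not coincide with an apex). ``match_bands`` turns a peak list into an
assignment report in the convention of published carrageenan band tables:
a numeric matched position, "+" for a weak-but-present band, or "-" for an
absent band. ``classify_carrageenan`` reduces a report to a dominant type.

Carrageenan typing logic
------------------------
kappa-carrageenan (G4S-DA) and iota-carrageenan (G4S-DA2S) share the
anhydro-bridge bands near 930 (DA) and 1070 (DA*) cm^-1; iota additionally
carries a 2-sulfate on the anhydrogalactose, giving exclusive bands near
805 (DA2S) and 905 (DA2S*) cm^-1. The biosynthetic precursor nu keeps a C6
sulfate instead of the bridge, with bands at 825-830 (G/D2S), 815-820
(G/D6S) and a shouldered 867 cm^-1 (G/D6S*) feature. kappa therefore has no
exclusive band of its own: it is recognized by the bridge bands *without*
any 2-sulfate evidence. The 867-874 cm^-1 feature also appears on kappa and
iota standards (any sulfate can contribute there), so it counts toward nu
at half weight only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .errors import ContractError, FormatError, RangeError
from .spectra_io import SampleMeta, Spectrum

CARRAGEENAN_TYPES = frozenset({"iota", "kappa", "nu", "lambda"})
COLLOID_FAMILIES = ("carrageenan", "fucoidan", "alginate")


# ---------------------------------------------------------------------------
# library


@dataclass(frozen=True)
class BandReference:
    """One diagnostic band of a library."""

    code: str
    center: float
    window: tuple[float, float]
    indicated_types: frozenset[str]
    shoulder_expected: bool = False
    specificity: Literal["specific", "shared"] = "shared"
    weight: float = 1.0
    vibration: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.window
        if not lo <= self.center <= hi:
            raise ContractError(f"band {self.code}: center {self.center} outside "
                                f"window {self.window}")
        if not self.indicated_types:
            raise ContractError(f"band {self.code}: indicated_types must be nonempty")

    def contains(self, position: float) -> bool:
        return self.window[0] <= position <= self.window[1]


@dataclass(frozen=True)
class BandLibrary:
    """A named, versioned collection of diagnostic bands (order preserved)."""

    name: str
    version: str
    entries: tuple[BandReference, ...]

    def __post_init__(self) -> None:
        codes = [b.code for b in self.entries]
        if len(set(codes)) != len(codes):
            raise ContractError(f"library {self.name}: duplicate band codes")
        windows: dict[tuple[float, float], str] = {}
        for b in self.entries:
            if b.window in windows:
                raise ContractError(
                    f"library {self.name}: bands {windows[b.window]!r} and {b.code!r} "
                    "declare identical windows")
            windows[b.window] = b.code

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def codes(self) -> list[str]:
        return [b.code for b in self.entries]

    def get(self, code: str) -> BandReference:
        for b in self.entries:
            if b.code == code:
                return b
        raise KeyError(code)

    @property
    def types(self) -> frozenset[str]:
        out: set[str] = set()
        for b in self.entries:
            out |= b.indicated_types
        return frozenset(out)


def _parse_bool(s: str) -> bool:
    return s.strip().lower() in ("true", "1", "yes")


def load_band_library(path: str | Path) -> BandLibrary:
    """Load a band library from its plain-text CSV form.

    Comment lines starting with '#' may carry ``# library:`` and
    ``# version:`` headers.
    """
    path = Path(path)
    name, version = path.stem, "0"
    rows: list[dict[str, str]] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("library:"):
                    name = body.split(":", 1)[1].strip()
                elif body.lower().startswith("version:"):
                    version = body.split(":", 1)[1].strip()
                continue
            fields = next(csv.reader([line]))
            if header is None:
                header = [f.strip() for f in fields]
                continue
            rows.append(dict(zip(header, fields)))
    if header is None or not rows:
        raise FormatError(f"{path}: no band rows found")
    entries = []
    try:
        for r in rows:
            entries.append(BandReference(
                code=r["code"].strip(),
                center=float(r["center"]),
                window=(float(r["window_lo"]), float(r["window_hi"])),
                indicated_types=frozenset(t.strip() for t in r["types"].split("|")),
                shoulder_expected=_parse_bool(r["shoulder_expected"]),
                specificity=r["specificity"].strip(),  # type: ignore[arg-type]
                weight=float(r.get("weight", "1") or 1.0),
                vibration=r.get("vibration", "").strip(),
            ))
    except (KeyError, ValueError) as exc:
        raise FormatError(f"{path}: malformed band row: {exc}") from exc
    return BandLibrary(name=name, version=version, entries=tuple(entries))


def builtin_library(name: Literal["carrageenan", "fucoidan", "alginate"]) -> BandLibrary:
    """Load one of the shipped libraries."""
    if name not in COLLOID_FAMILIES:
        raise ContractError(f"no builtin library {name!r}; known: {COLLOID_FAMILIES}")
    ref = resources.files("phycoftir.data") / f"{name}_v1.csv"
    with resources.as_file(ref) as p:
        return load_band_library(p)


# ---------------------------------------------------------------------------
# peak detection


@dataclass(frozen=True)
class Peak:
    """A detected apex or shoulder."""

    position: float
    height: float
    prominence: float
    is_shoulder: bool = False

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ContractError("peak height must be >= 0 (baseline-correct first)")
        if not self.is_shoulder and self.prominence > self.height + 1e-12:
            raise ContractError("prominence cannot exceed height for an apex peak")


@dataclass(frozen=True)
class PeakList:
    peaks: tuple[Peak, ...]
    source_window: tuple[float, float]

    def __post_init__(self) -> None:
        pos = [p.position for p in self.peaks]
        if sorted(pos) != pos:
            raise ContractError("peaks must be sorted by position")
        lo, hi = self.source_window
        if pos and (pos[0] < lo or pos[-1] > hi):
            raise ContractError("peak positions must lie inside source_window")

    def __iter__(self):
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])

    def apexes(self) -> list[Peak]:
        return [p for p in self.peaks if not p.is_shoulder]

    def shoulders(self) -> list[Peak]:
        return [p for p in self.peaks if p.is_shoulder]


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int) -> tuple[float, float]:
    """3-point parabola through (i-1, i, i+1); returns (position, height)."""
    if i == 0 or i == len(y) - 1:
        return float(x[i]), float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if abs(denom) < 1e-300:
        return float(x[i]), float(y[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    step = x[i + 1] - x[i]
    pos = float(x[i] + delta * step)
    height = float(y1 - 0.25 * (y0 - y2) * delta)
    return pos, height


def detect_peaks(spectrum: Spectrum, min_prominence_frac: float = 0.02,
                 shoulder_threshold: float = 0.10,
                 sg_window_points: int = 21, sg_polyorder: int = 3) -> PeakList:
    """Find apex peaks and shoulders in a baseline-corrected, cropped trace.

    Apexes: local maxima of the Savitzky-Golay-smoothed trace with
    prominence >= ``min_prominence_frac`` x (max - min of the window),
    positions refined by 3-point parabolic interpolation.

    Shoulders: minima of the SG second derivative, at least 2 grid steps
    from any apex, with |d2| >= ``shoulder_threshold`` x max |d2| in the
    window.
    """
    if not spectrum.is_uniform():
        raise ContractError("detect_peaks requires a uniform grid; resample first")
    if len(spectrum) < sg_window_points:
        raise RangeError("window too short for peak detection")
    x = spectrum.wavenumbers
    step = spectrum.grid_step()
    y = savgol_filter(spectrum.absorbance, sg_window_points, sg_polyorder)
    span = float(y.max() - y.min())
    if span <= 0:
        return PeakList((), (float(x[0]), float(x[-1])))

    # Robust noise floor: residual of the smoother estimates the white-noise
    # sd; prominences below a few noise sd on the smoothed trace are noise
    # bumps, whatever the window span is.
    sd_res = 1.4826 * float(np.median(np.abs(spectrum.absorbance - y)))
    coeffs = savgol_coeffs(sg_window_points, sg_polyorder)
    noise_gain = float(np.sqrt(np.sum(coeffs ** 2)))
    prom_floor = max(min_prominence_frac * span, 5.0 * noise_gain * sd_res)

    idx, props = find_peaks(y, prominence=prom_floor)
    peaks: list[Peak] = []
    apex_positions: list[float] = []
    for i, prom in zip(idx, props["prominences"]):
        pos, height = _parabolic_refine(x, y, int(i))
        height = max(0.0, height)
        peaks.append(Peak(pos, height, float(min(prom, height)), is_shoulder=False))
        apex_positions.append(pos)

    # Second derivative on a doubled smoothing window: SG differentiation
    # amplifies high-frequency noise steeply, and shoulders of interest are
    # broad (>= band FWHM), so the wider window costs no real feature.
    d2_window = min(2 * sg_window_points + 1, len(spectrum) - (len(spectrum) + 1) % 2)
    d2 = savgol_filter(spectrum.absorbance, d2_window, sg_polyorder,
                       deriv=2, delta=step)
    d2max = float(np.abs(d2).max())
    d2_coeffs = savgol_coeffs(d2_window, sg_polyorder, deriv=2, delta=step)
    d2_noise = float(np.sqrt(np.sum(d2_coeffs ** 2))) * sd_res
    d2_floor = max(shoulder_threshold * d2max, 5.0 * d2_noise)
    if d2max > 0:
        min_idx, _ = find_peaks(-d2)
        for i in min_idx:
            if abs(d2[i]) < d2_floor:
                continue
            pos, _ = _parabolic_refine(x, -d2, int(i))
            if apex_positions and min(abs(pos - a) for a in apex_positions) <= 2 * step:
                continue
            height = max(0.0, float(np.interp(pos, x, y)))
            # a shoulder must ride on real absorbance, not on noise wiggles
            if height < 0.15 * float(y.max()):
                continue
            peaks.append(Peak(pos, height, 0.0, is_shoulder=True))

    peaks.sort(key=lambda p: p.position)
    return PeakList(tuple(peaks), (float(x[0]), float(x[-1])))


# ---------------------------------------------------------------------------
# band assignment


@dataclass(frozen=True)
class Assignment:
    """Status of one library band: matched / present_low / absent."""

    status: Literal["matched", "present_low", "absent"]
    position: float | None = None
    height: float | None = None
    is_shoulder: bool = False


@dataclass(frozen=True)
class AssignmentReport:
    """Band-table row for one sample: exactly one status per library code."""

    library: BandLibrary
    assignments: Mapping[str, Assignment]
    meta: SampleMeta = field(default_factory=SampleMeta)

    def __post_init__(self) -> None:
        if set(self.assignments) != set(self.library.codes()):
            raise ContractError("report must carry exactly one status per library code")

    def __getitem__(self, code: str) -> Assignment:
        return self.assignments[code]

    def status(self, code: str) -> str:
        return self.assignments[code].status

    def matched_codes(self) -> list[str]:
        return [c for c in self.library.codes() if self.assignments[c].status == "matched"]


def match_bands(peaks: PeakList, library: BandLibrary,
                low_intensity_frac: float = 0.08,
                meta: SampleMeta | None = None) -> AssignmentReport:
    """Assign detected peaks to library bands.

    Each peak may satisfy at most one band: the containing band with the
    nearest center (ties toward lower wavenumber). Per band, shoulder
    detections are preferred when the band is shoulder-expected. Bands whose
    best peak is shorter than ``low_intensity_frac`` x the tallest matched
    height are downgraded to ``present_low`` ("+" in table rendering);
    bands with no peak in-window are ``absent`` ("-").
    """
    # peak -> band (nearest center among containing bands)
    claimed: dict[str, list[Peak]] = {b.code: [] for b in library}
    for p in peaks:
        containing = [b for b in library if b.contains(p.position)]
        if not containing:
            continue
        best = min(containing, key=lambda b: (abs(p.position - b.center), b.center))
        claimed[best.code].append(p)

    chosen: dict[str, Peak] = {}
    for b in library:
        cands = claimed[b.code]
        if not cands:
            continue
        if b.shoulder_expected and any(p.is_shoulder for p in cands):
            cands = [p for p in cands if p.is_shoulder]
        chosen[b.code] = min(cands, key=lambda p: (abs(p.position - b.center), p.position))

    tallest = max((p.height for p in chosen.values()), default=0.0)
    assignments: dict[str, Assignment] = {}
    for b in library:
        p = chosen.get(b.code)
        if p is None:
            assignments[b.code] = Assignment("absent")
        elif tallest > 0 and p.height < low_intensity_frac * tallest:
            assignments[b.code] = Assignment("present_low", p.position, p.height, p.is_shoulder)
        else:
            assignments[b.code] = Assignment("matched", p.position, p.height, p.is_shoulder)
    return AssignmentReport(library, assignments, meta or SampleMeta())


# ---------------------------------------------------------------------------
# classification


@dataclass(frozen=True)
class TypeProfile:
    """Evidence-weighted classification of one sample."""

    evidence: Mapping[str, tuple[float, float]]  # type -> (specific score, shared score)
    dominant: Literal["iota", "kappa", "nu", "mixture", "undetermined"] = "undetermined"
    colloid_family: Literal["carrageenan", "fucoidan", "alginate", "undetermined"] = "undetermined"


def _status_weight(a: Assignment) -> float:
    return {"matched": 1.0, "present_low": 0.5, "absent": 0.0}[a.status]


def classify_carrageenan(report: AssignmentReport) -> TypeProfile:
    """Dominant carrageenan type from an assignment report.

    Scores: iota = iota-exclusive bands (DA2S, DA2S*); nu = nu-exclusive
    bands (G/D2S, G/D6S, and G/D6S* at its library half-weight); kappa =
    the shared iota/kappa anhydro-bridge bands (DA, DA*) counted only when
    no iota-exclusive evidence exists. present_low counts at half weight.
    ``mixture`` when >= 2 types score >= 1; ``undetermined`` when no
    type-specific band matched at all.
    """
    lib = report.library
    if not (lib.types & CARRAGEENAN_TYPES):
        raise ContractError(f"library {lib.name!r} carries no carrageenan types")

    def band_w(b: BandReference) -> float:
        return b.weight * _status_weight(report[b.code])

    score = {"iota": 0.0, "kappa": 0.0, "nu": 0.0}
    bridge = 0.0  # iota/kappa shared anhydro-bridge evidence
    for b in lib:
        w = band_w(b)
        if w == 0.0 or b.specificity != "specific":
            continue
        if b.indicated_types == {"iota"}:
            score["iota"] += w
        elif b.indicated_types == {"nu"}:
            score["nu"] += w
        elif b.indicated_types == {"iota", "kappa"}:
            bridge += w
    if score["iota"] == 0.0:
        score["kappa"] = bridge

    evidence: dict[str, tuple[float, float]] = {}
    for t in sorted(lib.types & CARRAGEENAN_TYPES):
        spec = sum(band_w(b) for b in lib
                   if b.specificity == "specific" and t in b.indicated_types)
        shared = sum(band_w(b) for b in lib
                     if b.specificity == "shared" and t in b.indicated_types)
        evidence[t] = (spec, shared)

    any_specific = any(
        report[b.code].status != "absent" for b in lib if b.specificity == "specific")
    strong = [t for t, s in score.items() if s >= 1.0]
    if not any_specific or all(s == 0.0 for s in score.values()):
        dominant = "undetermined"
    elif len(strong) >= 2:
        dominant = "mixture"
    else:
        best = max(score.values())
        winners = [t for t, s in score.items() if s == best]
        dominant = winners[0] if len(winners) == 1 else "undetermined"

    family = "undetermined"
    backbone = any(report.status(c) == "matched" for c in ("G/D", "G4S")
                   if c in report.assignments)
    if "S=O" in report.assignments and report.status("S=O") == "matched" and backbone:
        family = "carrageenan"
    return TypeProfile(evidence=evidence, dominant=dominant, colloid_family=family)


def classify_colloid_family(peaks: PeakList,
                            libraries: Iterable[BandLibrary]) -> TypeProfile:
    """Colloid family = library with the highest fraction of markers matched.

    present_low hits count at half. The fraction is shrunk as
    ``hits / (n_bands + 1)`` so that a small marker library cannot win on a
    single coincidental hit against a large library with many true matches;
    ties and all-zero scores give ``undetermined``.
    """
    libraries = list(libraries)
    if not libraries:
        raise ContractError("classify_colloid_family needs at least one library")
    fractions: dict[str, float] = {}
    for lib in libraries:
        report = match_bands(peaks, lib)
        hit = sum(_status_weight(report[c]) for c in lib.codes())
        fractions[lib.name] = hit / (len(lib) + 1)
    best = max(fractions.values())
    winners = [n for n, f in fractions.items() if f == best]
    family = winners[0] if (best > 0 and len(winners) == 1) else "undetermined"
    evidence = {n: (f, 0.0) for n, f in fractions.items()}
    return TypeProfile(evidence=evidence, dominant="undetermined",
                       colloid_family=family)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# table rendering


def render_cell(a: Assignment) -> str:
    if a.status == "matched":
        return f"{a.position:.2f}"
    return "+" if a.status == "present_low" else "-"


def report_to_table(reports: Iterable[AssignmentReport]) -> pd.DataFrame:
    """Render reports as a band table: rows = samples, columns = band codes.

    Cells follow the published convention: position to 2 decimals when
    matched, "+" when present at low intensity, "-" when absent.
    """
    reports = list(reports)
    if not reports:
        return pd.DataFrame()
    lib = reports[0].library
    for r in reports[1:]:
        if (r.library.name, r.library.version) != (lib.name, lib.version):
            raise ContractError("all reports in one table must share a library")
    rows = {}
    for r in reports:
        rows[r.meta.sample_id or f"sample{len(rows) + 1}"] = [
            render_cell(r[c]) for c in lib.codes()]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=lib.codes())
    df.index.name = "sample_id"
    return df
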
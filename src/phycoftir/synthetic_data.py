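"""Seeded synthetic ATR-FTIR spectra with known ground-truth composition.

No public repository of raw seaweed-polysaccharide ATR spectra exists for
the systems this package targets, so every other module is exercised on
simulated data with planted truth. A spectrum is a weighted sum of
component band sets (iota/kappa/nu carrageenan, fucoidan, alginate, and a
protein amide background), each band a pseudo-Voigt profile, plus a smooth
low-order polynomial baseline drift and additive Gaussian noise.

Band centers for the carrageenan components are the positions measured on
commercial iota and kappa standards; fucoidan and alginate use their
published marker positions. Relative heights use three tiers
(1.0 strong / 0.5 medium / 0.25 weak-shouldered) so that the
matched-vs-"present (low intensity)" distinction in band tables is
meaningful on simulated data.

Seeding: one master seed per dataset; each spectrum draws from a
``numpy.random.SeedSequence(master, spawn_key=(year, month, replicate))``
stream, so adding a month to a design never perturbs the other months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .spectra_io import SampleMeta, Spectrum, SpectrumSet, canonical_grid

DEFAULT_ETA = 0.3          # Lorentzian fraction of the pseudo-Voigt profile
FWHM_STRONG = 12.0         # cm^-1
FWHM_SHOULDER = 14.0       # cm^-1, shouldered bands overlap their neighbor more
COMPONENTS = ("iota", "kappa", "nu", "fucoidan", "alginate", "amide_background")


@dataclass(frozen=True)
class BandShape:
    """One planted absorption band (pseudo-Voigt)."""

    center: float
    height: float
    fwhm: float = FWHM_STRONG
    eta: float = DEFAULT_ETA

    def __post_init__(self) -> None:
        if self.height < 0:
            raise ContractError("band height must be >= 0")
        if self.fwhm <= 0:
            raise ContractError("band fwhm must be > 0")
        if not 0.0 <= self.eta <= 1.0:
            raise ContractError("eta must lie in [0, 1]")


def pseudo_voigt(x: np.ndarray, band: BandShape) -> np.ndarray:
    """Height-normalized pseudo-Voigt: (1-eta) Gaussian + eta Lorentzian."""
    x = np.asarray(x, dtype=float)
    u = (x - band.center) / band.fwhm
    gauss = np.exp(-4.0 * np.log(2.0) * u * u)
    lorentz = 1.0 / (1.0 + 4.0 * u * u)
    return band.height * ((1.0 - band.eta) * gauss + band.eta * lorentz)


# canonical component band sets: (center, height, fwhm)
_COMPONENT_BANDS: dict[str, tuple[tuple[float, float, float], ...]] = {
    # measured on the commercial iota-carrageenan standard
    "iota": (
        (1218.05, 1.00, FWHM_STRONG),   # S=O ester sulfate
        (1066.37, 0.25, FWHM_SHOULDER), # DA* (shoulder)
        (967.89, 1.00, FWHM_STRONG),    # G/D galactose backbone
        (923.74, 0.50, FWHM_STRONG),    # DA anhydro bridge
        (901.51, 0.25, FWHM_SHOULDER),  # DA2S* (shoulder)
        (870.45, 0.25, FWHM_SHOULDER),  # G/D6S* sulfate feature
        (844.70, 1.00, FWHM_STRONG),    # G4S
        (802.50, 0.50, FWHM_STRONG),    # DA2S
    ),
    # measured on the commercial kappa-carrageenan standard
    "kappa": (
        (1224.62, 1.00, FWHM_STRONG),
        (1063.61, 0.25, FWHM_SHOULDER),
        (970.00, 1.00, FWHM_STRONG),
        (921.27, 0.50, FWHM_STRONG),
        (874.26, 0.25, FWHM_SHOULDER),
        (843.27, 1.00, FWHM_STRONG),
    ),
    # biosynthetic precursor: C6 sulfate instead of the anhydro bridge
    "nu": (
        (1232.00, 1.00, FWHM_STRONG),   # S=O (more sulfated)
        (971.00, 1.00, FWHM_STRONG),    # G/D
        (867.00, 0.50, FWHM_SHOULDER),  # G/D6S*
        (843.00, 1.00, FWHM_STRONG),    # G4S
        (827.50, 0.50, FWHM_STRONG),    # G/D2S
        (817.50, 0.50, FWHM_STRONG),    # G/D6S
    ),
    "fucoidan": (
        (1220.00, 1.00, FWHM_STRONG),   # S=O
        (1020.00, 1.00, 18.0),          # O=S=O broad envelope
        (820.00, 0.60, FWHM_STRONG),    # C-O-S
    ),
    "alginate": (
        (1600.00, 1.00, 16.0),          # carboxylate C-C / C=O
        (1410.00, 0.80, 16.0),          # C-OH
        (1081.00, 0.60, FWHM_SHOULDER), # guluronic ring
        (1026.00, 1.00, 18.0),          # O=S=O / C-O envelope
        (797.00, 0.50, FWHM_STRONG),    # guluronic anomeric
    ),
    # protein contamination: amide I/II envelope
    "amide_background": (
        (1645.00, 0.30, 40.0),
        (1555.00, 0.40, 30.0),
    ),
}


def component_bandset(component: str, library=None) -> list[BandShape]:
    """Canonical band set of one composition component.

    If a :class:`~phycoftir.band_model.BandLibrary` is passed, each band
    falling inside a library window is checked for consistency (centers
    must lie in their band's window).
    """
    try:
        rows = _COMPONENT_BANDS[component]
    except KeyError:
        raise ContractError(
            f"unknown component {component!r}; known: {sorted(_COMPONENT_BANDS)}") from None
    bands = [BandShape(center=c, height=h, fwhm=f) for c, h, f in rows]
    if library is not None:
        in_any = [any(b.contains(s.center) for b in library) for s in bands]
        if not any(in_any):
            raise ContractError(
                f"no band of component {component!r} falls in a window of "
                f"library {library.name!r}")
    return bands


@dataclass(frozen=True)
class CompositionProfile:
    """Nonnegative component weights defining one sample's composition."""

    weights: Mapping[str, float]
    name: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.weights) - set(COMPONENTS)
        if unknown:
            raise ContractError(f"unknown components: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise ContractError("component weights must be nonnegative")
        if not any(w > 0 for w in self.weights.values()):
            raise ContractError("at least one component weight must be positive")


def simulate_spectrum(profile: CompositionProfile | Mapping[str, float],
                      grid: np.ndarray | None = None, *,
                      position_jitter_sd: float = 0.0,
                      height_cv: float = 0.0,
                      noise_sd: float = 0.0,
                      baseline_drift_amplitude: float = 0.0,
                      seed: int | np.random.SeedSequence | np.random.Generator = 0,
                      meta: SampleMeta | None = None
                      ) -> tuple[Spectrum, list[BandShape]]:
    """Simulate one absorbance trace; returns (spectrum, planted bands).

    absorbance = sum_c w_c * sum_bands pseudoVoigt(center+jitter,
    height*(1 + cv*eps), fwhm, eta) + smooth quadratic drift + N(0, sd).
    Fully reproducible from *seed*.
    """
    if not isinstance(profile, CompositionProfile):
        weights = dict(profile)
        if any(w > 0 for w in weights.values()):
            profile = CompositionProfile(weights)
        else:
            # degenerate request: no signal at all; keep going with a warning
            warnings.warn("all component weights are zero; "
                          "returning a baseline/noise-only trace")
            profile = None  # type: ignore[assignment]
    if grid is None:
        grid = canonical_grid()
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ContractError("grid must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    active = ({c: w for c, w in profile.weights.items() if w > 0}
              if profile is not None else {})
    y = np.zeros_like(grid)
    planted: list[BandShape] = []
    for comp in sorted(active):
        w = active[comp]
        for b in component_bandset(comp):
            center = b.center + (rng.normal(0.0, position_jitter_sd)
                                 if position_jitter_sd > 0 else 0.0)
            height = w * b.height * (1.0 + (height_cv * rng.standard_normal()
                                            if height_cv > 0 else 0.0))
            realized = BandShape(center=center, height=max(0.0, height),
                                 fwhm=b.fwhm, eta=b.eta)
            planted.append(realized)
            y += pseudo_voigt(grid, realized)

    if baseline_drift_amplitude > 0:
        t = (grid - grid[0]) / (grid[-1] - grid[0])
        coeffs = rng.uniform(-1.0, 1.0, size=3)
        drift = coeffs[0] + coeffs[1] * t + coeffs[2] * t * t
        peak = np.abs(drift).max()
        if peak > 0:
            y += baseline_drift_amplitude * drift / peak
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=grid.size)

    name = (profile.name if profile is not None else "") or "synthetic"
    return Spectrum(grid, y, meta or SampleMeta(sample_id=name)), planted


# ---------------------------------------------------------------------------
# seasonal datasets


@dataclass(frozen=True)
class SeasonalDesign:
    """A monthly sampling design with per-month composition profiles."""

    name: str
    species: str
    months: tuple[tuple[int, int], ...]          # (month, year)
    profile_per_month: Mapping[int, CompositionProfile]
    n_replicates: int = 3
    position_jitter_sd: float = 0.5              # cm^-1
    height_cv: float = 0.05
    noise_sd: float = 0.005                      # AU
    baseline_drift_amplitude: float = 0.02       # AU
    seed: int = 0
    grid: np.ndarray | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ContractError("n_replicates must be >= 1")
        for v in (self.position_jitter_sd, self.height_cv, self.noise_sd,
                  self.baseline_drift_amplitude):
            if v < 0:
                raise ContractError("dispersions must be >= 0")
        for m, _ in self.months:
            if m not in self.profile_per_month:
                raise ContractError(f"no composition profile for month {m}")


def simulate_seasonal_dataset(design: SeasonalDesign) -> tuple[SpectrumSet, pd.DataFrame]:
    """Simulate the full design; returns (spectra, ground-truth table).

    Ground truth has one row per planted band with the sample's component
    weights alongside. Deterministic from ``design.seed``.
    """
    grid = design.grid if design.grid is not None else canonical_grid()
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []
    for month, year in design.months:
        profile = design.profile_per_month[month]
        for rep in range(1, design.n_replicates + 1):
            ss = np.random.SeedSequence(design.seed, spawn_key=(year, month, rep))
            rng = np.random.default_rng(ss)
            meta = SampleMeta(
                sample_id=f"{design.species}_{year}-{month:02d}_rep{rep}",
                species=design.species, month=month, year=year, replicate=rep)
            spec, planted = simulate_spectrum(
                profile, grid,
                position_jitter_sd=design.position_jitter_sd,
                height_cv=design.height_cv,
                noise_sd=design.noise_sd,
                baseline_drift_amplitude=design.baseline_drift_amplitude,
                seed=rng, meta=meta)
            spectra.append(spec)
            for band in planted:
                truth_rows.append({
                    "sample_id": meta.sample_id, "month": month, "year": year,
                    "replicate": rep, "profile": profile.name,
                    "center": band.center, "height": band.height,
                    "fwhm": band.fwhm, "eta": band.eta,
                    **{f"w_{c}": profile.weights.get(c, 0.0) for c in COMPONENTS},
                })
    return SpectrumSet(spectra, grid), pd.DataFrame(truth_rows)


def month_to_season(month: int) -> str:
    return {12: "winter", 1: "winter", 2: "winter",
            3: "spring", 4: "spring", 5: "spring",
            6: "summer", 7: "summer", 8: "summer",
            9: "autumn", 10: "autumn", 11: "autumn"}[month]


def solieria_2014(seed: int = 0, grid: np.ndarray | None = None) -> SeasonalDesign:
    """Red-alga design: 12 months x 3 replicates, two-block seasonal structure.

    September-December (maturity): pure iota-carrageenan with a small
    protein background. January-August (growth/transition): iota plus a
    nu-precursor fraction and a stronger amide background. The between-block
    composition shift is several times the within-month dispersion.
    """
    mature = CompositionProfile({"iota": 1.0, "amide_background": 0.1}, name="mature_iota")
    growth = CompositionProfile({"iota": 1.0, "nu": 0.3, "amide_background": 0.3},
                                name="growth_iota_nu")
    profiles = {m: (mature if m in (9, 10, 11, 12) else growth) for m in range(1, 13)}
    return SeasonalDesign(
        name="solieria_2014", species="Schordalis",
        months=tuple((m, 2014) for m in range(1, 13)),
        profile_per_month=profiles, seed=seed, grid=grid)


def sargassum_2015(seed: int = 0, grid: np.ndarray | None = None) -> SeasonalDesign:
    """Brown-alga design: 4 sampling months (Feb/Apr/Jun/Oct) x 3 replicates.

    Alginate-dominated composition whose alginate/fucoidan balance shifts
    with season, one profile per sampled month.
    """
    profiles = {
        2: CompositionProfile({"alginate": 1.0, "fucoidan": 0.35,
                               "amide_background": 0.15}, name="winter"),
        4: CompositionProfile({"alginate": 0.85, "fucoidan": 0.55,
                               "amide_background": 0.20}, name="spring"),
        6: CompositionProfile({"alginate": 1.15, "fucoidan": 0.20,
                               "amide_background": 0.30}, name="summer"),
        10: CompositionProfile({"alginate": 1.0, "fucoidan": 0.70,
                                "amide_background": 0.10}, name="autumn"),
    }
    return SeasonalDesign(
        name="sargassum_2015", species="Smuticum",
        months=((2, 2015), (4, 2015), (6, 2015), (10, 2015)),
        profile_per_month=profiles, seed=seed, grid=grid)


SHIPPED_DESIGNS = {"solieria_2014": solieria_2014, "sargassum_2015": sargassum_2015}

#: Canonical single-sample composition profiles used for classifier checks.
SHIPPED_PROFILES = {
    "iota": CompositionProfile({"iota": 1.0, "amide_background": 0.1}, name="iota"),
    "kappa": CompositionProfile({"kappa": 1.0, "amide_background": 0.1}, name="kappa"),
    "fucoidan": CompositionProfile({"fucoidan": 1.0, "amide_background": 0.1},
                                   name="fucoidan"),
    "alginate": CompositionProfile({"alginate": 1.0, "amide_background": 0.1},
                                   name="alginate"),
}
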
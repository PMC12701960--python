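"""Per-scan diagnostic-ion matching with tolerance and noise filtering.

Each selected ion is looked up independently against the scan (no peak
exclusivity — isobaric catalog entries may share a peak; one ion consumes at
most one peak). A peak qualifies when it lies within the tolerance window
around the theoretical m/z and passes the signal filter: the S/N threshold
when the scan carries noise estimates, the intensity threshold otherwise.
Among qualifying peaks the most intense wins; intensity ties break toward
the smallest absolute mass error.

Peak depth is the intensity rank within the whole scan (1 = most intense;
ties broken by ascending m/z).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from glycoscreen.ion_library import IonDefinition, IonSelection
from glycoscreen.spectra_io import ActivationType, SpectrumRecord

#: Peak-depth windows used for the classifier's in-window ion count.
DEFAULT_DEPTH_WINDOWS: dict[ActivationType, int] = {
    ActivationType.HCD: 25,
    ActivationType.ETD_FAMILY: 50,
    ActivationType.UVPD: 25,
    ActivationType.OTHER: 25,
}


@dataclass(frozen=True)
class ExtractionSettings:
    """Tolerance, thresholds and MS-level selection for ion extraction."""

    tolerance_value: float = 15.0
    tolerance_unit: str = "ppm"  # "ppm" or "Da"
    sn_threshold: float = 3.0
    intensity_threshold: float = 0.0
    ms_levels: frozenset[int] = frozenset({2})

    def __post_init__(self) -> None:
        if self.tolerance_value <= 0:
            raise ValueError("tolerance must be positive")
        if self.tolerance_unit not in ("ppm", "Da"):
            raise ValueError(f"tolerance unit must be 'ppm' or 'Da', got {self.tolerance_unit!r}")
        if self.sn_threshold < 0 or self.intensity_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        object.__setattr__(self, "ms_levels", frozenset(int(l) for l in self.ms_levels))

    def window_da(self, theoretical_mz: float) -> float:
        """Half-width of the symmetric match window, in Da, at this m/z."""
        if self.tolerance_unit == "ppm":
            return theoretical_mz * self.tolerance_value * 1e-6
        return self.tolerance_value


@dataclass(frozen=True)
class IonMatch:
    ion_name: str
    observed_mz: float
    intensity: float
    peak_depth: int  # 1 = most intense peak in the scan
    mass_error_ppm: float


@dataclass
class SpectrumOxoniumSummary:
    """Extraction result for one scan."""

    scan_number: int
    activation: ActivationType
    tic: float
    matches: list[IonMatch] = field(default_factory=list)
    oxonium_tic_fraction: float = 0.0
    n_matched: int = 0
    n_matched_in_window: int = 0
    likely_glyco: bool = False
    ms_level: int = 2
    retention_time: float | None = None

    @property
    def matched_names(self) -> set[str]:
        return {m.ion_name for m in self.matches}


def rank_peaks(spectrum: SpectrumRecord) -> np.ndarray:
    """Intensity ranks per peak (1 = most intense; ties → lower m/z first).

    Returns an array parallel to the peak arrays; empty for an empty scan.
    """
    n = spectrum.n_peaks
    if n == 0:
        return np.array([], dtype=np.int64)
    # stable sort on ascending m/z order input gives the documented tie-break
    order = np.argsort(-spectrum.intensity, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def _qualifying(spectrum: SpectrumRecord, settings: ExtractionSettings) -> np.ndarray:
    """Boolean mask of peaks passing the S/N-or-intensity filter."""
    if spectrum.noise is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            sn = np.where(spectrum.noise > 0, spectrum.intensity / spectrum.noise, np.inf)
        return sn >= settings.sn_threshold
    return spectrum.intensity >= settings.intensity_threshold


def match_ion(
    spectrum: SpectrumRecord,
    ion: IonDefinition,
    settings: ExtractionSettings,
    ranks: np.ndarray | None = None,
    qualifying: np.ndarray | None = None,
) -> IonMatch | None:
    """Match one ion against a scan; ``None`` when no peak qualifies."""
    if spectrum.n_peaks == 0:
        return None
    if ranks is None:
        ranks = rank_peaks(spectrum)
    if qualifying is None:
        qualifying = _qualifying(spectrum, settings)

    target = ion.mz
    half = settings.window_da(target)
    lo = int(np.searchsorted(spectrum.mz, target - half, side="left"))
    hi = int(np.searchsorted(spectrum.mz, target + half, side="right"))
    if lo >= hi:
        return None
    idx = np.arange(lo, hi)[qualifying[lo:hi]]
    if idx.size == 0:
        return None
    best = None
    best_key = None
    for i in idx:
        err = abs(spectrum.mz[i] - target)
        key = (-spectrum.intensity[i], err)
        if best_key is None or key < best_key:
            best, best_key = int(i), key
    observed = float(spectrum.mz[best])
    return IonMatch(
        ion_name=ion.name,
        observed_mz=observed,
        intensity=float(spectrum.intensity[best]),
        peak_depth=int(ranks[best]),
        mass_error_ppm=(observed - target) / target * 1e6,
    )


def extract_spectrum(
    spectrum: SpectrumRecord,
    ions: IonSelection | Iterable[IonDefinition],
    settings: ExtractionSettings = ExtractionSettings(),
    depth_windows: dict[ActivationType, int] | None = None,
) -> SpectrumOxoniumSummary:
    """Extract every selected ion from one scan.

    The TIC fraction sums *all* matched intensities regardless of depth;
    the depth window only gates ``n_matched_in_window`` (used by the
    classifier count rule). The ``likely_glyco`` flag is left False here and
    filled by :mod:`glycoscreen.glyco_classifier`.
    """
    windows = depth_windows or DEFAULT_DEPTH_WINDOWS
    ranks = rank_peaks(spectrum)
    qualifying = _qualifying(spectrum, settings)
    matches = []
    for ion in ions:
        match = match_ion(spectrum, ion, settings, ranks=ranks, qualifying=qualifying)
        if match is not None:
            matches.append(match)

    window = windows.get(spectrum.activation, windows[ActivationType.OTHER])
    matched_intensity = sum(m.intensity for m in matches)
    fraction = min(1.0, matched_intensity / spectrum.tic) if spectrum.tic > 0 else 0.0
    return SpectrumOxoniumSummary(
        scan_number=spectrum.scan_number,
        activation=spectrum.activation,
        tic=spectrum.tic,
        matches=matches,
        oxonium_tic_fraction=fraction,
        n_matched=len(matches),
        n_matched_in_window=sum(1 for m in matches if m.peak_depth <= window),
        ms_level=spectrum.ms_level,
        retention_time=spectrum.retention_time,
    )
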
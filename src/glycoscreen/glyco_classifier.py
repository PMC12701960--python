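"""The LikelyGlycoSpectrum classifier.

A scan is flagged when two conjuncts hold for its activation family:

1. the number of matched diagnostic ions found within the family's
   peak-depth window (25 / 50 / 25 most intense peaks for HCD / ETD-family /
   UVPD) reaches the required count, and
2. the summed matched-ion intensity is at least the family's minimum TIC
   fraction (defaults 0.20 / 0.05 / 0.20).

The required count scales with the number of ions the user selected:
4 below six selected ions, half the selection (rounded half up) for 6–15,
and 8 above 15; ETD-family counts are halved (half up). The count can never
drop below 4, and with fewer than four ions selected no scan is ever
flagged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from glycoscreen.oxonium_extraction import DEFAULT_DEPTH_WINDOWS, SpectrumOxoniumSummary
from glycoscreen.spectra_io import ActivationType

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ClassifierSettings:
    """Per-activation thresholds and count-rule parameters; all overridable."""

    depth_windows: dict[ActivationType, int] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_WINDOWS)
    )
    tic_fraction_min: dict[ActivationType, float] = field(
        default_factory=lambda: {
            ActivationType.HCD: 0.20,
            ActivationType.ETD_FAMILY: 0.05,
            ActivationType.UVPD: 0.20,
        }
    )
    small_set_count: int = 4   # required below small_set_limit selected ions
    small_set_limit: int = 6
    mid_set_limit: int = 15    # inclusive upper bound of the "half of n" regime
    large_set_count: int = 8   # required above mid_set_limit
    etd_halving: bool = True
    absolute_min: int = 4

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.depth_windows.values()):
            raise ValueError("depth windows must be >= 1")
        if any(not 0.0 <= f <= 1.0 for f in self.tic_fraction_min.values()):
            raise ValueError("TIC fraction thresholds must be within [0, 1]")


def required_ion_count(
    n_selected: int,
    activation: ActivationType,
    settings: ClassifierSettings = ClassifierSettings(),
) -> int | None:
    """Matched-ion count required for a LikelyGlyco call; ``None`` = never.

    With fewer than ``absolute_min`` (default 4) ions selected, no spectrum
    can be flagged, so ``None`` is returned.
    """
    if n_selected < 0:
        raise ValueError("n_selected must be non-negative")
    if n_selected < settings.absolute_min:
        return None
    if n_selected < settings.small_set_limit:
        base = settings.small_set_count
    elif n_selected <= settings.mid_set_limit:
        base = _round_half_up(n_selected / 2)
    else:
        base = settings.large_set_count
    if activation is ActivationType.ETD_FAMILY and settings.etd_halving:
        base = _round_half_up(base / 2)
    return max(settings.absolute_min, base)


def classify_spectrum(
    summary: SpectrumOxoniumSummary,
    n_selected: int,
    settings: ClassifierSettings = ClassifierSettings(),
) -> bool:
    """LikelyGlycoSpectrum boolean for one extracted scan.

    Scans with an unrecognized activation are never flagged (logged skip).
    """
    activation = summary.activation
    if activation not in settings.tic_fraction_min:
        logger.debug(
            "scan %s: activation %s not eligible for classification",
            summary.scan_number, activation.value,
        )
        return False
    required = required_ion_count(n_selected, activation, settings)
    if required is None:
        return False
    return (
        summary.n_matched_in_window >= required
        and summary.oxonium_tic_fraction >= settings.tic_fraction_min[activation]
    )


def classify_summaries(
    summaries: list[SpectrumOxoniumSummary],
    n_selected: int,
    settings: ClassifierSettings = ClassifierSettings(),
) -> list[SpectrumOxoniumSummary]:
    """Fill ``likely_glyco`` in place for a batch of summaries."""
    for summary in summaries:
        summary.likely_glyco = classify_spectrum(summary, n_selected, settings)
    return summaries
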
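"""Y-type ion enumeration and extraction for identified glycopeptides.

Y-ions are peptide-backbone fragments that retain part of the glycan. Two
equivalent definitions are supported:

* ``REMAINDER`` — specify the monosaccharide composition still attached to
  the peptide; the ion mass is built up from the bare peptide backbone.
* ``NEUTRAL_LOSS`` — specify the glycan mass lost from the intact precursor
  glycopeptide; the ion mass is built down from the precursor neutral mass.

For a glycan partitioned into remainder R and loss L (R + L = glycan), the
two routes give identical m/z at every charge and isotope — the module's
central algebraic invariant.

Inputs are a PSM table in a FragPipe-psm.tsv-like dialect and a glycan
database (TSV with ``glycan`` and ``mass`` columns). Matching against the
spectrum reuses the oxonium-extraction matcher, so tolerance and threshold
semantics are identical.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from glycoscreen.ion_library import (
    ISOTOPE_SPACING,
    PROTON_MASS,
    WATER_MASS,
    composition_mass,
    parse_composition,
)
from glycoscreen.oxonium_extraction import (
    ExtractionSettings,
    IonMatch,
    match_ion,
    rank_peaks,
    _qualifying,
)
from glycoscreen.ion_library import IonDefinition
from glycoscreen.spectra_io import SpectrumRecord

logger = logging.getLogger(__name__)

#: Monoisotopic residue masses of the 20 canonical amino acids, Da.
AMINO_ACID_MASSES: Mapping[str, float] = {
    "G": 57.02146374, "A": 71.03711379, "S": 87.03202841, "P": 97.05276385,
    "V": 99.06841392, "T": 101.04767847, "C": 103.00918496, "L": 113.08406398,
    "I": 113.08406398, "N": 114.04292745, "D": 115.02694302, "Q": 128.05857751,
    "K": 128.09496302, "E": 129.04259309, "M": 131.04048509, "H": 137.05891186,
    "F": 147.06841392, "R": 156.10111102, "Y": 163.06332853, "W": 186.07931295,
}


def peptide_backbone_mass(
    sequence: str,
    modifications: Sequence[tuple[int, float]] = (),
) -> float:
    """Neutral monoisotopic mass of a peptide with non-glycan modifications.

    ``modifications`` are (position, delta-mass) pairs; positions are not
    interpreted, only the deltas are summed. The glycan mass is explicitly
    NOT included.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    mass = WATER_MASS
    for letter in sequence:
        try:
            mass += AMINO_ACID_MASSES[letter]
        except KeyError:
            raise ValueError(
                f"unknown amino acid residue {letter!r} in {sequence!r}"
            ) from None
    for _pos, delta in modifications:
        mass += delta
    return mass


class YIonMode(Enum):
    REMAINDER = "remainder"
    NEUTRAL_LOSS = "neutral-loss"


@dataclass(frozen=True)
class YIonDefinition:
    """One Y-ion target: mode, mass delta, charge and isotope index."""

    mode: YIonMode
    delta_mass: float  # remainder composition mass, or neutral-loss mass
    charge: int
    isotope: int  # 0 = monoisotopic, 1 = M+1, 2 = M+2
    label: str

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError("Y-ion charge must be >= 1")
        if self.isotope not in (0, 1, 2):
            raise ValueError("isotope index must be 0, 1 or 2")
        if self.mode is YIonMode.REMAINDER and self.delta_mass < 0:
            raise ValueError("remainder mass must be non-negative")


def y_ion_mz_remainder(
    peptide_mass: float, remainder_mass: float, charge: int, isotope: int = 0
) -> float:
    """m/z of a Y-ion built from the bare peptide plus a glycan remainder."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (
        (peptide_mass + remainder_mass + charge * PROTON_MASS) / charge
        + isotope * ISOTOPE_SPACING / charge
    )


def y_ion_mz_neutral_loss(
    precursor_neutral_mass: float, loss_mass: float, charge: int, isotope: int = 0
) -> float:
    """m/z of a Y-ion built from the intact precursor minus a neutral loss."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    residual = precursor_neutral_mass - loss_mass
    if residual <= 0:
        raise ValueError(
            f"neutral loss {loss_mass} Da exceeds precursor mass "
            f"{precursor_neutral_mass} Da"
        )
    return (
        (residual + charge * PROTON_MASS) / charge
        + isotope * ISOTOPE_SPACING / charge
    )


# --- charge-range specification ---------------------------------------------

_CHARGE_TERM = re.compile(r"^\s*(?:(\d+)|P\s*(?:([+-])\s*(\d+))?)\s*$", re.IGNORECASE)


def _resolve_charge_term(term: str | int, precursor_charge: int) -> int:
    if isinstance(term, int):
        return term
    match = _CHARGE_TERM.match(str(term))
    if not match:
        raise ValueError(
            f"bad charge bound {term!r}; use an integer or an expression in P "
            "such as 'P-1'"
        )
    if match.group(1) is not None:
        return int(match.group(1))
    value = precursor_charge
    if match.group(2):
        offset = int(match.group(3))
        value = value + offset if match.group(2) == "+" else value - offset
    return value


@dataclass(frozen=True)
class ChargeRangeSpec:
    """Charge bounds as integers or expressions in the precursor charge P."""

    lower: str | int = 1
    upper: str | int = "P"

    def resolve(self, precursor_charge: int) -> list[int]:
        lo = _resolve_charge_term(self.lower, precursor_charge)
        hi = _resolve_charge_term(self.upper, precursor_charge)
        hi = min(hi, precursor_charge)
        if lo < 1:
            raise ValueError(f"resolved lower charge {lo} < 1")
        if hi < lo:
            raise ValueError(
                f"resolved charge range [{lo}, {hi}] is empty for P={precursor_charge}"
            )
        return list(range(lo, hi + 1))


def resolve_charge_range(
    spec: ChargeRangeSpec | tuple[str | int, str | int], precursor_charge: int
) -> list[int]:
    """Resolve a charge-range spec against a precursor charge."""
    if not isinstance(spec, ChargeRangeSpec):
        spec = ChargeRangeSpec(*spec)
    return spec.resolve(precursor_charge)


# --- PSM and glycan-database tables ------------------------------------------

@dataclass(frozen=True)
class GlycoPSM:
    """One identified glycopeptide from a search-engine PSM table."""

    scan_number: int
    peptide_sequence: str
    modifications: tuple[tuple[int, float], ...]
    glycan_name: str
    precursor_charge: int
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        bad = set(self.peptide_sequence) - set(AMINO_ACID_MASSES)
        if bad:
            raise ValueError(
                f"peptide {self.peptide_sequence!r} contains non-canonical "
                f"residues {sorted(bad)}"
            )


_PSM_COLUMN_ALIASES = {
    "scan": ("scan", "spectrum", "spectrum name"),
    "peptide": ("peptide", "peptide sequence"),
    "modifications": ("assigned modifications", "modifications"),
    "glycan": ("total glycan composition", "glycan", "observed modifications"),
    "charge": ("charge", "precursor charge"),
    "precursor_mz": ("observed m/z", "precursor m/z"),
}

_MOD_TOKEN = re.compile(r"(\d+|N-term|C-term)[A-Za-z]*\(([-\d.]+)\)", re.IGNORECASE)
_SCAN_FROM_SPECTRUM = re.compile(r"\.(\d+)\.\d+\.\d+$")


def _parse_modifications(cell: str) -> tuple[tuple[int, float], ...]:
    """Parse FragPipe-style assigned modifications, e.g. ``"4C(57.0215)"``."""
    mods = []
    for token in cell.split(","):
        token = token.strip()
        if not token:
            continue
        match = _MOD_TOKEN.search(token)
        if not match:
            raise ValueError(f"unparsable modification token {token!r}")
        pos_text = match.group(1)
        position = 0 if pos_text.lower() in ("n-term", "c-term") else int(pos_text)
        mods.append((position, float(match.group(2))))
    return tuple(mods)


def _parse_scan(cell: str) -> int:
    cell = cell.strip()
    if cell.isdigit():
        return int(cell)
    match = _SCAN_FROM_SPECTRUM.search(cell)
    if match:
        return int(match.group(1))
    match = re.search(r"scan[=\s:]*(\d+)", cell, re.IGNORECASE)
    if match:
        return int(match.group(1))
    raise ValueError(f"cannot read a scan number from {cell!r}")


def read_psm_table(path: str | Path) -> list[GlycoPSM]:
    """Read glycopeptide PSMs from a FragPipe-psm.tsv-like TSV file.

    Required columns (case-insensitive, FragPipe names or plain aliases):
    scan/Spectrum, Peptide, Assigned Modifications, Total Glycan
    Composition/Glycan, Charge. Rows without a glycan assignment are skipped.
    """
    path = Path(path)
    psms: list[GlycoPSM] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty PSM table")
        lower = {f.strip().lower(): f for f in reader.fieldnames if f}
        cols: dict[str, str] = {}
        for key, aliases in _PSM_COLUMN_ALIASES.items():
            for alias in aliases:
                if alias in lower:
                    cols[key] = lower[alias]
                    break
        missing = {"scan", "peptide", "glycan", "charge"} - set(cols)
        if missing:
            raise ValueError(
                f"{path}: missing required PSM columns {sorted(missing)}; "
                f"header was {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            glycan = (row.get(cols["glycan"]) or "").strip()
            if not glycan:
                continue
            try:
                psms.append(
                    GlycoPSM(
                        scan_number=_parse_scan(row[cols["scan"]]),
                        peptide_sequence=(row[cols["peptide"]] or "").strip(),
                        modifications=_parse_modifications(
                            row.get(cols.get("modifications", ""), "") or ""
                        ),
                        glycan_name=glycan,
                        precursor_charge=int(float(row[cols["charge"]])),
                        precursor_mz=(
                            float(row[cols["precursor_mz"]])
                            if cols.get("precursor_mz") and row.get(cols["precursor_mz"])
                            else None
                        ),
                    )
                )
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return psms


def read_glycan_database(path: str | Path) -> dict[str, float]:
    """Read a glycan database TSV with ``glycan`` and ``mass`` columns."""
    path = Path(path)
    masses: dict[str, float] = {}
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty glycan database")
        lower = {f.strip().lower(): f for f in reader.fieldnames if f}
        name_col = lower.get("glycan") or lower.get("name") or lower.get("composition")
        mass_col = lower.get("mass") or lower.get("monoisotopic mass")
        if name_col is None or mass_col is None:
            raise ValueError(
                f"{path}: glycan database needs 'glycan' and 'mass' columns "
                f"(got {reader.fieldnames})"
            )
        for lineno, row in enumerate(reader, start=2):
            name = (row.get(name_col) or "").strip()
            if not name:
                continue
            if name in masses:
                raise ValueError(f"{path}:{lineno}: duplicate glycan name {name!r}")
            mass = float(row[mass_col])
            if mass <= 0:
                raise ValueError(f"{path}:{lineno}: non-positive glycan mass {mass}")
            masses[name] = mass
    return masses


def lookup_glycan(glycans: Mapping[str, float], name: str) -> float:
    """Resolve a glycan name; on failure, list near-miss candidates."""
    if name in glycans:
        return glycans[name]
    normalized = name.replace(" ", "").replace("%", "").lower()
    for candidate, mass in glycans.items():
        if candidate.replace(" ", "").lower() == normalized:
            return mass
    candidates = [g for g in glycans if g[: max(3, len(name) // 2)] in name or name[:3] in g]
    raise KeyError(
        f"glycan {name!r} not found in database; candidates: "
        f"{sorted(candidates)[:8] or sorted(glycans)[:8]}"
    )


# --- Y-ion enumeration and extraction ----------------------------------------

#: Default remainder compositions: Y0 plus the N-glycan core series.
DEFAULT_Y_COMPOSITIONS: tuple[str, ...] = (
    "Y0",
    "HexNAc1",
    "HexNAc2",
    "HexNAc2Hex1",
    "HexNAc2Hex2",
    "HexNAc2Hex3",
)


@dataclass(frozen=True)
class YnaughtSettings:
    """User choices for the Y-ion run."""

    remainder_compositions: tuple[str, ...] = DEFAULT_Y_COMPOSITIONS
    neutral_loss_compositions: tuple[str, ...] = ()
    isotopes: tuple[int, ...] = (0,)
    charge_range: ChargeRangeSpec = ChargeRangeSpec(1, "P")
    custom_additions: tuple[tuple[str, float], ...] = ()     # added to peptide mass
    custom_subtractions: tuple[tuple[str, float], ...] = ()  # subtracted from precursor
    precursor_from_observed: bool = False
    max_definitions: int = 10_000


def remainder_mass_of(composition: str) -> float:
    """Mass of a remainder composition string; ``Y0`` means no glycan."""
    if composition.strip().lower() in ("y0", "0", "none", ""):
        return 0.0
    return composition_mass(parse_composition(composition))


def build_y_ion_definitions(
    psm: GlycoPSM,
    glycan_mass: float,
    settings: YnaughtSettings,
) -> list[YIonDefinition]:
    """Enumerate Y-ion targets: user choices x charge range x isotopes.

    Custom-addition masses combine with every selected remainder; custom
    subtractions with every selected neutral loss. The cartesian product is
    capped at ``settings.max_definitions``.
    """
    charges = settings.charge_range.resolve(psm.precursor_charge)
    definitions: list[YIonDefinition] = []

    remainder_deltas: list[tuple[str, float]] = [
        (comp, remainder_mass_of(comp)) for comp in settings.remainder_compositions
    ]
    remainder_deltas += [
        (f"{comp}+{label}", mass + extra)
        for comp, mass in list(remainder_deltas)
        for label, extra in settings.custom_additions
    ]

    loss_deltas: list[tuple[str, float]] = [
        (f"-{comp}", remainder_mass_of(comp)) for comp in settings.neutral_loss_compositions
    ]
    loss_deltas += [
        (f"{label0}-{label}", mass + extra)
        for label0, mass in list(loss_deltas)
        for label, extra in settings.custom_subtractions
    ]

    for label, delta in remainder_deltas:
        for z in charges:
            for k in settings.isotopes:
                definitions.append(
                    YIonDefinition(YIonMode.REMAINDER, delta, z, k, label)
                )
    for label, delta in loss_deltas:
        budget = glycan_mass + sum(m for _, m in settings.custom_subtractions)
        if delta > budget + 1e-6:
            raise ValueError(
                f"neutral loss {label!r} ({delta:.4f} Da) exceeds the glycan "
                f"mass budget"
            )
        for z in charges:
            for k in settings.isotopes:
                definitions.append(
                    YIonDefinition(YIonMode.NEUTRAL_LOSS, delta, z, k, label)
                )
    if len(definitions) > settings.max_definitions:
        logger.warning(
            "Y-ion definition count %d capped at %d",
            len(definitions), settings.max_definitions,
        )
        definitions = definitions[: settings.max_definitions]
    return definitions


@dataclass(frozen=True)
class YIonRow:
    """One Y-ion extraction result row."""

    scan_number: int
    label: str
    mode: YIonMode
    charge: int
    isotope: int
    theoretical_mz: float
    match: IonMatch | None

    @property
    def column(self) -> str:
        """Stable output-column key, e.g. ``HexNAc1_z2_M+1``."""
        iso = f"_M+{self.isotope}" if self.isotope else ""
        return f"{self.label}_z{self.charge}{iso}"


def y_ion_theoretical_mz(
    definition: YIonDefinition, peptide_mass: float, precursor_neutral: float
) -> float:
    if definition.mode is YIonMode.REMAINDER:
        return y_ion_mz_remainder(
            peptide_mass, definition.delta_mass, definition.charge, definition.isotope
        )
    return y_ion_mz_neutral_loss(
        precursor_neutral, definition.delta_mass, definition.charge, definition.isotope
    )


def extract_y_ions(
    spectrum: SpectrumRecord,
    psm: GlycoPSM,
    glycans: Mapping[str, float],
    settings: ExtractionSettings = ExtractionSettings(),
    y_settings: YnaughtSettings = YnaughtSettings(),
) -> list[YIonRow]:
    """Match every enumerated Y-ion target against the PSM's spectrum.

    Matching reuses the oxonium-extraction matcher, so the tolerance and
    S/N-or-intensity threshold semantics are identical. Rows are returned
    for matched targets only.
    """
    if spectrum.scan_number != psm.scan_number:
        raise ValueError(
            f"spectrum scan {spectrum.scan_number} does not match PSM scan "
            f"{psm.scan_number}"
        )
    glycan_mass = lookup_glycan(glycans, psm.glycan_name)
    peptide_mass = peptide_backbone_mass(psm.peptide_sequence, psm.modifications)
    if y_settings.precursor_from_observed and psm.precursor_mz is not None:
        precursor_neutral = (
            psm.precursor_mz * psm.precursor_charge
            - psm.precursor_charge * PROTON_MASS
        )
    else:
        precursor_neutral = peptide_mass + glycan_mass

    ranks = rank_peaks(spectrum)
    qualifying = _qualifying(spectrum, settings)
    rows: list[YIonRow] = []
    for definition in build_y_ion_definitions(psm, glycan_mass, y_settings):
        theo = y_ion_theoretical_mz(definition, peptide_mass, precursor_neutral)
        probe = IonDefinition(name=definition.label, explicit_mz=theo, group="custom")
        match = match_ion(spectrum, probe, settings, ranks=ranks, qualifying=qualifying)
        if match is not None:
            rows.append(
                YIonRow(
                    scan_number=spectrum.scan_number,
                    label=definition.label,
                    mode=definition.mode,
                    charge=definition.charge,
                    isotope=definition.isotope,
                    theoretical_mz=theo,
                    match=match,
                )
            )
    return rows
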
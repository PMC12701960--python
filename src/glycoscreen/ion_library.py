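"""Monoisotopic mass arithmetic and the diagnostic-ion catalog.

All oxonium-ion m/z values are derived from a small table of monosaccharide
*residue* masses (the dehydrated, in-chain form) plus elemental constants.
A singly protonated oxonium ion of composition ``{Hex: 1, HexNAc: 1}`` has

    m/z = m(Hex residue) + m(HexNAc residue) + m(proton)

optionally shifted by neutral losses (e.g. ``H2O``) or adducts (e.g. ``CO``
for a formyl adduct) given as elemental formulas.

The built-in catalog ships two selections: ``"common"`` — the 17 ions used
when only widely shared diagnostic ions are wanted — and ``"all"``, 50+ ions
spanning HexNAc/Hex fragment series, sialic-acid ions (NeuAc/NeuGc, with
water losses and acetyl variants), fucosylated and phosphorylated species,
and larger oligosaccharide B-ions.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

# --- elemental constants (monoisotopic, Da) ---------------------------------

PROTON_MASS = 1.007276466
WATER_MASS = 18.010564684
ISOTOPE_SPACING = 1.0033548378  # 13C - 12C

_ELEMENTS: Mapping[str, float] = MappingProxyType(
    {
        "H": 1.0078250319,
        "C": 12.0,
        "N": 14.0030740052,
        "O": 15.9949146221,
        "P": 30.97376151,
        "S": 31.97207069,
        "Na": 22.98976928,
        "K": 38.96370649,
    }
)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def formula_mass(formula: str) -> float:
    """Monoisotopic mass of an elemental formula such as ``"C2H4O2"``.

    Raises
    ------
    ValueError
        If the formula contains an unknown element symbol or stray
        characters.
    """
    if not formula or not formula.strip():
        raise ValueError("empty elemental formula")
    formula = formula.strip()
    mass = 0.0
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(
                f"unparsable formula {formula!r} at {formula[pos:]!r}"
            )
        if not match.group(0):
            break
        symbol, count = match.group(1), match.group(2)
        if symbol not in _ELEMENTS:
            raise ValueError(f"unknown element {symbol!r} in formula {formula!r}")
        mass += _ELEMENTS[symbol] * (int(count) if count else 1)
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula):
        raise ValueError(f"unparsable formula {formula!r} at {formula[pos:]!r}")
    return mass


# --- monosaccharide residue table -------------------------------------------

#: Residue (in-chain, dehydrated) monoisotopic masses, Da. Immutable.
MONOSACCHARIDES: Mapping[str, float] = MappingProxyType(
    {
        "Hex": formula_mass("C6H10O5"),        # 162.05282
        "HexNAc": formula_mass("C8H13NO5"),    # 203.07937
        "dHex": formula_mass("C6H10O4"),       # 146.05791
        "NeuAc": formula_mass("C11H17NO8"),    # 291.09542
        "NeuGc": formula_mass("C11H17NO9"),    # 307.09033
        "Pent": formula_mass("C5H8O4"),        # 132.04226
        "HexA": formula_mass("C6H8O6"),        # 176.03209
        "Phospho": formula_mass("HPO3"),       # 79.96633
        "Sulfo": formula_mass("SO3"),          # 79.95682
        "Acetyl": formula_mass("C2H2O"),       # 42.01057
    }
)


def residue_mass(name: str) -> float:
    """Residue monoisotopic mass for a monosaccharide (or modifier) name."""
    try:
        return MONOSACCHARIDES[name]
    except KeyError:
        raise ValueError(
            f"unknown residue {name!r}; known residues: "
            f"{', '.join(sorted(MONOSACCHARIDES))}"
        ) from None


_COMPOSITION_TOKEN = re.compile(r"([A-Za-z]+)(\d*)")


def parse_composition(text: str) -> dict[str, int]:
    """Parse ``"Hex2HexNAc1"`` / ``"Hex(2)HexNAc(1)"`` into a residue multiset."""
    cleaned = text.replace("(", "").replace(")", "").replace(" ", "")
    if not cleaned:
        raise ValueError("empty composition string")
    out: dict[str, int] = {}
    pos = 0
    for match in _COMPOSITION_TOKEN.finditer(cleaned):
        if match.start() != pos or not match.group(0):
            break
        name, count = match.group(1), match.group(2)
        if name not in MONOSACCHARIDES:
            raise ValueError(
                f"unknown residue {name!r} in composition {text!r}"
            )
        out[name] = out.get(name, 0) + (int(count) if count else 1)
        pos = match.end()
    if pos != len(cleaned):
        raise ValueError(f"unparsable composition {text!r} at {cleaned[pos:]!r}")
    return out


def composition_mass(composition: Mapping[str, int]) -> float:
    """Neutral residue-mass sum of a monosaccharide multiset."""
    return sum(residue_mass(name) * n for name, n in composition.items())


def oxonium_mz(
    composition: Mapping[str, int] | None = None,
    losses: Sequence[str] = (),
    adducts: Sequence[str] = (),
) -> float:
    """m/z of a singly protonated oxonium ion.

    Parameters
    ----------
    composition
        Residue multiset, e.g. ``{"Hex": 1, "HexNAc": 1}``.
    losses
        Elemental formulas subtracted as neutral losses (e.g. ``["H2O"]``).
    adducts
        Elemental formulas added (e.g. ``["CO"]`` for formylation).

    Returns
    -------
    float
        Sum of residue masses minus losses plus adducts, plus one proton.
    """
    composition = composition or {}
    if not composition and not adducts:
        raise ValueError(
            "oxonium ion requires a non-empty composition or at least one adduct"
        )
    mz = composition_mass(composition) + PROTON_MASS
    for loss in losses:
        mz -= formula_mass(loss)
    for adduct in adducts:
        mz += formula_mass(adduct)
    return mz


# --- ion definitions ---------------------------------------------------------

ION_GROUPS = ("HexNAc-derived", "Hex-derived", "sialic-acid", "oligosaccharide", "phospho", "custom")


@dataclass(frozen=True)
class IonDefinition:
    """One diagnostic ion: either a residue composition (± neutral losses /
    adducts) or an explicit m/z.

    ``explicit_mz`` overrides the composition when both are present; exactly
    one of the two routes must resolve an m/z greater than the proton mass.
    """

    name: str
    composition: tuple[tuple[str, int], ...] = ()
    losses: tuple[str, ...] = ()
    adducts: tuple[str, ...] = ()
    explicit_mz: float | None = None
    group: str = "custom"

    def __post_init__(self) -> None:
        if self.group not in ION_GROUPS:
            raise ValueError(f"unknown ion group {self.group!r}")
        mz = self.mz  # resolves or raises
        if mz <= PROTON_MASS:
            raise ValueError(
                f"ion {self.name!r} resolves to m/z {mz:.5f} <= proton mass"
            )

    @property
    def mz(self) -> float:
        """Resolved theoretical m/z (singly protonated)."""
        if self.explicit_mz is not None:
            return self.explicit_mz
        return oxonium_mz(dict(self.composition), self.losses, self.adducts)

    @property
    def composition_dict(self) -> dict[str, int]:
        return dict(self.composition)


@dataclass(frozen=True)
class IonSelection:
    """An ordered, name-unique set of ions; order drives output column order."""

    ions: tuple[IonDefinition, ...]
    label: str = "mixed"  # common | all | custom | mixed

    def __post_init__(self) -> None:
        names = [ion.name for ion in self.ions]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate ion names in selection: {sorted(dupes)}")
        mzs: dict[float, str] = {}
        for ion in self.ions:
            key = round(ion.mz, 4)
            if key in mzs:
                logger.info(
                    "ions %s and %s share m/z %.4f (isobaric entries allowed)",
                    mzs[key], ion.name, key,
                )
            else:
                mzs[key] = ion.name

    def __len__(self) -> int:
        return len(self.ions)

    def __iter__(self):
        return iter(self.ions)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(ion.name for ion in self.ions)

    def merged_with(self, other: "IonSelection") -> "IonSelection":
        """Union preserving this selection's order first; duplicate names in
        ``other`` are dropped with a log message."""
        seen = set(self.names)
        extra = []
        for ion in other.ions:
            if ion.name in seen:
                logger.warning("dropping duplicate ion %r during merge", ion.name)
            else:
                extra.append(ion)
                seen.add(ion.name)
        label = self.label if self.label == other.label else "mixed"
        return IonSelection(self.ions + tuple(extra), label=label)


def _ion(
    name: str,
    composition: Mapping[str, int],
    group: str,
    losses: Sequence[str] = (),
    adducts: Sequence[str] = (),
) -> IonDefinition:
    return IonDefinition(
        name=name,
        composition=tuple(sorted(composition.items())),
        losses=tuple(losses),
        adducts=tuple(adducts),
        group=group,
    )


# The 17-ion "common" selection: HexNAc fragment ladder, Hex, the four
# sialic-acid monosaccharide ions (± water), and the most widely used
# oligosaccharide B-ions.
_COMMON_IONS: tuple[IonDefinition, ...] = (
    _ion("HexNAc-CH6O3", {"HexNAc": 1}, "HexNAc-derived", losses=["CH6O3"]),   # 138.055
    _ion("HexNAc-C2H4O2", {"HexNAc": 1}, "HexNAc-derived", losses=["C2H4O2"]),  # 144.066
    _ion("Hex", {"Hex": 1}, "Hex-derived"),                                     # 163.060
    _ion("HexNAc-2H2O", {"HexNAc": 1}, "HexNAc-derived", losses=["H2O", "H2O"]),  # 168.066
    _ion("HexNAc-H2O", {"HexNAc": 1}, "HexNAc-derived", losses=["H2O"]),        # 186.076
    _ion("HexNAc", {"HexNAc": 1}, "HexNAc-derived"),                            # 204.087
    _ion("NeuAc-H2O", {"NeuAc": 1}, "sialic-acid", losses=["H2O"]),             # 274.092
    _ion("NeuGc-H2O", {"NeuGc": 1}, "sialic-acid", losses=["H2O"]),             # 290.087
    _ion("NeuAc", {"NeuAc": 1}, "sialic-acid"),                                 # 292.103
    _ion("NeuGc", {"NeuGc": 1}, "sialic-acid"),                                 # 308.098
    _ion("Hex-HexNAc", {"Hex": 1, "HexNAc": 1}, "oligosaccharide"),             # 366.140
    _ion("NeuAc-Hex", {"NeuAc": 1, "Hex": 1}, "sialic-acid"),                   # 454.156
    _ion("NeuAc-HexNAc", {"NeuAc": 1, "HexNAc": 1}, "sialic-acid"),             # 495.182
    _ion("Hex-HexNAc-dHex", {"Hex": 1, "HexNAc": 1, "dHex": 1}, "oligosaccharide"),  # 512.197
    _ion("Hex2-HexNAc", {"Hex": 2, "HexNAc": 1}, "oligosaccharide"),            # 528.192
    _ion("NeuAc-Hex-HexNAc", {"NeuAc": 1, "Hex": 1, "HexNAc": 1}, "oligosaccharide"),  # 657.235
    _ion("NeuGc-Hex-HexNAc", {"NeuGc": 1, "Hex": 1, "HexNAc": 1}, "oligosaccharide"),  # 673.230
)

_EXTRA_IONS: tuple[IonDefinition, ...] = (
    # HexNAc fragment ladder extensions
    _ion("HexNAc-C2H6O3", {"HexNAc": 1}, "HexNAc-derived", losses=["C2H6O3"]),  # 126.055
    _ion("HexNAc-dHex", {"HexNAc": 1, "dHex": 1}, "oligosaccharide"),           # 350.145
    _ion("HexNAc2", {"HexNAc": 2}, "oligosaccharide"),                          # 407.166
    _ion("HexNAc2-dHex", {"HexNAc": 2, "dHex": 1}, "oligosaccharide"),          # 553.224
    # Hex series
    _ion("Hex-2H2O", {"Hex": 1}, "Hex-derived", losses=["H2O", "H2O"]),         # 127.039
    _ion("Hex-H2O", {"Hex": 1}, "Hex-derived", losses=["H2O"]),                 # 145.050
    _ion("Hex2", {"Hex": 2}, "Hex-derived"),                                    # 325.113
    _ion("Hex3", {"Hex": 3}, "Hex-derived"),                                    # 487.166
    _ion("Hex4", {"Hex": 4}, "Hex-derived"),                                    # 649.218
    # dHex (fucose)
    _ion("dHex", {"dHex": 1}, "Hex-derived"),                                   # 147.065
    _ion("dHex-H2O", {"dHex": 1}, "Hex-derived", losses=["H2O"]),               # 129.055
    # sialic-acid extensions
    _ion("NeuAc-2H2O", {"NeuAc": 1}, "sialic-acid", losses=["H2O", "H2O"]),     # 256.082
    _ion("NeuAc[Ac]-H2O", {"NeuAc": 1, "Acetyl": 1}, "sialic-acid", losses=["H2O"]),  # 316.103
    _ion("NeuAc[Ac]", {"NeuAc": 1, "Acetyl": 1}, "sialic-acid"),                # 334.113
    _ion("NeuGc[Ac]-H2O", {"NeuGc": 1, "Acetyl": 1}, "sialic-acid", losses=["H2O"]),  # 332.098
    _ion("NeuGc[Ac]", {"NeuGc": 1, "Acetyl": 1}, "sialic-acid"),                # 350.108
    _ion("NeuAc2", {"NeuAc": 2}, "sialic-acid"),                                # 583.198
    _ion("NeuGc-Hex", {"NeuGc": 1, "Hex": 1}, "sialic-acid"),                   # 470.150
    _ion("NeuGc-HexNAc", {"NeuGc": 1, "HexNAc": 1}, "sialic-acid"),             # 511.177
    _ion("NeuAc-Hex2", {"NeuAc": 1, "Hex": 2}, "sialic-acid"),                  # 616.208
    _ion("NeuGc-Hex2", {"NeuGc": 1, "Hex": 2}, "sialic-acid"),                  # 632.203
    # larger oligosaccharide B-ions
    _ion("Hex-HexNAc2", {"Hex": 1, "HexNAc": 2}, "oligosaccharide"),            # 569.219
    _ion("Hex2-HexNAc-dHex", {"Hex": 2, "HexNAc": 1, "dHex": 1}, "oligosaccharide"),  # 674.250
    _ion("Hex3-HexNAc", {"Hex": 3, "HexNAc": 1}, "oligosaccharide"),            # 690.245
    _ion("Hex-HexNAc2-dHex", {"Hex": 1, "HexNAc": 2, "dHex": 1}, "oligosaccharide"),  # 715.277
    _ion("Hex2-HexNAc2", {"Hex": 2, "HexNAc": 2}, "oligosaccharide"),           # 731.272
    _ion("NeuAc-Hex-HexNAc-dHex", {"NeuAc": 1, "Hex": 1, "HexNAc": 1, "dHex": 1}, "oligosaccharide"),  # 803.292
    _ion("Hex2-HexNAc2-dHex", {"Hex": 2, "HexNAc": 2, "dHex": 1}, "oligosaccharide"),  # 877.330
    _ion("Hex3-HexNAc2", {"Hex": 3, "HexNAc": 2}, "oligosaccharide"),           # 893.325
    _ion("NeuAc2-Hex-HexNAc", {"NeuAc": 2, "Hex": 1, "HexNAc": 1}, "oligosaccharide"),  # 948.330
    # m/z 964.33: reproducible as mixed NeuAc/NeuGc sialylation
    _ion("NeuAc-NeuGc-Hex-HexNAc", {"NeuAc": 1, "NeuGc": 1, "Hex": 1, "HexNAc": 1}, "oligosaccharide"),  # 964.325
    _ion("NeuAc2-Hex2-HexNAc2", {"NeuAc": 2, "Hex": 2, "HexNAc": 2}, "oligosaccharide"),
    # phosphorylated (mannose-6-phosphate) series
    _ion("Hex-Phospho", {"Hex": 1, "Phospho": 1}, "phospho"),                   # 243.026
    _ion("Hex2-Phospho", {"Hex": 2, "Phospho": 1}, "phospho"),                  # 405.079
    _ion("Hex-Phospho-H2O", {"Hex": 1, "Phospho": 1}, "phospho", losses=["H2O"]),  # 225.016
    _ion("Hex3-Phospho", {"Hex": 3, "Phospho": 1}, "phospho"),                  # 567.132
    _ion("HexNAc-Phospho", {"HexNAc": 1, "Phospho": 1}, "phospho"),             # 284.053
    # sulfated
    _ion("HexNAc-Sulfo", {"HexNAc": 1, "Sulfo": 1}, "phospho"),                 # 284.043
    _ion("Hex-HexNAc-Sulfo", {"Hex": 1, "HexNAc": 1, "Sulfo": 1}, "phospho"),   # 446.096
)


def builtin_catalog(selection: str = "common") -> IonSelection:
    """The built-in diagnostic-ion catalog.

    ``"common"`` returns the 17-ion default selection; ``"all"`` the full
    50+ ion catalog (common ions first, in stable order).
    """
    if selection == "common":
        return IonSelection(_COMMON_IONS, label="common")
    if selection == "all":
        return IonSelection(_COMMON_IONS + _EXTRA_IONS, label="all")
    raise ValueError(f"unknown catalog selection {selection!r}; use 'common' or 'all'")


# --- custom ion tables -------------------------------------------------------

def _split_formulas(cell: str) -> tuple[str, ...]:
    return tuple(tok.strip() for tok in re.split(r"[;,+]", cell) if tok.strip())


def parse_custom_ions(path: str | Path) -> IonSelection:
    """Parse a custom-ion TSV into an :class:`IonSelection` labeled ``custom``.

    The file is UTF-8, tab-delimited, header required. Recognized columns:
    ``name`` plus either ``mz`` (explicit m/z) or ``composition`` (residue
    multiset string like ``Hex1HexNAc1``) with optional ``adducts`` /
    ``losses`` (``;``-separated elemental formulas).
    """
    path = Path(path)
    ions: list[IonDefinition] = []
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("custom ion file %s is empty; returning empty selection", path)
            return IonSelection((), label="custom")
        fields = {f.strip().lower(): f for f in reader.fieldnames if f}
        if "name" not in fields or ("mz" not in fields and "composition" not in fields):
            raise ValueError(
                f"{path}: header must contain 'name' and either 'mz' or 'composition' "
                f"(got {reader.fieldnames})"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                ions.append(_parse_custom_row(row, fields))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    if not ions:
        logger.warning("custom ion file %s has no data rows", path)
    return IonSelection(tuple(ions), label="custom")


def _parse_custom_row(row: Mapping[str, str], fields: Mapping[str, str]) -> IonDefinition:
    def get(key: str) -> str:
        col = fields.get(key)
        return (row.get(col) or "").strip() if col else ""

    name = get("name")
    if not name:
        raise ValueError("missing ion name")
    mz_text = get("mz")
    comp_text = get("composition")
    losses = _split_formulas(get("losses"))
    adducts = _split_formulas(get("adducts"))
    if mz_text:
        try:
            mz = float(mz_text)
        except ValueError:
            raise ValueError(f"malformed m/z {mz_text!r} for ion {name!r}") from None
        if mz <= PROTON_MASS:
            raise ValueError(f"m/z {mz} for ion {name!r} is <= proton mass")
        return IonDefinition(name=name, explicit_mz=mz, group="custom")
    if not comp_text:
        raise ValueError(f"ion {name!r} has neither m/z nor composition")
    composition = parse_composition(comp_text)
    return IonDefinition(
        name=name,
        composition=tuple(sorted(composition.items())),
        losses=losses,
        adducts=adducts,
        group="custom",
    )
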
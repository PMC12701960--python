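"""Streaming mzML reader for centroided MS/MS scans.

Reads mzML 1.1 (indexed or plain) with the standard library XML machinery,
yielding one :class:`SpectrumRecord` per scan at the requested MS levels.
Iteration is single-pass and memory-bounded: only the current ``<spectrum>``
element is resident.

zlib-compressed binary arrays are accepted; gzip-packaged files are rejected
with a clear message. Profile-mode MS2 spectra raise an error instructing
the user to centroid first (e.g. the MSConvert peak-picking filter).
"""

from __future__ import annotations

import base64
import logging
import re
import zlib
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

logger = logging.getLogger(__name__)


class ActivationType(Enum):
    """Dissociation family of an MS/MS scan.

    Any ETD-centric type (ETD, EThcD, AI-ETD, ETcaD — i.e. ETD with any
    supplemental activation) maps to ``ETD_FAMILY``.
    """

    HCD = "HCD"
    ETD_FAMILY = "ETD"
    UVPD = "UVPD"
    OTHER = "Other"


@dataclass
class SpectrumRecord:
    """One centroided MS/MS scan."""

    scan_number: int
    ms_level: int
    activation: ActivationType
    tic: float
    mz: np.ndarray
    intensity: np.ndarray
    noise: np.ndarray | None = None
    precursor_mz: float | None = None
    precursor_charge: int | None = None
    retention_time: float | None = None  # minutes

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.noise is not None:
            self.noise = np.asarray(self.noise, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays must be parallel")
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
            if self.noise is not None:
                self.noise = self.noise[order]
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_number}: negative intensities")

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)


# --- activation mapping ------------------------------------------------------

_ETD_TERMS = {
    "MS:1000598",
    "electron transfer dissociation",
}
_HCD_TERMS = {
    "MS:1000422",
    "beam-type collision-induced dissociation",
    "HCD",
}
_UVPD_TERMS = {
    "MS:1003246",
    "ultraviolet photodissociation",
}


def detect_activation(terms: Iterable[str]) -> ActivationType:
    """Map activation CV terms (accessions and/or names) to a family.

    Any ETD term wins even when combined with supplemental collisional
    activation (EThcD); unknown terms map to ``OTHER``.
    """
    terms = set(terms)
    if terms & _ETD_TERMS:
        return ActivationType.ETD_FAMILY
    if terms & _UVPD_TERMS:
        return ActivationType.UVPD
    if terms & _HCD_TERMS:
        return ActivationType.HCD
    return ActivationType.OTHER


_FILTER_ACTIVATION = (
    ("@etd", ActivationType.ETD_FAMILY),
    ("@uvpd", ActivationType.UVPD),
    ("@hcd", ActivationType.HCD),
)


def activation_from_filter_string(filter_string: str) -> ActivationType:
    """Fallback: parse a Thermo scan filter string (e.g. ``... @hcd28.00``)."""
    lowered = filter_string.lower()
    for token, activation in _FILTER_ACTIVATION:
        if token in lowered:
            return activation
    return ActivationType.OTHER


# --- binary array decoding ---------------------------------------------------

_DTYPE_ACCESSIONS = {
    "MS:1000523": np.float64,
    "MS:1000521": np.float32,
}


def _decode_binary(text: str, dtype: type, zlib_compressed: bool) -> np.ndarray:
    raw = base64.b64decode(text.strip()) if text.strip() else b""
    if not raw:
        return np.array([], dtype=np.float64)
    if zlib_compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(np.float64)


_SCAN_RE = re.compile(r"scan=(\d+)")


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


class MzmlFormatError(ValueError):
    """Raised for files glycoscreen cannot process."""


def _parse_spectrum_element(elem, index_fallback: int) -> dict:
    """Pull scan metadata and peak arrays out of one <spectrum> element."""
    info: dict = {
        "ms_level": None,
        "tic": None,
        "centroided": None,
        "rt": None,
        "precursor_mz": None,
        "precursor_charge": None,
        "activation_terms": set(),
        "filter_string": None,
        "arrays": {},
    }
    scan_id = elem.get("id", "")
    match = _SCAN_RE.search(scan_id)
    if match:
        info["scan_number"] = int(match.group(1))
    else:
        idx = elem.get("index")
        info["scan_number"] = (int(idx) + 1) if idx is not None else index_fallback + 1

    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            value = child.get("value", "")
            if acc == "MS:1000511":
                info["ms_level"] = int(value)
            elif acc == "MS:1000285":
                info["tic"] = float(value)
            elif acc == "MS:1000127":
                info["centroided"] = True
            elif acc == "MS:1000128":
                info["centroided"] = False
            elif acc == "MS:1000512":
                info["filter_string"] = value

    # context-sensitive blocks
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "scan":
            for cv in child:
                if _local(cv.tag) == "cvParam" and cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value", "nan"))
                    unit = (cv.get("unitName") or "").lower()
                    info["rt"] = rt / 60.0 if unit.startswith("second") else rt
        elif tag == "selectedIon":
            for cv in child:
                if _local(cv.tag) != "cvParam":
                    continue
                if cv.get("accession") == "MS:1000744":
                    info["precursor_mz"] = float(cv.get("value"))
                elif cv.get("accession") == "MS:1000041":
                    info["precursor_charge"] = int(cv.get("value"))
        elif tag == "activation":
            for cv in child:
                if _local(cv.tag) == "cvParam":
                    info["activation_terms"].add(cv.get("accession", ""))
                    info["activation_terms"].add(cv.get("name", ""))
        elif tag == "binaryDataArray":
            _parse_binary_array(child, info["arrays"])
    return info


def _parse_binary_array(elem, arrays: dict) -> None:
    dtype = np.float64
    compressed = False
    kind = None
    text = ""
    for child in elem:
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            name = (child.get("name") or "").lower()
            value = (child.get("value") or "").lower()
            if acc in _DTYPE_ACCESSIONS:
                dtype = _DTYPE_ACCESSIONS[acc]
            elif acc == "MS:1000574":
                compressed = True
            elif acc == "MS:1000514" or name == "m/z array":
                kind = "mz"
            elif acc == "MS:1000515" or name == "intensity array":
                kind = "intensity"
            elif "noise" in name or "noise" in value:
                kind = "noise"
        elif tag == "binary":
            text = child.text or ""
    if kind is not None:
        arrays[kind] = _decode_binary(text, dtype, compressed)


def _looks_profile(mz: np.ndarray) -> bool:
    """Heuristic centroid check: dense, regular spacing over many peaks."""
    if mz.size <= 500:
        return False
    spacing = np.diff(mz)
    return bool(np.median(spacing) < 0.005)


def read_spectra(
    path: str | Path,
    ms_levels: Iterable[int] = (2,),
) -> Iterator[SpectrumRecord]:
    """Stream :class:`SpectrumRecord` objects from an mzML file.

    Parameters
    ----------
    path
        mzML 1.1 file (plain or indexed; zlib-compressed peak arrays are
        accepted).
    ms_levels
        Only scans at these MS levels are yielded (default: MS2).

    Yields
    ------
    SpectrumRecord
        In file order. Scans whose intensities sum to zero are skipped with
        a warning. TIC comes from file metadata unless it disagrees with the
        intensity sum by more than 20%, in which case the sum is used.

    Raises
    ------
    MzmlFormatError
        For gzip-packaged input, profile-mode MS/MS scans, or unreadable
        files.
    """
    import xml.etree.ElementTree as ET

    path = Path(path)
    if not path.exists():
        raise MzmlFormatError(f"mzML file not found: {path}")
    with path.open("rb") as probe:
        if probe.read(2) == b"\x1f\x8b":
            raise MzmlFormatError(
                f"{path} is gzip-packaged; decompress it first (zlib-compressed "
                "peak arrays inside plain mzML are fine)"
            )

    ms_levels = frozenset(int(lvl) for lvl in ms_levels)
    index = -1
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _event, elem in context:
            if _local(elem.tag) != "spectrum":
                continue
            index += 1
            record = _record_from_element(elem, index, ms_levels, path)
            elem.clear()
            if record is not None:
                yield record
    except ET.ParseError as exc:
        raise MzmlFormatError(f"cannot parse mzML file {path}: {exc}") from exc


def _record_from_element(elem, index, ms_levels, path) -> SpectrumRecord | None:
    info = _parse_spectrum_element(elem, index)
    ms_level = info["ms_level"] or 1
    if ms_level not in ms_levels:
        return None

    if info["centroided"] is False and ms_level >= 2:
        raise MzmlFormatError(
            f"{path} scan {info['scan_number']}: MS/MS scans must contain only "
            "centroided peaks; convert with peak picking (e.g. MSConvert, "
            "filter 'peakPicking true 2-')"
        )
    mz = info["arrays"].get("mz", np.array([]))
    intensity = info["arrays"].get("intensity", np.array([]))
    noise = info["arrays"].get("noise")
    if mz.size != intensity.size:
        raise MzmlFormatError(
            f"{path} scan {info['scan_number']}: m/z and intensity array "
            f"lengths differ ({mz.size} vs {intensity.size})"
        )
    if intensity.sum() <= 0:
        logger.warning(
            "scan %s in %s has no signal; skipped", info["scan_number"], path.name
        )
        return None
    if ms_level >= 2 and _looks_profile(mz):
        raise MzmlFormatError(
            f"{path} scan {info['scan_number']}: peak spacing suggests profile "
            "mode; MS/MS scans must contain only centroided peaks"
        )

    activation = detect_activation(info["activation_terms"])
    if activation is ActivationType.OTHER and info["filter_string"]:
        activation = activation_from_filter_string(info["filter_string"])

    total = float(intensity.sum())
    tic = info["tic"]
    if tic is None or tic <= 0:
        tic = total
    elif abs(tic - total) > 0.2 * max(tic, total):
        logger.warning(
            "scan %s: file TIC %.4g disagrees with intensity sum %.4g by >20%%; "
            "using the sum",
            info["scan_number"], tic, total,
        )
        tic = total

    return SpectrumRecord(
        scan_number=info["scan_number"],
        ms_level=ms_level,
        activation=activation,
        tic=tic,
        mz=mz,
        intensity=intensity,
        noise=noise if noise is not None and noise.size == mz.size else None,
        precursor_mz=info["precursor_mz"],
        precursor_charge=info["precursor_charge"],
        retention_time=info["rt"],
    )


def resolve_input_paths(path: str | Path) -> list[Path]:
    """Resolve a single mzML file or a batch folder into a file list."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".mzml")
        if not files:
            raise MzmlFormatError(f"no .mzML files found in folder {path}")
        return files
    if not path.exists():
        raise MzmlFormatError(f"input path does not exist: {path}")
    return [path]
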
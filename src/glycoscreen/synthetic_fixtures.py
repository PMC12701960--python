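"""Seeded synthetic fixtures: mzML with planted diagnostic ions, plus PSM and
glycan tables for Y-ion runs.

Planted ions are placed at their theoretical m/z with a drawn mass error of
at most 5 ppm; decoy peaks are kept at least 30 ppm away from every catalog
ion (and every planted target), so at the 15 ppm default tolerance planted
recall is exactly 100% and the decoy false-match rate is exactly 0 — the
recall/specificity assertions in the tests are deterministic, not
probabilistic.

Intensities are constructed so the planted ions occupy the top intensity
ranks (optionally below a block of high decoys) and the planted share of the
TIC equals the requested fraction exactly.
"""

from __future__ import annotations

import base64
import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from glycoscreen.ion_library import PROTON_MASS, builtin_catalog
from glycoscreen.spectra_io import ActivationType, SpectrumRecord
from glycoscreen.ynaught import (
    YnaughtSettings,
    peptide_backbone_mass,
    remainder_mass_of,
    y_ion_mz_remainder,
)

#: Exclusion zone (ppm) around catalog/planted targets for decoy placement.
DECOY_EXCLUSION_PPM = 30.0
#: Largest mass error drawn for planted peaks.
PLANT_ERROR_PPM = 5.0


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a batch of synthetic MS/MS scans.

    ``activations`` is cycled across scans. ``planted_ions`` (catalog ion
    names from the ``"all"`` selection, or custom names in
    ``extra_targets``) are planted in every scan; an empty tuple gives a
    pure-decoy null fixture. ``n_decoys_above`` decoys are placed *above*
    the planted intensities, pushing planted peak depths down by that much.
    """

    n_scans: int = 1
    activations: tuple[ActivationType, ...] = (ActivationType.HCD,)
    planted_ions: tuple[str, ...] = ()
    target_fraction: float = 0.30
    n_decoys: int = 100
    n_decoys_above: int = 0
    decoy_mz_range: tuple[float, float] = (110.0, 2000.0)
    intensity_jitter: float = 0.0  # uniform +/- fraction on decoy draw weights
    seed: int = 0
    with_noise_array: bool = False
    extra_targets: tuple[tuple[str, float], ...] = ()  # (name, m/z) beyond catalog

    def __post_init__(self) -> None:
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")
        if not 0.0 <= self.target_fraction < 1.0:
            raise ValueError("target_fraction must be in [0, 1)")
        if self.planted_ions and self.target_fraction <= 0.0:
            raise ValueError("planted ions require a positive target fraction")
        if self.n_decoys < 1:
            raise ValueError("at least one decoy peak is required")
        lo, hi = self.decoy_mz_range
        if not lo < hi:
            raise ValueError("decoy m/z range must be increasing")
        _validate_feasible(self)


def _planted_intensities(k: int) -> np.ndarray:
    # strictly decreasing so target ranks are unambiguous
    return 1000.0 * np.power(0.95, np.arange(k))


def _validate_feasible(spec: FixtureSpec) -> None:
    k = len(spec.planted_ions)
    if k == 0:
        return
    planted = _planted_intensities(k)
    above = 1100.0 + 10.0 * np.arange(spec.n_decoys_above)[::-1] if spec.n_decoys_above else np.array([])
    s = planted.sum()
    budget = s * (1.0 / spec.target_fraction - 1.0) - above.sum()
    if budget <= 0:
        raise ValueError(
            f"infeasible fixture: fraction {spec.target_fraction} leaves no "
            f"decoy intensity budget below the planted peaks"
        )
    # each decoy must stay strictly below the weakest planted peak
    if budget / spec.n_decoys >= planted.min() * 0.9:
        raise ValueError(
            f"infeasible fixture: fraction {spec.target_fraction} with "
            f"{spec.n_decoys} decoys forces decoy peaks above planted peaks"
        )


def _target_mz_map(spec: FixtureSpec) -> dict[str, float]:
    catalog = {ion.name: ion.mz for ion in builtin_catalog("all")}
    catalog.update(dict(spec.extra_targets))
    return catalog


def generate_spectrum(spec: FixtureSpec, scan_index: int) -> SpectrumRecord:
    """Build one synthetic scan. Deterministic in (spec.seed, scan_index)."""
    rng = np.random.default_rng([spec.seed, scan_index])
    targets = _target_mz_map(spec)
    try:
        planted_mz_theo = np.array([targets[name] for name in spec.planted_ions])
    except KeyError as exc:
        raise ValueError(f"planted ion {exc.args[0]!r} is not a known target") from None

    k = planted_mz_theo.size
    errors = rng.uniform(-PLANT_ERROR_PPM, PLANT_ERROR_PPM, size=k) * 1e-6
    planted_mz = planted_mz_theo * (1.0 + errors)
    planted_int = _planted_intensities(k)

    above_int = (
        1100.0 + 10.0 * np.arange(spec.n_decoys_above)[::-1]
        if spec.n_decoys_above
        else np.array([])
    )

    # decoy intensity budget keeps the planted TIC share exact
    if k:
        s = planted_int.sum()
        budget = s * (1.0 / spec.target_fraction - 1.0) - above_int.sum()
    else:
        budget = 1000.0 * spec.n_decoys
    weights = rng.uniform(0.5, 1.5, size=spec.n_decoys)
    if spec.intensity_jitter:
        weights *= 1.0 + rng.uniform(
            -spec.intensity_jitter, spec.intensity_jitter, size=spec.n_decoys
        )
    decoy_int = weights / weights.sum() * budget
    if k and decoy_int.max() >= planted_int.min():
        raise ValueError("infeasible fixture realization: decoy exceeds planted peak")

    exclusion = np.array(sorted(targets.values()))
    decoy_mz = _draw_decoy_mz(rng, spec.decoy_mz_range, exclusion,
                              spec.n_decoys + spec.n_decoys_above)
    above_mz = decoy_mz[spec.n_decoys:]
    decoy_mz = decoy_mz[: spec.n_decoys]

    mz = np.concatenate([planted_mz, decoy_mz, above_mz])
    intensity = np.concatenate([planted_int, decoy_int, above_int])
    order = np.argsort(mz, kind="stable")

    noise = None
    if spec.with_noise_array:
        noise = np.full(mz.size, 1.0)

    activation = spec.activations[scan_index % len(spec.activations)]
    return SpectrumRecord(
        scan_number=scan_index + 1,
        ms_level=2,
        activation=activation,
        tic=float(intensity.sum()),
        mz=mz[order],
        intensity=intensity[order],
        noise=noise[order] if noise is not None else None,
        precursor_mz=1000.0,
        precursor_charge=2,
        retention_time=0.5 + scan_index * 0.01,
    )


def _draw_decoy_mz(
    rng: np.random.Generator,
    mz_range: tuple[float, float],
    exclusion_sorted: np.ndarray,
    n: int,
) -> np.ndarray:
    """Rejection-sample m/z values >= 30 ppm away from every excluded target."""
    out = np.empty(n)
    filled = 0
    for _attempt in range(200):
        draw = rng.uniform(mz_range[0], mz_range[1], size=max(4 * (n - filled), 16))
        idx = np.searchsorted(exclusion_sorted, draw)
        ok = np.ones(draw.size, dtype=bool)
        for side in (np.clip(idx - 1, 0, exclusion_sorted.size - 1),
                     np.clip(idx, 0, exclusion_sorted.size - 1)):
            nearest = exclusion_sorted[side]
            ok &= np.abs(draw - nearest) / nearest > DECOY_EXCLUSION_PPM * 1e-6
        accepted = draw[ok][: n - filled]
        out[filled:filled + accepted.size] = accepted
        filled += accepted.size
        if filled == n:
            return out
    raise RuntimeError("decoy rejection sampling failed to converge")


def generate_spectra(spec: FixtureSpec) -> list[SpectrumRecord]:
    """All scans of a fixture spec, deterministic per seed."""
    return [generate_spectrum(spec, i) for i in range(spec.n_scans)]


# --- mzML writing ------------------------------------------------------------

_ACTIVATION_CV = {
    ActivationType.HCD: ("MS:1000422", "beam-type collision-induced dissociation"),
    ActivationType.ETD_FAMILY: ("MS:1000598", "electron transfer dissociation"),
    ActivationType.UVPD: ("MS:1003246", "ultraviolet photodissociation"),
    ActivationType.OTHER: ("MS:1000133", "collision-induced dissociation"),
}


def _b64(values: np.ndarray) -> str:
    return base64.b64encode(
        np.asarray(values, dtype="<f8").tobytes()
    ).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    ET.SubElement(
        parent, "cvParam",
        {"cvRef": "MS", "accession": accession, "name": name, "value": value, **attrs},
    )


def _binary_array(parent, values: np.ndarray, kind: str) -> None:
    arr = ET.SubElement(parent, "binaryDataArray")
    _cv(arr, "MS:1000523", "64-bit float")
    _cv(arr, "MS:1000576", "no compression")
    if kind == "mz":
        _cv(arr, "MS:1000514", "m/z array", unitName="m/z")
    elif kind == "intensity":
        _cv(arr, "MS:1000515", "intensity array", unitName="number of detector counts")
    else:
        _cv(arr, "MS:1000786", "non-standard data array", value="sampled noise")
    ET.SubElement(arr, "binary").text = _b64(values)


def write_fixture_mzml(spectra: Sequence[SpectrumRecord], path: str | Path) -> Path:
    """Write scans as standards-conformant (minimal) mzML 1.1."""
    path = Path(path)
    root = ET.Element("mzML", {
        "xmlns": "http://psi.hupo.org/ms/mzml",
        "version": "1.1.0",
    })
    cv_list = ET.SubElement(root, "cvList", {"count": "1"})
    ET.SubElement(cv_list, "cv", {
        "id": "MS",
        "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    })
    run = ET.SubElement(root, "run", {"id": "synthetic"})
    spectrum_list = ET.SubElement(run, "spectrumList", {"count": str(len(spectra))})

    for index, record in enumerate(spectra):
        spectrum = ET.SubElement(spectrum_list, "spectrum", {
            "index": str(index),
            "id": f"controllerType=0 controllerNumber=1 scan={record.scan_number}",
            "defaultArrayLength": str(record.n_peaks),
        })
        _cv(spectrum, "MS:1000511", "ms level", str(record.ms_level))
        _cv(spectrum, "MS:1000127", "centroid spectrum")
        _cv(spectrum, "MS:1000285", "total ion current", repr(record.tic))

        scan_list = ET.SubElement(spectrum, "scanList", {"count": "1"})
        scan = ET.SubElement(scan_list, "scan")
        if record.retention_time is not None:
            _cv(scan, "MS:1000016", "scan start time",
                repr(record.retention_time), unitName="minute")

        if record.ms_level >= 2:
            precursor_list = ET.SubElement(spectrum, "precursorList", {"count": "1"})
            precursor = ET.SubElement(precursor_list, "precursor")
            si_list = ET.SubElement(precursor, "selectedIonList", {"count": "1"})
            si = ET.SubElement(si_list, "selectedIon")
            if record.precursor_mz is not None:
                _cv(si, "MS:1000744", "selected ion m/z", repr(record.precursor_mz))
            if record.precursor_charge is not None:
                _cv(si, "MS:1000041", "charge state", str(record.precursor_charge))
            activation = ET.SubElement(precursor, "activation")
            accession, name = _ACTIVATION_CV[record.activation]
            _cv(activation, accession, name)

        n_arrays = 3 if record.noise is not None else 2
        array_list = ET.SubElement(
            spectrum, "binaryDataArrayList", {"count": str(n_arrays)}
        )
        _binary_array(array_list, record.mz, "mz")
        _binary_array(array_list, record.intensity, "intensity")
        if record.noise is not None:
            _binary_array(array_list, record.noise, "noise")

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)
    return path


# --- glycopeptide (Ynaught) fixtures -----------------------------------------

@dataclass(frozen=True)
class PlantedYIon:
    """A Y-ion to plant: remainder composition string, charge and isotope."""

    composition: str  # "Y0", "HexNAc1", ...
    charge: int = 1
    isotope: int = 0


def generate_glycopeptide_fixture(
    peptide: str,
    glycan_name: str,
    glycan_composition: str,
    precursor_charge: int,
    planted_y: Sequence[PlantedYIon],
    out_dir: str | Path,
    seed: int = 0,
    n_decoys: int = 60,
    scan_number: int = 1,
) -> tuple[Path, Path, Path]:
    """Emit (mzML, PSM TSV, glycan TSV) with planted Y-ions.

    The glycan mass in the database is the composition mass, so the
    fixture's precursor neutral mass is exactly peptide + glycan and the
    planted m/z values flow through the same closed forms Ynaught uses.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    peptide_mass = peptide_backbone_mass(peptide)
    glycan_mass = remainder_mass_of(glycan_composition)
    precursor_mz = (
        peptide_mass + glycan_mass + precursor_charge * PROTON_MASS
    ) / precursor_charge

    planted_mz = np.array([
        y_ion_mz_remainder(peptide_mass, remainder_mass_of(p.composition),
                           p.charge, p.isotope)
        for p in planted_y
    ])
    planted_int = _planted_intensities(len(planted_y)) if planted_y else np.array([])

    # decoys avoid all plantable Y-ion positions (any default composition,
    # charge up to P, isotopes 0-2) so isotope/charge gating tests are exact
    exclusion = []
    for comp in set(list(YnaughtSettings().remainder_compositions)
                    + [p.composition for p in planted_y] + [glycan_composition]):
        mass = remainder_mass_of(comp)
        for z in range(1, precursor_charge + 1):
            for iso in (0, 1, 2):
                exclusion.append(y_ion_mz_remainder(peptide_mass, mass, z, iso))
    exclusion_sorted = np.array(sorted(exclusion))
    decoy_mz = _draw_decoy_mz(rng, (120.0, precursor_mz + 500.0),
                              exclusion_sorted, n_decoys)
    decoy_int = rng.uniform(10.0, 100.0, size=n_decoys)
    if planted_y:
        decoy_int = np.minimum(decoy_int, planted_int.min() * 0.5)

    mz = np.concatenate([planted_mz, decoy_mz])
    intensity = np.concatenate([planted_int, decoy_int])
    order = np.argsort(mz, kind="stable")
    record = SpectrumRecord(
        scan_number=scan_number,
        ms_level=2,
        activation=ActivationType.HCD,
        tic=float(intensity.sum()),
        mz=mz[order],
        intensity=intensity[order],
        precursor_mz=precursor_mz,
        precursor_charge=precursor_charge,
        retention_time=1.0,
    )
    mzml_path = write_fixture_mzml([record], out_dir / "glycopeptide.mzML")

    psm_path = out_dir / "psm.tsv"
    with psm_path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow([
            "Spectrum", "Peptide", "Charge", "Assigned Modifications",
            "Observed M/Z", "Total Glycan Composition",
        ])
        writer.writerow([
            f"synthetic.{scan_number:05d}.{scan_number:05d}.{precursor_charge}",
            peptide, precursor_charge, "", f"{precursor_mz:.6f}", glycan_name,
        ])

    glycan_path = out_dir / "glycans.tsv"
    with glycan_path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["glycan", "mass"])
        writer.writerow([glycan_name, f"{glycan_mass:.6f}"])

    return mzml_path, psm_path, glycan_path
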
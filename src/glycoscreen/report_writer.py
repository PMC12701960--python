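"""Tab-delimited result files.

Each run produces three files per input: a peak-depth table (rows = scans,
columns = ions, cells = intensity rank or blank), a signal table (same
shape, cells = intensity) and a per-scan summary. Output is byte-stable for
identical inputs: fixed column order (the ion selection order), fixed float
formats (fractions 4 decimals, m/z 5 decimals, intensities as 4-significant-
digit scientific notation).

File names: ``<stem>_OxoPeakDepth.txt``, ``<stem>_OxoSignal.txt``,
``<stem>_Summary.txt`` — and ``<stem>_YPeakDepth.txt`` /
``<stem>_YSignal.txt`` / ``<stem>_YSummary.txt`` for Ynaught runs.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

from glycoscreen.ion_library import IonSelection
from glycoscreen.oxonium_extraction import SpectrumOxoniumSummary
from glycoscreen.ynaught import YIonRow

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "ScanNumber",
    "MSLevel",
    "Activation",
    "RetentionTime",
    "TIC",
    "IonsMatched",
    "IonsMatchedInDepthWindow",
    "OxoniumTICFraction",
    "LikelyGlycoSpectrum",
)


def _fmt_intensity(value: float) -> str:
    return f"{value:.4g}"


def _fmt_fraction(value: float) -> str:
    return f"{value:.4f}"


def _resolve_collision(path: Path) -> Path:
    if not path.exists():
        return path
    stamped = path.with_name(f"{path.stem}_{int(time.time())}{path.suffix}")
    logger.warning("output %s exists; writing %s instead", path, stamped)
    return stamped


def write_bundle(
    summaries: Sequence[SpectrumOxoniumSummary],
    ions: IonSelection,
    out_dir: str | Path,
    file_stem: str,
) -> tuple[Path, Path, Path]:
    """Write the oxonium peak-depth, signal and summary tables.

    Returns the three paths in that order.
    """
    if len(ions) == 0:
        raise ValueError("cannot write outputs for an empty ion selection")
    if not summaries:
        raise ValueError("no spectrum summaries to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    depth_path = _resolve_collision(out_dir / f"{file_stem}_OxoPeakDepth.txt")
    signal_path = _resolve_collision(out_dir / f"{file_stem}_OxoSignal.txt")
    summary_path = _resolve_collision(out_dir / f"{file_stem}_Summary.txt")

    ion_names = list(ions.names)
    header = "ScanNumber\t" + "\t".join(ion_names) + "\n"

    with depth_path.open("w", encoding="utf-8", newline="\n") as depth_f, \
            signal_path.open("w", encoding="utf-8", newline="\n") as signal_f:
        depth_f.write(header)
        signal_f.write(header)
        for summary in summaries:
            by_name = {m.ion_name: m for m in summary.matches}
            depth_cells = [str(summary.scan_number)]
            signal_cells = [str(summary.scan_number)]
            for name in ion_names:
                match = by_name.get(name)
                depth_cells.append(str(match.peak_depth) if match else "")
                signal_cells.append(_fmt_intensity(match.intensity) if match else "")
            depth_f.write("\t".join(depth_cells) + "\n")
            signal_f.write("\t".join(signal_cells) + "\n")

    with summary_path.open("w", encoding="utf-8", newline="\n") as summary_f:
        summary_f.write("\t".join(SUMMARY_COLUMNS) + "\n")
        for summary in summaries:
            rt = "" if summary.retention_time is None else f"{summary.retention_time:.4f}"
            summary_f.write(
                "\t".join(
                    (
                        str(summary.scan_number),
                        str(summary.ms_level),
                        summary.activation.value,
                        rt,
                        _fmt_intensity(summary.tic),
                        str(summary.n_matched),
                        str(summary.n_matched_in_window),
                        _fmt_fraction(summary.oxonium_tic_fraction),
                        "TRUE" if summary.likely_glyco else "FALSE",
                    )
                )
                + "\n"
            )
    return depth_path, signal_path, summary_path


Y_SUMMARY_COLUMNS = (
    "ScanNumber",
    "Peptide",
    "Glycan",
    "PrecursorCharge",
    "YIonsMatched",
    "YIonTICFraction",
)


def write_y_bundle(
    rows_by_scan: Sequence[tuple[dict, Sequence[YIonRow]]],
    out_dir: str | Path,
    file_stem: str,
) -> tuple[Path, Path, Path]:
    """Write the Ynaught peak-depth, signal and summary tables.

    ``rows_by_scan`` pairs a per-scan info dict (keys ``scan_number``,
    ``peptide``, ``glycan``, ``charge``, ``tic``) with that scan's matched
    :class:`~glycoscreen.ynaught.YIonRow` list. Columns are the union of
    matched Y-ion column keys, in first-seen order.
    """
    if not rows_by_scan:
        raise ValueError("no Y-ion results to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    columns: list[str] = []
    for _info, rows in rows_by_scan:
        for row in rows:
            if row.column not in columns:
                columns.append(row.column)

    depth_path = _resolve_collision(out_dir / f"{file_stem}_YPeakDepth.txt")
    signal_path = _resolve_collision(out_dir / f"{file_stem}_YSignal.txt")
    summary_path = _resolve_collision(out_dir / f"{file_stem}_YSummary.txt")

    header = "ScanNumber\t" + "\t".join(columns) + "\n"
    with depth_path.open("w", encoding="utf-8", newline="\n") as depth_f, \
            signal_path.open("w", encoding="utf-8", newline="\n") as signal_f:
        depth_f.write(header)
        signal_f.write(header)
        for info, rows in rows_by_scan:
            by_col = {row.column: row for row in rows}
            depth_cells = [str(info["scan_number"])]
            signal_cells = [str(info["scan_number"])]
            for col in columns:
                row = by_col.get(col)
                if row is None or row.match is None:
                    depth_cells.append("")
                    signal_cells.append("")
                else:
                    depth_cells.append(str(row.match.peak_depth))
                    signal_cells.append(_fmt_intensity(row.match.intensity))
            depth_f.write("\t".join(depth_cells) + "\n")
            signal_f.write("\t".join(signal_cells) + "\n")

    with summary_path.open("w", encoding="utf-8", newline="\n") as summary_f:
        summary_f.write("\t".join(Y_SUMMARY_COLUMNS) + "\n")
        for info, rows in rows_by_scan:
            matched_signal = sum(r.match.intensity for r in rows if r.match)
            tic = info.get("tic") or 0.0
            fraction = min(1.0, matched_signal / tic) if tic > 0 else 0.0
            summary_f.write(
                "\t".join(
                    (
                        str(info["scan_number"]),
                        str(info.get("peptide", "")),
                        str(info.get("glycan", "")),
                        str(info.get("charge", "")),
                        str(sum(1 for r in rows if r.match)),
                        _fmt_fraction(fraction),
                    )
                )
                + "\n"
            )
    return depth_path, signal_path, summary_path
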
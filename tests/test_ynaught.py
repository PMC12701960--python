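"""Y-ion arithmetic, PSM/glycan parsing and planted-fixture extraction.

Expected peptide masses were frozen from an independent residue-mass
summation oracle using a separately transcribed amino-acid table.
"""

import math

import pytest
from hypothesis import given, strategies as st

from glycoscreen.ion_library import ISOTOPE_SPACING, PROTON_MASS
from glycoscreen.oxonium_extraction import ExtractionSettings
from glycoscreen.spectra_io import read_spectra
from glycoscreen.synthetic_fixtures import PlantedYIon, generate_glycopeptide_fixture
from glycoscreen.ynaught import (
    ChargeRangeSpec,
    GlycoPSM,
    YnaughtSettings,
    build_y_ion_definitions,
    extract_y_ions,
    lookup_glycan,
    peptide_backbone_mass,
    read_glycan_database,
    read_psm_table,
    remainder_mass_of,
    resolve_charge_range,
    y_ion_mz_neutral_loss,
    y_ion_mz_remainder,
)

# independent residue-mass oracle (transcribed from a standard table,
# separate from the package's constants)
_ORACLE_RESIDUES = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276, "V": 99.06841,
    "T": 101.04768, "C": 103.00919, "L": 113.08406, "I": 113.08406,
    "N": 114.04293, "D": 115.02694, "Q": 128.05858, "K": 128.09496,
    "E": 129.04259, "M": 131.04049, "H": 137.05891, "F": 147.06841,
    "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
_ORACLE_WATER = 18.01056


def oracle_peptide_mass(sequence):
    return sum(_ORACLE_RESIDUES[a] for a in sequence) + _ORACLE_WATER


class TestPeptideBackboneMass:
    def test_glycine(self):
        assert peptide_backbone_mass("G") == pytest.approx(75.03203, abs=1e-4)

    def test_peptide(self):
        assert peptide_backbone_mass("PEPTIDE") == pytest.approx(
            oracle_peptide_mass("PEPTIDE"), abs=1e-3
        )
        assert peptide_backbone_mass("PEPTIDE") == pytest.approx(799.35997, abs=1e-3)

    def test_modifications_added(self):
        plain = peptide_backbone_mass("PEPTIDEK")
        modified = peptide_backbone_mass("PEPTIDEK", [(2, 57.02146), (5, 15.99491)])
        assert modified == pytest.approx(plain + 57.02146 + 15.99491, abs=1e-9)

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            peptide_backbone_mass("")

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="B"):
            peptide_backbone_mass("PEPBTIDE")

    @given(st.text(alphabet=sorted(_ORACLE_RESIDUES), min_size=1, max_size=30))
    def test_matches_oracle(self, sequence):
        assert peptide_backbone_mass(sequence) == pytest.approx(
            oracle_peptide_mass(sequence), abs=5e-3
        )


class TestYIonMz:
    def test_remainder_hexnac(self):
        # (1000 + 203.07937 + 1.007276) / 1
        assert y_ion_mz_remainder(1000.0, 203.07937, 1, 0) == pytest.approx(1204.08665, abs=1e-4)

    def test_y0_identity(self):
        assert y_ion_mz_remainder(1000.0, 0.0, 1, 0) == pytest.approx(1001.00728, abs=1e-4)

    def test_charge2_isotope1(self):
        expected = (1000.0 + 203.07937 + 2 * 1.007276466) / 2 + 1.0033548378 / 2
        assert y_ion_mz_remainder(1000.0, 203.07937, 2, 1) == pytest.approx(expected, abs=1e-6)
        assert y_ion_mz_remainder(1000.0, 203.07937, 2, 1) == pytest.approx(603.04864, abs=1e-4)

    def test_zero_loss_is_precursor_mz(self):
        neutral = 2500.0
        for z in (1, 2, 3):
            assert y_ion_mz_neutral_loss(neutral, 0.0, z) == pytest.approx(
                (neutral + z * PROTON_MASS) / z
            )

    def test_excess_loss_rejected(self):
        with pytest.raises(ValueError):
            y_ion_mz_neutral_loss(1000.0, 1500.0, 1)

    def test_bad_charge_rejected(self):
        with pytest.raises(ValueError):
            y_ion_mz_remainder(1000.0, 0.0, 0)
        with pytest.raises(ValueError):
            y_ion_mz_neutral_loss(1000.0, 0.0, -1)

    @given(
        peptide=st.floats(500.0, 4000.0),
        glycan=st.floats(200.0, 3000.0),
        split=st.floats(0.0, 1.0),
        z=st.integers(1, 6),
        k=st.integers(0, 2),
    )
    def test_mode_equivalence(self, peptide, glycan, split, z, k):
        """REMAINDER(R) == NEUTRAL_LOSS(G - R) when precursor = peptide + glycan."""
        remainder = glycan * split
        loss = glycan - remainder
        lhs = y_ion_mz_remainder(peptide, remainder, z, k)
        rhs = y_ion_mz_neutral_loss(peptide + glycan, loss, z, k)
        assert math.isclose(lhs, rhs, abs_tol=1e-6)

    @given(mass=st.floats(500.0, 5000.0), z=st.integers(1, 6), k=st.integers(0, 1))
    def test_isotope_offset_exact(self, mass, z, k):
        delta = y_ion_mz_remainder(mass, 0.0, z, k + 1) - y_ion_mz_remainder(mass, 0.0, z, k)
        assert math.isclose(delta, ISOTOPE_SPACING / z, abs_tol=1e-12)

    @given(mass=st.floats(500.0, 5000.0), z=st.integers(1, 5))
    def test_mz_decreases_with_charge(self, mass, z):
        assert y_ion_mz_remainder(mass, 0.0, z + 1) < y_ion_mz_remainder(mass, 0.0, z)


class TestChargeRange:
    def test_paper_example(self):
        assert resolve_charge_range(("1", "P-1"), 3) == [1, 2]

    def test_integer_bounds(self):
        assert resolve_charge_range(("2", "2"), 4) == [2]

    def test_p_with_charge_1(self):
        assert resolve_charge_range(("1", "P"), 1) == [1]

    def test_upper_clamped_to_p(self):
        assert resolve_charge_range(("1", "5"), 3) == [1, 2, 3]

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            resolve_charge_range(("3", "P-1"), 3)

    def test_bad_expression(self):
        with pytest.raises(ValueError):
            ChargeRangeSpec("Q", "P").resolve(3)


class TestTables:
    def test_psm_table_fragpipe_dialect(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text(
            "Spectrum\tPeptide\tCharge\tAssigned Modifications\tTotal Glycan Composition\n"
            "run.00042.00042.3\tPEPTIDEK\t3\t2P(15.9949)\tHexNAc2Hex5\n"
            "run.00050.00050.2\tSEQ\t2\t\t\n"  # no glycan -> skipped
        )
        psms = read_psm_table(path)
        assert len(psms) == 1
        psm = psms[0]
        assert psm.scan_number == 42
        assert psm.peptide_sequence == "PEPTIDEK"
        assert psm.precursor_charge == 3
        assert psm.modifications == ((2, 15.9949),)
        assert psm.glycan_name == "HexNAc2Hex5"

    def test_psm_table_plain_dialect(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text("scan\tpeptide\tcharge\tglycan\n7\tPEPTIDEK\t2\tG1\n")
        psms = read_psm_table(path)
        assert psms[0].scan_number == 7

    def test_psm_missing_columns(self, tmp_path):
        path = tmp_path / "psm.tsv"
        path.write_text("scan\tpeptide\n1\tPEP\n")
        with pytest.raises(ValueError, match="missing required"):
            read_psm_table(path)

    def test_glycan_database(self, tmp_path):
        path = tmp_path / "glycans.tsv"
        path.write_text("glycan\tmass\nHexNAc2Hex5\t1216.4229\n")
        glycans = read_glycan_database(path)
        assert glycans["HexNAc2Hex5"] == pytest.approx(1216.4229)

    def test_glycan_duplicates_rejected(self, tmp_path):
        path = tmp_path / "glycans.tsv"
        path.write_text("glycan\tmass\nA\t100\nA\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_glycan_database(path)

    def test_glycan_lookup_lists_candidates(self):
        with pytest.raises(KeyError, match="candidates"):
            lookup_glycan({"HexNAc2Hex5": 1216.4}, "HexNAc2Hex9")


class TestBuildDefinitions:
    def _psm(self, charge=3):
        return GlycoPSM(1, "PEPTIDEK", (), "G", charge)

    def test_cartesian_size(self):
        settings = YnaughtSettings(
            remainder_compositions=("Y0", "HexNAc1"),
            isotopes=(0, 1),
            charge_range=ChargeRangeSpec(1, "P-1"),
        )
        defs = build_y_ion_definitions(self._psm(3), 2000.0, settings)
        assert len(defs) == 2 * 2 * 2  # compositions x charges(1,2) x isotopes

    def test_custom_additions_combine(self):
        settings = YnaughtSettings(
            remainder_compositions=("Y0",),
            isotopes=(0,),
            charge_range=ChargeRangeSpec(1, 1),
            custom_additions=(("tag", 100.0),),
        )
        defs = build_y_ion_definitions(self._psm(1), 2000.0, settings)
        labels = {d.label for d in defs}
        assert labels == {"Y0", "Y0+tag"}


class TestExtractYIons:
    @pytest.fixture
    def bundle(self, tmp_path):
        planted = [
            PlantedYIon("Y0", 1),
            PlantedYIon("HexNAc1", 1),
            PlantedYIon("HexNAc2Hex1", 2),
        ]
        return generate_glycopeptide_fixture(
            "PEPTIDEK", "HexNAc2Hex5", "HexNAc2Hex5", 3, planted, tmp_path, seed=11
        )

    def test_planted_recovery(self, bundle):
        mzml, psm_path, glycan_path = bundle
        psm = read_psm_table(psm_path)[0]
        glycans = read_glycan_database(glycan_path)
        record = next(read_spectra(mzml))
        rows = extract_y_ions(record, psm, glycans)
        found = {(r.label, r.charge, r.isotope) for r in rows}
        assert found == {("Y0", 1, 0), ("HexNAc1", 1, 0), ("HexNAc2Hex1", 2, 0)}
        for row in rows:
            assert abs(row.match.observed_mz - row.theoretical_mz) < 1e-6

    def test_no_planted_gives_empty_table(self, tmp_path):
        mzml, psm_path, glycan_path = generate_glycopeptide_fixture(
            "PEPTIDEK", "HexNAc2Hex5", "HexNAc2Hex5", 2, [], tmp_path, seed=5
        )
        record = next(read_spectra(mzml))
        rows = extract_y_ions(record, read_psm_table(psm_path)[0],
                              read_glycan_database(glycan_path))
        assert rows == []

    def test_isotope_gating(self, tmp_path):
        planted = [PlantedYIon("Y0", 1, isotope=1)]  # only M+1 planted
        mzml, psm_path, glycan_path = generate_glycopeptide_fixture(
            "PEPTIDEK", "HexNAc2Hex5", "HexNAc2Hex5", 2, planted, tmp_path, seed=9
        )
        record = next(read_spectra(mzml))
        psm = read_psm_table(psm_path)[0]
        glycans = read_glycan_database(glycan_path)
        with_m1 = extract_y_ions(record, psm, glycans,
                                 y_settings=YnaughtSettings(isotopes=(0, 1)))
        only_m0 = extract_y_ions(record, psm, glycans,
                                 y_settings=YnaughtSettings(isotopes=(0,)))
        assert {(r.label, r.isotope) for r in with_m1} == {("Y0", 1)}
        assert only_m0 == []

    def test_scan_mismatch_rejected(self, bundle):
        mzml, psm_path, glycan_path = bundle
        psm = read_psm_table(psm_path)[0]
        record = next(read_spectra(mzml))
        record.scan_number = 999
        with pytest.raises(ValueError, match="does not match"):
            extract_y_ions(record, psm, read_glycan_database(glycan_path))

    def test_unresolved_glycan(self, bundle):
        mzml, psm_path, _ = bundle
        psm = read_psm_table(psm_path)[0]
        record = next(read_spectra(mzml))
        with pytest.raises(KeyError, match="candidates"):
            extract_y_ions(record, psm, {"Other": 500.0})

    def test_neutral_loss_route_matches_remainder_route(self, bundle):
        mzml, psm_path, glycan_path = bundle
        psm = read_psm_table(psm_path)[0]
        glycans = read_glycan_database(glycan_path)
        record = next(read_spectra(mzml))
        # losing the whole glycan is the same target as remainder Y0
        rows = extract_y_ions(
            record, psm, glycans,
            y_settings=YnaughtSettings(
                remainder_compositions=(),
                neutral_loss_compositions=("HexNAc2Hex5",),
                charge_range=ChargeRangeSpec(1, 1),
            ),
        )
        assert len(rows) == 1
        y0 = y_ion_mz_remainder(
            peptide_backbone_mass("PEPTIDEK"), 0.0, 1, 0
        )
        assert rows[0].theoretical_mz == pytest.approx(y0, abs=1e-6)


def test_remainder_mass_of_y0_aliases():
    assert remainder_mass_of("Y0") == 0.0
    assert remainder_mass_of("none") == 0.0
    assert remainder_mass_of("HexNAc2") == pytest.approx(2 * 203.07937, abs=1e-4)
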
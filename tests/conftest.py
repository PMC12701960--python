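import numpy as np
import pytest

from glycoscreen.ion_library import builtin_catalog
from glycoscreen.spectra_io import ActivationType, SpectrumRecord
from glycoscreen.synthetic_fixtures import FixtureSpec, generate_spectra, write_fixture_mzml

PLANTED_EIGHT = (
    "HexNAc",
    "Hex",
    "NeuAc",
    "Hex-HexNAc",
    "HexNAc-H2O",
    "NeuAc-H2O",
    "Hex2-HexNAc",
    "NeuAc-Hex-HexNAc",
)


@pytest.fixture(scope="session")
def common_ions():
    return builtin_catalog("common")


@pytest.fixture(scope="session")
def all_ions():
    return builtin_catalog("all")


@pytest.fixture
def planted_spec():
    return FixtureSpec(
        n_scans=5,
        planted_ions=PLANTED_EIGHT,
        target_fraction=0.30,
        n_decoys=100,
        seed=42,
    )


@pytest.fixture
def planted_spectra(planted_spec):
    return generate_spectra(planted_spec)


@pytest.fixture
def planted_mzml(tmp_path, planted_spectra):
    return write_fixture_mzml(planted_spectra, tmp_path / "planted.mzML")


def make_spectrum(mz, intensity, *, activation=ActivationType.HCD, noise=None,
                  scan_number=1, tic=None, **kwargs):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    return SpectrumRecord(
        scan_number=scan_number,
        ms_level=2,
        activation=activation,
        tic=float(intensity.sum()) if tic is None else tic,
        mz=mz,
        intensity=intensity,
        noise=None if noise is None else np.asarray(noise, dtype=float),
        **kwargs,
    )
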
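# glycoscreen

Search-engine-independent screening of glycopeptide MS/MS spectra.

`glycoscreen` extracts glycan-specific diagnostic (oxonium) ions and Y-type
ions from centroided tandem mass spectra, scores the glycan content of every
scan, and flags spectra likely to come from glycopeptides — without running
or depending on any glycopeptide search engine. It reads mzML 1.1, ships a
50+ ion diagnostic-ion catalog (with a 17-ion "common" subset), accepts
custom ion tables, and writes three tab-delimited report files per input.

## Features

- **Oxonium extraction** — per-scan matching of diagnostic ions at a
  configurable tolerance (default 15 ppm; Da tolerance supported), with
  signal-to-noise filtering when the file carries noise estimates and an
  intensity threshold otherwise. Each match records its intensity and its
  *peak depth* (intensity rank within the scan, 1 = most intense).
- **LikelyGlycoSpectrum classifier** — a per-scan boolean requiring both a
  minimum number of matched ions inside an activation-specific depth window
  (top 25 / 50 / 25 peaks for HCD / ETD-family / UVPD) and a minimum
  oxonium share of the total ion current (20% / 5% / 20%). The required
  count scales with the number of ions selected (4 below six, half the
  selection for 6–15, 8 above 15; halved for ETD-family; never below 4).
- **Ynaught module** — Y-type ion enumeration for identified glycopeptides
  from a FragPipe-psm.tsv-like table plus a glycan mass database, by glycan
  remainder or precursor neutral loss, over a charge range expressed in the
  precursor charge P (e.g. `1` to `P-1`) with optional M+1/M+2 isotopes and
  custom mass additions/subtractions.
- **Synthetic fixtures** — seeded generators produce mzML files with
  planted ions at known ranks and TIC fractions (decoys kept ≥ 30 ppm from
  every catalog ion), so the whole pipeline is testable offline.

## CLI

```bash
# oxonium extraction over one file or a folder of .mzML files
glycoscreen extract data/run.mzML --ions common --tolerance 15 --out-dir out/
glycoscreen extract data/folder/ --ions all                  # batch mode
glycoscreen extract data/run.mzML --ions my_custom_ions.tsv  # custom ions

# Y-ion extraction for identified glycopeptides
glycoscreen ynaught data/run.mzML --psm psm.tsv --glycans glycans.tsv \
    --charge-min 1 --charge-max P-1 --isotopes 0,1

# synthetic fixtures with planted ions
glycoscreen fixtures out/ --n-scans 10 --planted HexNAc,Hex,NeuAc,Hex-HexNAc \
    --fraction 0.3 --seed 1
```

`extract` writes `<stem>_OxoPeakDepth.txt`, `<stem>_OxoSignal.txt` and
`<stem>_Summary.txt`; `ynaught` writes the `Y`-prefixed analogs. A
`key=value` config file (`--config`) can seed any `extract` option; flags
win. Exit code 0 means success, 2 means some (but not all) batch inputs
failed.

### Custom-ion TSV

Tab-delimited with header; columns `name` plus either `mz` or
`composition` (e.g. `Hex1HexNAc1`), with optional `losses` / `adducts`
elemental-formula columns:

```
name	mz
HexNAzoSi	345.14
```

### PSM table and glycan database

The PSM table is FragPipe-psm.tsv-like: columns `Spectrum` (or `scan`),
`Peptide`, `Charge`, `Assigned Modifications`, `Total Glycan Composition`
(or `glycan`). The glycan database is a TSV with `glycan` and `mass`
columns matching the names used in the search.

## Library use

```python
from glycoscreen import builtin_catalog, extract_spectrum, read_spectra
from glycoscreen.glyco_classifier import classify_summaries

ions = builtin_catalog("common")          # the 17-ion default selection
summaries = [extract_spectrum(s, ions) for s in read_spectra("run.mzML")]
classify_summaries(summaries, len(ions))  # fills .likely_glyco in place
```
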
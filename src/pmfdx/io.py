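"""Reading and writing spectra, metadata and fingerprint matrices.

Spectrum formats: two-column CSV (``mz,intensity`` with a header line) and
mzML.  Both mzML directions are handled by a small standards-following
codec (PSI-MS cvParam accessions, base64 little-endian floats, optional
zlib) so files round-trip and interoperate with standard tooling.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from pathlib import Path
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd

from .fingerprint import FingerprintMatrix, Spectrum

_MZML_NS = "{http://psi.hupo.org/ms/mzml}"
# PSI-MS controlled-vocabulary accessions for binary data arrays
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"

__all__ = [
    "read_spectrum",
    "write_spectrum_csv",
    "write_spectrum_mzml",
    "write_spectra_mzml",
    "read_fingerprints_csv",
    "write_fingerprints_csv",
    "read_metadata",
    "write_metadata",
]


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; message locates the fault."""


def _finish(mz: np.ndarray, intensity: np.ndarray, sample_id: str, path) -> Spectrum:
    if mz.size == 0:
        raise SpectrumParseError(f"{path}: no data rows")
    if np.any(intensity < 0):
        i = int(np.flatnonzero(intensity < 0)[0])
        raise SpectrumParseError(f"{path}: negative intensity at point {i}")
    if np.any(np.diff(mz) <= 0):
        warnings.warn(f"{path}: m/z not strictly increasing; sorting", stacklevel=3)
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        # collapse exact duplicate m/z by summing (keeps the axis strict)
        uniq, inv = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            summed = np.zeros(uniq.size)
            np.add.at(summed, inv, intensity)
            mz, intensity = uniq, summed
    return Spectrum(mz=mz, intensity=intensity, sample_id=sample_id)


def _read_csv_spectrum(path: Path, sample_id: str) -> Spectrum:
    mzs, intens = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1:  # header
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise SpectrumParseError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            try:
                mzs.append(float(parts[0]))
                intens.append(float(parts[1]))
            except ValueError:
                raise SpectrumParseError(f"{path}: line {lineno}: non-numeric value in {line!r}") from None
    return _finish(np.asarray(mzs), np.asarray(intens), sample_id, path)


def _decode_binary_array(elem) -> np.ndarray:
    accessions = {cv.get("accession") for cv in elem.iter(f"{_MZML_NS}cvParam")}
    binary = elem.find(f"{_MZML_NS}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if _ACC_ZLIB in accessions:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_F32 in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _read_mzml_spectrum(path: Path, sample_id: str) -> Spectrum:
    try:
        tree = ElementTree.parse(path)
    except ElementTree.ParseError as e:
        raise SpectrumParseError(f"{path}: malformed mzML: {e}") from None
    spec = tree.getroot().find(f".//{_MZML_NS}spectrum")
    if spec is None:
        raise SpectrumParseError(f"{path}: mzML file contains no spectra")
    mz = intensity = None
    for arr in spec.iter(f"{_MZML_NS}binaryDataArray"):
        accessions = {cv.get("accession") for cv in arr.iter(f"{_MZML_NS}cvParam")}
        if _ACC_MZ_ARRAY in accessions:
            mz = _decode_binary_array(arr)
        elif _ACC_INT_ARRAY in accessions:
            intensity = _decode_binary_array(arr)
    if mz is None or intensity is None:
        raise SpectrumParseError(f"{path}: spectrum lacks m/z or intensity binary arrays")
    return _finish(mz, intensity, sample_id, path)


def read_spectrum(path, format: str | None = None, sample_id: str | None = None) -> Spectrum:
    """Read one spectrum from CSV or mzML (format inferred from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "csv"
    sid = sample_id if sample_id is not None else path.stem
    if format.lower() == "csv":
        return _read_csv_spectrum(path, sid)
    if format.lower() == "mzml":
        return _read_mzml_spectrum(path, sid)
    raise ValueError(f"unknown spectrum format {format!r}")


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz,intensity\n")
        for m, i in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{float(m)!r},{float(i)!r}\n")


def _encode_array(values: np.ndarray) -> str:
    raw = struct.pack(f"<{values.size}d", *values.astype(float))
    return base64.b64encode(raw).decode("ascii")


_MZML_SPECTRUM = """\
   <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
    <cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <binaryDataArrayList count="2">
     <binaryDataArray encodedLength="{len_mz}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
      <binary>{b64_mz}</binary>
     </binaryDataArray>
     <binaryDataArray encodedLength="{len_int}">
      <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
      <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
      <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
      <binary>{b64_int}</binary>
     </binaryDataArray>
    </binaryDataArrayList>
   </spectrum>
"""


def write_spectra_mzml(spectra: list, path) -> None:
    """Write spectra to a minimal mzML file (profile mode, uncompressed)."""
    parts = []
    for idx, s in enumerate(spectra):
        b64_mz = _encode_array(s.mz)
        b64_int = _encode_array(s.intensity)
        parts.append(
            _MZML_SPECTRUM.format(
                index=idx, scan=idx + 1, npts=len(s),
                len_mz=len(b64_mz), b64_mz=b64_mz,
                len_int=len(b64_int), b64_int=b64_int,
            )
        )
    sample_id = escape(spectra[0].sample_id) if spectra else "run"
    body = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        ' <cvList count="1">\n'
        '  <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology"'
        ' URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>\n'
        " </cvList>\n"
        f' <run id="{sample_id}">\n'
        f'  <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">\n'
        + "".join(parts)
        + "  </spectrumList>\n </run>\n</mzML>\n"
    )
    Path(path).write_text(body, encoding="utf-8")


def write_spectrum_mzml(spectrum: Spectrum, path) -> None:
    write_spectra_mzml([spectrum], path)


def write_fingerprints_csv(matrix: FingerprintMatrix, path) -> None:
    matrix.to_dataframe().to_csv(path)


def read_fingerprints_csv(path, normalization_tag: str = "unknown") -> FingerprintMatrix:
    df = pd.read_csv(path, index_col=0)
    return FingerprintMatrix(
        sample_ids=[str(s) for s in df.index],
        feature_mz=np.asarray([float(c) for c in df.columns]),
        values=df.to_numpy(dtype=float),
        normalization_tag=normalization_tag,
    )


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    md = pd.read_csv(path)
    required = {"sample_id", "mmd_grade", "pm_label", "group3"}
    missing = required - set(md.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    return md
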
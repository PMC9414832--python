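"""Minimal mzML 1.1.0 reader/writer for unit-mass centroid data.

Covers the subset of mzML this package needs: MS1 centroid spectra with
uncompressed or zlib-compressed 32/64-bit float binary arrays and scan start
times in minutes or seconds.  Spectra read from file are binned to the
nearest integer m/z (the package works on nominal-mass quadrupole data).
"""

from __future__ import annotations

import base64
import zlib
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from .chromdata import ChromRun, DataValidationError, Scan, Spectrum

NS = "http://psi.hupo.org/ms/mzml"

ACC_MS_LEVEL = "MS:1000511"
ACC_SCAN_START = "MS:1000016"
ACC_MZ_ARRAY = "MS:1000514"
ACC_INTENSITY_ARRAY = "MS:1000515"
ACC_F64 = "MS:1000523"
ACC_F32 = "MS:1000521"
ACC_NO_COMPRESSION = "MS:1000576"
ACC_ZLIB = "MS:1000574"


def _tag(name: str) -> str:
    return f"{{{NS}}}{name}"


def _cv_params(elem) -> dict[str, str]:
    return {cv.get("accession"): cv.get("value", "")
            for cv in elem.findall(_tag("cvParam"))}


def _decode_binary_array(bda) -> np.ndarray:
    accs = _cv_params(bda)
    raw = base64.b64decode((bda.findtext(_tag("binary")) or "").strip())
    if ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if ACC_F32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path, **run_kwargs) -> ChromRun:
    """Read MS1 spectra from an mzML file into a ChromRun (times in minutes)."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise DataValidationError(f"{path}: not well-formed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag == _tag("indexedmzML"):
        root = root.find(_tag("mzML"))
    if root is None or root.tag != _tag("mzML"):
        raise DataValidationError(f"{path}: no <mzML> document found")

    scans: list[Scan] = []
    for sp in root.iter(_tag("spectrum")):
        accs = _cv_params(sp)
        if accs.get(ACC_MS_LEVEL, "1") != "1":
            continue
        time_min = None
        scan_list = sp.find(_tag("scanList"))
        if scan_list is not None:
            for scan in scan_list.findall(_tag("scan")):
                for cv in scan.findall(_tag("cvParam")):
                    if cv.get("accession") == ACC_SCAN_START:
                        t = float(cv.get("value"))
                        unit = (cv.get("unitName") or "").lower()
                        time_min = t / 60.0 if unit.startswith("sec") else t
        if time_min is None:
            raise DataValidationError(
                f"{path}: spectrum {sp.get('id')!r} has no scan start time")
        mz = inten = None
        for bda in sp.iter(_tag("binaryDataArray")):
            accs_b = _cv_params(bda)
            if ACC_MZ_ARRAY in accs_b:
                mz = _decode_binary_array(bda)
            elif ACC_INTENSITY_ARRAY in accs_b:
                inten = _decode_binary_array(bda)
        if mz is None or inten is None:
            raise DataValidationError(
                f"{path}: spectrum {sp.get('id')!r} lacks m/z or intensity array")
        if len(mz) != len(inten):
            raise DataValidationError(
                f"{path}: spectrum {sp.get('id')!r} array length mismatch")
        if (inten < 0).any():
            inten = np.clip(inten, 0, None)
        scans.append(Scan(time_min, Spectrum.from_arrays(mz, inten)))

    run_meta = root.find(_tag("run"))
    kwargs = dict(run_kwargs)
    if run_meta is not None and "sample_id" not in kwargs:
        kwargs["sample_id"] = run_meta.get("id", "")
    return ChromRun(scans=scans, **kwargs)


_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="iondecon" version="0.1.0"/>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1"/>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="iondecon"/>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_SPECTRUM = """      <spectrum index="{i}" id="scan={i}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t:.10g}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{lm}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{bm}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{li}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{bi}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values) -> str:
    return base64.b64encode(np.asarray(values, dtype="<f8").tobytes()).decode("ascii")


def write_mzml(run: ChromRun, path) -> None:
    """Write a ChromRun as centroid mzML (64-bit float, uncompressed)."""
    lo, hi = run.mz_range
    parts = [_HEADER.format(run_id=run.sample_id or "run", count=len(run.scans))]
    for i, scan in enumerate(run.scans):
        mzs = sorted(scan.spectrum.peaks)
        bad = [m for m in mzs if not (lo <= m <= hi)]
        if bad:
            raise DataValidationError(f"m/z {bad} outside scan range {run.mz_range}")
        bm = _b64([float(m) for m in mzs])
        bi = _b64([scan.spectrum.peaks[m] for m in mzs])
        parts.append(_SPECTRUM.format(i=i, n=len(mzs), t=scan.time,
                                      lm=len(bm), li=len(bi), bm=bm, bi=bi))
    parts.append(_FOOTER)
    Path(path).write_text("".join(parts))
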
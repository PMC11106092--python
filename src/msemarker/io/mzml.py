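"""Minimal mzML reading and writing.

The writer emits standards-conformant mzML 1.1 with uncompressed 64-bit
float binary arrays — enough for any PSI-aware reader to round-trip m/z,
intensity, retention time, ms level and centroid/profile mode. Low-energy
scans are written as ms level 1 and high-energy scans as ms level 2,
mirroring how MS^E converters map the two acquisition functions.

The reader is a small namespace-aware iterparse over ``<spectrum>``
elements supporting 32/64-bit float arrays, zlib or no compression, the
centroid/profile flag and scan start times in seconds or minutes — the
subset of mzML that LC-MS feature extraction needs.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Dict, Iterator, List, Optional, Sequence, Union
from xml.etree import ElementTree
from xml.sax.saxutils import escape

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from ..features.spectra import Spectrum

_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <softwareList count="1">
    <software id="msemarker" version="0.1.0">
      <cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="msemarker"/>
    </software>
  </softwareList>
  <instrumentConfigurationList count="1">
    <instrumentConfiguration id="IC1">
      <cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/>
    </instrumentConfiguration>
  </instrumentConfigurationList>
  <dataProcessingList count="1">
    <dataProcessing id="DP1">
      <processingMethod order="1" softwareRef="msemarker">
        <cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/>
      </processingMethod>
    </dataProcessing>
  </dataProcessingList>
  <run id="{run_id}" defaultInstrumentConfigurationRef="IC1">
    <spectrumList count="{count}" defaultDataProcessingRef="DP1">
"""

_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode(values: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _binary_array(values: Sequence[float], kind: str) -> str:
    encoded = _encode(values)
    if kind == "mz":
        name = ('<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" '
                'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>')
    else:
        name = ('<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" '
                'unitCvRef="MS" unitAccession="MS:1000131" '
                'unitName="number of detector counts"/>')
    return (
        f'          <binaryDataArray encodedLength="{len(encoded)}">\n'
        '            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>\n'
        '            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>\n'
        f"            {name}\n"
        f"            <binary>{encoded}</binary>\n"
        "          </binaryDataArray>\n"
    )


def write_mzml(
    spectra: Sequence["Spectrum"],
    path: Union[str, Path],
    run_id: str = "run",
) -> Path:
    """Write spectra to *path* as mzML; returns the path.

    Spectra are written in list order with their retention time in seconds,
    centroid/profile flag and ms level (low energy -> 1, high energy -> 2).
    """
    if not spectra:
        raise ValueError("no spectra to write")
    path = Path(path)
    parts: List[str] = [_HEADER.format(run_id=escape(run_id), count=len(spectra))]
    for i, s in enumerate(spectra):
        level = 1 if s.energy == "low" else 2
        mode_param = (
            '<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>'
            if s.mode == "centroid"
            else '<cvParam cvRef="MS" accession="MS:1000128" name="profile spectrum" value=""/>'
        )
        parts.append(
            f'      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(s)}">\n'
            f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{level}"/>\n'
            '        <cvParam cvRef="MS" accession="MS:1000294" name="mass spectrum" value=""/>\n'
            f"        {mode_param}\n"
            '        <scanList count="1">\n'
            '          <cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/>\n'
            "          <scan>\n"
            f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt:.6f}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n'
            "          </scan>\n"
            "        </scanList>\n"
            '        <binaryDataArrayList count="2">\n'
            + _binary_array(s.mz.tolist(), "mz")
            + _binary_array(s.intensity.tolist(), "intensity")
            + "        </binaryDataArrayList>\n"
            "      </spectrum>\n"
        )
    parts.append(_FOOTER)
    path.write_text("".join(parts), encoding="utf-8")
    return path


# -- reading ----------------------------------------------------------------

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_64BIT = "MS:1000523"
_ACC_32BIT = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


@dataclass
class SpectrumRecord:
    """Raw per-spectrum content of an mzML file."""

    index: int
    rt_seconds: float
    ms_level: Optional[int]
    mode: str  # 'centroid' | 'profile' | 'unknown'
    mz: np.ndarray
    intensity: np.ndarray


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def read_mzml(path: Union[str, Path]) -> Iterator[SpectrumRecord]:
    """Iterate over the spectra of an mzML file."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    index = 0
    for _, elem in ElementTree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) != "spectrum":
            continue
        ms_level: Optional[int] = None
        mode = "unknown"
        rt = 0.0
        mz = np.empty(0)
        intensity = np.empty(0)
        for child in elem.iter():
            name = _local(child.tag)
            if name == "cvParam":
                acc = child.get("accession", "")
                if acc == _ACC_MS_LEVEL:
                    ms_level = int(child.get("value", "0") or 0)
                elif acc == _ACC_CENTROID:
                    mode = "centroid"
                elif acc == _ACC_PROFILE:
                    mode = "profile"
                elif acc == _ACC_SCAN_START:
                    rt = float(child.get("value", "0") or 0.0)
                    unit = (child.get("unitName", "")
                            or child.get("unitAccession", ""))
                    if "minute" in unit or unit == "UO:0000031":
                        rt *= 60.0
        for bda in elem.iter():
            if _local(bda.tag) != "binaryDataArray":
                continue
            kind = None
            for cv in bda.iter():
                if _local(cv.tag) == "cvParam":
                    acc = cv.get("accession", "")
                    if acc == _ACC_MZ_ARRAY:
                        kind = "mz"
                    elif acc == _ACC_INTENSITY_ARRAY:
                        kind = "intensity"
            arr = _decode_array(bda)
            if kind == "mz":
                mz = arr
            elif kind == "intensity":
                intensity = arr
        yield SpectrumRecord(index=index, rt_seconds=rt, ms_level=ms_level,
                             mode=mode, mz=mz, intensity=intensity)
        index += 1
        elem.clear()


def _decode_array(bda: ElementTree.Element) -> np.ndarray:
    dtype = "<d"
    compressed = False
    text = ""
    for child in bda.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_64BIT:
                dtype = "<d"
            elif acc == _ACC_32BIT:
                dtype = "<f"
            elif acc == _ACC_ZLIB:
                compressed = True
        elif name == "binary":
            text = child.text or ""
    raw = base64.b64decode(text) if text else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)
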
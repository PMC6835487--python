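"""Shared fixtures: toy ontologies, synthetic libraries, and a minimal
mzML writer used to generate test inputs on the fly."""

from __future__ import annotations

import base64
import struct
from pathlib import Path

import pytest

from chemoclass.ontology import Ontology, ChemOntClass
from chemoclass.synthetic import default_motifs, make_library, toy_ontology

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64(values, fmt="<%dd"):
    packed = struct.pack(fmt % len(values), *values)
    return base64.b64encode(packed).decode()


def _binary_array(values, name_accession, name):
    data = _b64(list(values))
    return f"""        <binaryDataArray encodedLength="{len(data)}">
          <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
          <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
          <cvParam cvRef="MS" accession="{name_accession}" name="{name}" value=""/>
          <binary>{data}</binary>
        </binaryDataArray>
"""


def write_mzml(path: Path, scans: list[dict]) -> Path:
    """Write a minimal but valid mzML file.

    Each scan dict: ms_level (1 or 2), rt (float), rt_unit ("second" or
    "minute"), peaks (list of (mz, intensity)), and for MS2 optionally
    precursor_mz (omit to create a precursor-less MS2 scan).
    """
    chunks = [_MZML_HEADER.format(count=len(scans))]
    for i, scan in enumerate(scans):
        ms_level = scan.get("ms_level", 2)
        rt = scan.get("rt", 60.0)
        rt_unit = scan.get("rt_unit", "second")
        unit_acc = "UO:0000010" if rt_unit == "second" else "UO:0000031"
        peaks = scan.get("peaks", [(100.0, 200.0)])
        mzs = [p[0] for p in peaks]
        ints = [p[1] for p in peaks]
        chunks.append(
            f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{len(peaks)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{rt_unit}"/>
          </scan>
        </scanList>
""")
        if ms_level == 2 and "precursor_mz" in scan:
            chunks.append(
                f"""        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan['precursor_mz']}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
""")
        elif ms_level == 2:
            chunks.append(
                """        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
""")
        chunks.append(f"""        <binaryDataArrayList count="2">
{_binary_array(mzs, "MS:1000514", "m/z array")}{_binary_array(ints, "MS:1000515", "intensity array")}        </binaryDataArrayList>
      </spectrum>
""")
    chunks.append(_MZML_FOOTER)
    path.write_text("".join(chunks))
    return path


@pytest.fixture(scope="session")
def ontology() -> Ontology:
    return toy_ontology()


@pytest.fixture(scope="session")
def motifs():
    return default_motifs(seed=7)


@pytest.fixture(scope="session")
def library(ontology, motifs):
    """Small strong-signal reference library (20 spectra/class, 60 bg)."""
    return make_library(motifs, ontology, n_per_class=20, n_background=60, seed=7)


@pytest.fixture(scope="session")
def chain_ontology() -> Ontology:
    """Linear hierarchy a -> b -> c used for lineage path tests."""
    return Ontology([
        ChemOntClass("0000001", "a", None),
        ChemOntClass("0000002", "b", "0000001"),
        ChemOntClass("0000003", "c", "0000002"),
    ])
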
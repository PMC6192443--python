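"""Centroided LC-MS/MS run model and mzML input/output.

Retention time is canonically minutes throughout the package (the
co-elution criterion is 0.2 min). Only centroided peak lists are
supported; profile-mode spectra are rejected on read with advice to
centroid first.

The reader is a self-contained streaming mzML parser (indexed and
non-indexed documents; 32/64-bit float arrays, plain or zlib
compressed). The writer emits a minimal but standards-conformant
non-indexed mzML 1.1.0 document (64-bit float arrays, no compression)
that round-trips through the reader and through third-party mzML
readers.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Ms1Scan", "Ms2Scan", "Run", "read_mzml", "write_mzml"]


def _as_peak_arrays(mz, intensity):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape or mz.ndim != 1:
        raise ValueError("m/z and intensity arrays must be 1-D and equal length")
    if mz.size and np.any(np.diff(mz) <= 0):
        raise ValueError("m/z values must be strictly increasing")
    if np.any(intensity < 0):
        raise ValueError("intensities must be >= 0")
    return mz, intensity


@dataclass
class Ms1Scan:
    """A survey full scan: centroided peaks at one retention time."""

    scan_id: str
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        self.mz, self.intensity = _as_peak_arrays(self.mz, self.intensity)

    ms_level: int = field(default=1, init=False, repr=False)


@dataclass
class Ms2Scan:
    """A fragmentation scan with precursor metadata."""

    scan_id: str
    rt_min: float
    precursor_mz: float
    precursor_charge: int
    source_ms1_id: str
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        if self.rt_min < 0:
            raise ValueError("retention time must be >= 0")
        if not 300.0 <= self.precursor_mz <= 2000.0:
            raise ValueError(
                f"precursor m/z {self.precursor_mz:.4f} outside the 300-2000 survey range"
            )
        if self.precursor_charge < 2:
            raise ValueError("precursor charge must be >= 2 (multiply charged ions only)")
        self.mz, self.intensity = _as_peak_arrays(self.mz, self.intensity)

    ms_level: int = field(default=2, init=False, repr=False)


@dataclass
class Run:
    """An ordered, RT-interleaved sequence of MS1 and MS2 scans."""

    run_id: str
    scans: list
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        last_rt = -np.inf
        seen_ms1: set[str] = set()
        for scan in self.scans:
            if scan.rt_min < last_rt:
                raise ValueError(
                    f"scan {scan.scan_id}: RT {scan.rt_min} decreases "
                    f"(previous {last_rt})"
                )
            last_rt = scan.rt_min
            if scan.ms_level == 1:
                seen_ms1.add(scan.scan_id)
            elif scan.source_ms1_id and scan.source_ms1_id not in seen_ms1:
                raise ValueError(
                    f"MS2 scan {scan.scan_id}: source MS1 "
                    f"{scan.source_ms1_id!r} does not precede it"
                )

    def ms1_scans(self) -> list[Ms1Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> list[Ms2Scan]:
        return [s for s in self.scans if s.ms_level == 2]


# ---------------------------------------------------------------------------
# mzML writing

_NS = "http://psi.hupo.org/ms/mzml"


def _encode_floats(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *values)
    return base64.b64encode(raw).decode("ascii")


def _cv(parent, accession, name, value=None, unit=None):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": "" if value is None else str(value)}
    if unit is not None:
        unit_acc, unit_name, unit_ref = unit
        attrs.update(unitCvRef=unit_ref, unitAccession=unit_acc, unitName=unit_name)
    return ET.SubElement(parent, "cvParam", attrs)


_UNIT_MINUTE = ("UO:0000031", "minute", "UO")
_UNIT_MZ = ("MS:1000040", "m/z", "MS")
_UNIT_COUNTS = ("MS:1000131", "number of detector counts", "MS")


def _binary_array(parent, values: np.ndarray, array_accession: str, array_name: str):
    encoded = _encode_floats(values)
    bda = ET.SubElement(parent, "binaryDataArray", {"encodedLength": str(len(encoded))})
    _cv(bda, "MS:1000523", "64-bit float")
    _cv(bda, "MS:1000576", "no compression")
    unit = _UNIT_MZ if array_accession == "MS:1000514" else _UNIT_COUNTS
    _cv(bda, array_accession, array_name, unit=unit)
    ET.SubElement(bda, "binary").text = encoded


def write_mzml(run: Run, path: str | Path) -> None:
    """Write a :class:`Run` to a non-indexed mzML file."""
    run.validate()
    root = ET.Element(
        "mzML",
        {
            "xmlns": _NS,
            "version": "1.1.0",
            "id": run.run_id,
        },
    )
    cv_list = ET.SubElement(root, "cvList", {"count": "2"})
    ET.SubElement(cv_list, "cv", {
        "id": "MS",
        "fullName": "Proteomics Standards Initiative Mass Spectrometry Ontology",
        "URI": "https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    })
    ET.SubElement(cv_list, "cv", {
        "id": "UO",
        "fullName": "Unit Ontology",
        "URI": "http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo",
    })
    fd = ET.SubElement(root, "fileDescription")
    fc = ET.SubElement(fd, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000580", "MSn spectrum")
    _cv(fc, "MS:1000127", "centroid spectrum")

    sw_list = ET.SubElement(root, "softwareList", {"count": "1"})
    sw = ET.SubElement(sw_list, "software", {"id": "proglu", "version": "0.1.0"})
    _cv(sw, "MS:1000799", "custom unreleased software tool", value="proglu")

    ic_list = ET.SubElement(root, "instrumentConfigurationList", {"count": "1"})
    ic = ET.SubElement(ic_list, "instrumentConfiguration", {"id": "IC1"})
    _cv(ic, "MS:1000031", "instrument model")

    dp_list = ET.SubElement(root, "dataProcessingList", {"count": "1"})
    dp = ET.SubElement(dp_list, "dataProcessing", {"id": "DP1"})
    pm = ET.SubElement(dp, "processingMethod", {"order": "1", "softwareRef": "proglu"})
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_el = ET.SubElement(
        root, "run", {"id": run.run_id, "defaultInstrumentConfigurationRef": "IC1"}
    )
    spec_list = ET.SubElement(
        run_el,
        "spectrumList",
        {"count": str(len(run.scans)), "defaultDataProcessingRef": "DP1"},
    )
    for index, scan in enumerate(run.scans):
        spec = ET.SubElement(
            spec_list,
            "spectrum",
            {
                "index": str(index),
                "id": scan.scan_id,
                "defaultArrayLength": str(len(scan.mz)),
            },
        )
        _cv(spec, "MS:1000511", "ms level", value=scan.ms_level)
        if scan.ms_level == 1:
            _cv(spec, "MS:1000579", "MS1 spectrum")
        else:
            _cv(spec, "MS:1000580", "MSn spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        scan_list = ET.SubElement(spec, "scanList", {"count": "1"})
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = ET.SubElement(scan_list, "scan")
        _cv(scan_el, "MS:1000016", "scan start time", value=repr(scan.rt_min),
            unit=_UNIT_MINUTE)
        if scan.ms_level == 2:
            prec_list = ET.SubElement(spec, "precursorList", {"count": "1"})
            prec_attrs = {}
            if scan.source_ms1_id:
                prec_attrs["spectrumRef"] = scan.source_ms1_id
            prec = ET.SubElement(prec_list, "precursor", prec_attrs)
            iso = ET.SubElement(prec, "isolationWindow")
            _cv(iso, "MS:1000827", "isolation window target m/z",
                value=repr(scan.precursor_mz), unit=_UNIT_MZ)
            si_list = ET.SubElement(prec, "selectedIonList", {"count": "1"})
            si = ET.SubElement(si_list, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z",
                value=repr(scan.precursor_mz), unit=_UNIT_MZ)
            _cv(si, "MS:1000041", "charge state", value=scan.precursor_charge)
            act = ET.SubElement(prec, "activation")
            _cv(act, "MS:1000422", "beam-type collision-induced dissociation")
        bda_list = ET.SubElement(spec, "binaryDataArrayList", {"count": "2"})
        _binary_array(bda_list, scan.mz, "MS:1000514", "m/z array")
        _binary_array(bda_list, scan.intensity, "MS:1000515", "intensity array")

    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(path), xml_declaration=True, encoding="utf-8")


# ---------------------------------------------------------------------------
# mzML reading


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cv_params(element) -> dict[str, tuple[str, str]]:
    """accession -> (value, unitName) for direct cvParam children."""
    out: dict[str, tuple[str, str]] = {}
    for child in element:
        if _local(child.tag) == "cvParam":
            out[child.get("accession", "")] = (
                child.get("value", ""),
                child.get("unitName", ""),
            )
    return out


def _decode_binary_array(bda) -> np.ndarray:
    params = _cv_params(bda)
    text = ""
    for child in bda:
        if _local(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _rt_minutes(spectrum_el, path) -> float:
    for el in spectrum_el.iter():
        if _local(el.tag) == "scan":
            params = _cv_params(el)
            if "MS:1000016" in params:
                value, unit = params["MS:1000016"]
                rt = float(value)
                if unit in ("second", "seconds", "s"):
                    rt /= 60.0
                elif unit in ("millisecond", "milliseconds", "ms"):
                    rt /= 60000.0
                return rt
    raise ValueError(f"{path}: spectrum {spectrum_el.get('id')!r} has no scan start time")


def _peak_arrays(spectrum_el, path) -> tuple[np.ndarray, np.ndarray]:
    mz_arr = int_arr = None
    for el in spectrum_el.iter():
        if _local(el.tag) == "binaryDataArray":
            params = _cv_params(el)
            if "MS:1000514" in params:
                mz_arr = _decode_binary_array(el)
            elif "MS:1000515" in params:
                int_arr = _decode_binary_array(el)
    if mz_arr is None or int_arr is None:
        raise ValueError(
            f"{path}: spectrum {spectrum_el.get('id')!r} lacks m/z or intensity array"
        )
    return mz_arr, int_arr


def _parse_spectrum(spectrum_el, path, last_ms1_id: str):
    """Return an Ms1Scan/Ms2Scan, or None for an MS2 without a charge."""
    params = _cv_params(spectrum_el)
    if "MS:1000128" in params:
        raise ValueError(
            f"{path}: spectrum {spectrum_el.get('id')!r} is profile-mode; "
            "centroid the data before analysis"
        )
    if "MS:1000511" not in params:
        raise ValueError(f"{path}: spectrum {spectrum_el.get('id')!r} has no ms level")
    level = int(params["MS:1000511"][0])
    scan_id = spectrum_el.get("id", "")
    rt = _rt_minutes(spectrum_el, path)
    mz_arr, int_arr = _peak_arrays(spectrum_el, path)
    if level == 1:
        return Ms1Scan(scan_id, rt, mz_arr, int_arr)

    precursor_mz = None
    charge = None
    source_ref = last_ms1_id
    for el in spectrum_el.iter():
        tag = _local(el.tag)
        if tag == "precursor":
            source_ref = el.get("spectrumRef", source_ref)
        elif tag == "selectedIon":
            ion_params = _cv_params(el)
            if "MS:1000744" in ion_params:
                precursor_mz = float(ion_params["MS:1000744"][0])
            if "MS:1000041" in ion_params:
                charge = int(ion_params["MS:1000041"][0])
    if precursor_mz is None:
        raise ValueError(f"{path}: MS2 spectrum {scan_id!r} has no selected ion m/z")
    if charge is None:
        return None
    return Ms2Scan(scan_id, rt, precursor_mz, charge, source_ref, mz_arr, int_arr)


def read_mzml(path: str | Path) -> Run:
    """Read a centroided mzML file into a :class:`Run`.

    Indexed and non-indexed mzML are accepted. MS2 scans without a
    declared precursor charge are skipped (the count is recorded in
    ``Run.metadata['skipped_no_charge']``); profile-mode spectra raise,
    advising centroiding.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    scans: list = []
    skipped_no_charge = 0
    last_ms1_id = ""
    try:
        context = ET.iterparse(str(path), events=("end",))
        for _event, el in context:
            if _local(el.tag) != "spectrum":
                continue
            scan = _parse_spectrum(el, path, last_ms1_id)
            if scan is None:
                skipped_no_charge += 1
            else:
                scans.append(scan)
                if scan.ms_level == 1:
                    last_ms1_id = scan.scan_id
            el.clear()
    except ET.ParseError as exc:
        raise ValueError(f"{path}: malformed mzML ({exc})") from exc
    return Run(
        path.stem,
        scans,
        metadata={"skipped_no_charge": skipped_no_charge, "source": str(path)},
    )
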
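"""Raw LC-MS data I/O.

Reads centroided mzML / mzXML runs into a scan-ordered in-memory model,
writes synthetic mzML, and exports run metadata as stable JSON.  Retention
time is expressed in **minutes** everywhere inside the package; unit
conversion happens only at this I/O boundary.
"""

from __future__ import annotations

import base64
import json
import os
import struct
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Scan",
    "MSRun",
    "ParseError",
    "read_run",
    "write_synthetic_mzml",
    "export_metadata",
]


class ParseError(ValueError):
    """Raised when a raw file cannot be parsed; names the offending element."""


@dataclass
class Scan:
    """One MS event: centroid m/z / intensity arrays at a retention time.

    ``mz`` is strictly ascending and the same length as ``intensity``;
    ``rt`` is in minutes.  ``precursor_mz`` is set for MS2 scans only.
    """

    index: int
    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_mz: float | None = None
    polarity: str = "positive"
    scan_id: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]


@dataclass
class MSRun:
    """An ordered collection of scans from one acquisition."""

    scans: list[Scan]
    file_name: str = ""
    acquisition_timestamp: str | None = None
    timestamp_missing: bool = False
    instrument_class: str = "unknown"

    def ms1_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 1]

    def ms2_scans(self) -> list[Scan]:
        return [s for s in self.scans if s.ms_level == 2]

    @property
    def mz_range(self) -> tuple[float, float]:
        lo, hi = np.inf, -np.inf
        for s in self.scans:
            if s.mz.size:
                lo = min(lo, float(s.mz[0]))
                hi = max(hi, float(s.mz[-1]))
        return (lo, hi)

    @property
    def n_ms1_points(self) -> int:
        return sum(s.mz.size for s in self.scans if s.ms_level == 1)


def _rt_minutes(value) -> float:
    """Convert a pyteomics time value to minutes using its unit annotation."""
    unit = getattr(value, "unit_info", None)
    v = float(value)
    if unit is not None and "second" in str(unit):
        return v / 60.0
    # mzXML retentionTime durations default to seconds when unit-less
    if unit is None:
        return v / 60.0
    return v


def _localname(elem) -> str:
    return etree.QName(elem).localname


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one mzML binaryDataArray element (float32/64, zlib or none)."""
    dtype = "<f8"
    compressed = False
    payload = None
    for child in bda.iter():
        name = _localname(child)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload) if payload else b""
    if compressed and raw:
        import zlib

        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem) -> dict:
    """Flatten one <spectrum> element into scalar fields plus data arrays."""
    out = {
        "ms_level": 1,
        "rt": None,
        "polarity": "positive",
        "precursor_mz": None,
        "profile": False,
        "id": elem.get("id", ""),
        "mz": np.empty(0),
        "intensity": np.empty(0),
    }
    for cv in elem.iterchildren():
        if _localname(cv) == "cvParam":
            acc = cv.get("accession", "")
            if acc == "MS:1000511":
                out["ms_level"] = int(cv.get("value", 1))
            elif acc == "MS:1000129":
                out["polarity"] = "negative"
            elif acc == "MS:1000128":
                out["profile"] = True
    for node in elem.iter():
        name = _localname(node)
        if name == "scan" and out["rt"] is None:
            for cv in node.iterchildren():
                if _localname(cv) == "cvParam" and cv.get("accession") == "MS:1000016":
                    v = float(cv.get("value"))
                    unit = cv.get("unitName", "minute")
                    out["rt"] = v / 60.0 if "second" in unit else v
        elif name == "selectedIon":
            for cv in node.iterchildren():
                if _localname(cv) == "cvParam" and cv.get("accession") == "MS:1000744":
                    out["precursor_mz"] = float(cv.get("value"))
        elif name == "binaryDataArray":
            arr = _decode_binary_array(node)
            which = None
            for cv in node.iterchildren():
                if _localname(cv) == "cvParam":
                    if cv.get("accession") == "MS:1000514":
                        which = "mz"
                    elif cv.get("accession") == "MS:1000515":
                        which = "intensity"
            if which:
                out[which] = arr
    if out["rt"] is None:
        raise ParseError(f"spectrum {out['id']!r} lacks a scan start time")
    return out


def _iter_mzml(path: str):
    """Stream <spectrum> records from an (indexed or plain) mzML file."""
    context = etree.iterparse(str(path), events=("end",))
    try:
        for _event, elem in context:
            if _localname(elem) == "spectrum":
                yield _parse_mzml_spectrum(elem)
                elem.clear()
                while elem.getprevious() is not None:
                    del elem.getparent()[0]
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed mzML near {exc.position}: {exc}") from exc


def _read_start_timestamp(path: str) -> str | None:
    """Pull the run startTimeStamp attribute without a full parse."""
    try:
        for _event, elem in etree.iterparse(str(path), events=("start",), recover=True):
            tag = etree.QName(elem).localname
            if tag in ("run", "msRun"):
                ts = elem.get("startTimeStamp")
                return ts
            if tag in ("spectrum", "scan"):
                return None
    except etree.XMLSyntaxError:
        return None
    return None


def read_run(path: str | Path, ms1_only: bool = False) -> MSRun:
    """Parse an mzML or mzXML file into an :class:`MSRun`.

    Retention times are converted to minutes regardless of source units;
    unsorted centroid arrays are sorted ascending with intensities permuted
    in lockstep.  Profile-mode spectra trigger a warning and are processed
    on the points provided.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"file not found: {path}")
    suffix = path.suffix.lower()
    scans: list[Scan] = []
    warned_profile = False
    if suffix == ".mzml":
        for i, spec in enumerate(_iter_mzml(str(path))):
            if ms1_only and spec["ms_level"] != 1:
                continue
            if spec["profile"] and not warned_profile:
                warnings.warn(
                    f"{path.name}: profile-mode spectra found; "
                    "processing proceeds on the provided points"
                )
                warned_profile = True
            scans.append(
                Scan(
                    index=len(scans),
                    ms_level=spec["ms_level"],
                    rt=spec["rt"],
                    mz=spec["mz"],
                    intensity=spec["intensity"],
                    precursor_mz=spec["precursor_mz"],
                    polarity=spec["polarity"],
                    scan_id=spec["id"] or str(i),
                )
            )
    elif suffix == ".mzxml":
        from pyteomics import mzxml as backend

        try:
            with backend.read(str(path)) as reader:
                for i, spec in enumerate(reader):
                    level = int(spec.get("msLevel", 1))
                    if ms1_only and level != 1:
                        continue
                    precursor = None
                    if level == 2:
                        pm = spec.get("precursorMz")
                        if pm:
                            precursor = float(pm[0]["precursorMz"])
                    scans.append(
                        Scan(
                            index=len(scans),
                            ms_level=level,
                            rt=_rt_minutes(spec["retentionTime"]),
                            mz=np.asarray(spec["m/z array"], dtype=float),
                            intensity=np.asarray(spec["intensity array"], dtype=float),
                            precursor_mz=precursor,
                            polarity="negative" if spec.get("polarity") == "-" else "positive",
                            scan_id=str(spec.get("num", i)),
                        )
                    )
        except ParseError:
            raise
        except Exception as exc:  # truncated / malformed XML
            raise ParseError(f"failed to parse {path.name}: {exc}") from exc
    else:
        raise ParseError(f"unsupported raw format: {path.name}")

    ts = _read_start_timestamp(str(path))
    missing = ts is None
    if missing:
        # fall back to file modification time so acquisition-order logic stays usable
        ts = datetime.fromtimestamp(path.stat().st_mtime, tz=timezone.utc).isoformat()
    return MSRun(
        scans=scans,
        file_name=path.name,
        acquisition_timestamp=ts,
        timestamp_missing=missing,
    )


# ---------------------------------------------------------------------------
# mzML writing

_MZML_NS = "http://psi.hupo.org/ms/mzml"


def _encode(arr: np.ndarray) -> str:
    data = np.asarray(arr, dtype="<f8").tobytes()
    return base64.b64encode(data).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **extra) -> None:
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": value}
    attrs.update(extra)
    etree.SubElement(parent, "cvParam", **attrs)


def write_synthetic_mzml(
    scans: Sequence[tuple[float, np.ndarray, np.ndarray]] | Sequence[Scan],
    out_path: str | Path,
    polarity: str = "positive",
    start_timestamp: str | None = None,
) -> Path:
    """Write scans as a standards-conformant (plain, 64-bit, uncompressed) mzML file.

    ``scans`` is an iterable of ``(rt_minutes, mz, intensity)`` tuples or
    :class:`Scan` objects, ordered by retention time with per-scan arrays
    sorted by m/z.  Values round-trip bit-identically through
    :func:`read_run` (64-bit float encoding).
    """
    items: list[tuple[float, np.ndarray, np.ndarray]] = []
    for s in scans:
        if isinstance(s, Scan):
            items.append((s.rt, s.mz, s.intensity))
        else:
            rt, mz, inten = s
            items.append((float(rt), np.asarray(mz, float), np.asarray(inten, float)))
    if not items:
        raise ValueError("cannot write an mzML file with no scans")
    rts = [it[0] for it in items]
    if any(b < a for a, b in zip(rts, rts[1:])):
        raise ValueError("scans must be ordered by retention time")
    for _rt, mz, inten in items:
        if mz.shape != inten.shape:
            raise ValueError("per-scan mz and intensity arrays must match")
        if mz.size > 1 and np.any(np.diff(mz) < 0):
            raise ValueError("per-scan m/z arrays must be sorted ascending")

    root = etree.Element(
        "mzML",
        nsmap={None: _MZML_NS},
        version="1.1.0",
    )
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(
        cvlist, "cv", id="MS", fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    etree.SubElement(
        cvlist, "cv", id="UO", fullName="Unit Ontology",
        URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo",
    )
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000579", "MS1 spectrum")
    _cv(fcontent, "MS:1000127", "centroid spectrum")
    soft_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(soft_list, "software", id="ionflow", version="0.1.0")
    icl = etree.SubElement(root, "instrumentConfigurationList", count="1")
    ic = etree.SubElement(icl, "instrumentConfiguration", id="IC1")
    _cv(ic, "MS:1000031", "instrument model")
    dpl = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dpl, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="ionflow")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    run_attrs = {"id": "run1", "defaultInstrumentConfigurationRef": "IC1"}
    if start_timestamp is not None:
        run_attrs["startTimeStamp"] = start_timestamp
    run = etree.SubElement(root, "run", **run_attrs)
    slist = etree.SubElement(
        run, "spectrumList", count=str(len(items)), defaultDataProcessingRef="DP1"
    )
    pol_acc = ("MS:1000130", "positive scan") if polarity == "positive" else (
        "MS:1000129", "negative scan")
    for i, (rt, mz, inten) in enumerate(items):
        spec = etree.SubElement(
            slist,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(mz.size),
        )
        _cv(spec, "MS:1000511", "ms level", "1")
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000127", "centroid spectrum")
        _cv(spec, pol_acc[0], pol_acc[1])
        scan_list = etree.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan_el = etree.SubElement(scan_list, "scan")
        _cv(
            scan_el,
            "MS:1000016",
            "scan start time",
            repr(float(rt)),
            unitCvRef="UO",
            unitAccession="UO:0000031",
            unitName="minute",
        )
        bdal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for arr, acc, name, unit in (
            (mz, "MS:1000514", "m/z array", ("MS:1000040", "m/z")),
            (inten, "MS:1000515", "intensity array", ("MS:1000131", "number of detector counts")),
        ):
            payload = _encode(arr)
            bda = etree.SubElement(
                bdal, "binaryDataArray", encodedLength=str(len(payload))
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(
                bda, acc, name,
                unitCvRef="MS", unitAccession=unit[0], unitName=unit[1],
            )
            binary = etree.SubElement(bda, "binary")
            binary.text = payload

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    etree.ElementTree(root).write(
        str(out_path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )
    return out_path


# ---------------------------------------------------------------------------
# Run-metadata provenance


def _dependency_versions() -> dict[str, str]:
    import pandas
    import pyteomics
    import scipy

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "pyteomics": getattr(pyteomics, "__version__", "unknown"),
    }


def export_metadata(
    params: dict,
    modules: Sequence[str],
    out_path: str | Path | None = None,
) -> dict:
    """Materialize the parameter map used by a run into a key-sorted JSON record.

    The record carries the assembled module list, every tunable parameter
    (defaults included), dependency versions, and an export timestamp so an
    identical run can be reproduced from the file alone.
    """
    record = {
        "modules": list(modules),
        "parameters": {str(k): v for k, v in params.items()},
        "dependency_versions": _dependency_versions(),
        "export_timestamp": datetime.now(timezone.utc).isoformat(),
    }
    if out_path is not None:
        Path(out_path).write_text(json.dumps(record, sort_keys=True, indent=2))
    return record
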
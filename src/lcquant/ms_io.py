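"""Raw LC-MS run ingestion and tabular artifact I/O.

Supported raw formats: mzML (1.0/1.1), mzXML (2.0/2.1/3.0) and ANDI-MS style
netCDF, each optionally wrapped in a zip archive containing exactly one raw
file.  All readers normalize retention times to minutes (the chromatography
convention) regardless of the file's native unit and keep only MS1 spectra —
fragment spectra carry no quantifier-ion signal in this single-stage model.

mzXML parsing is delegated to :mod:`pyteomics` and netCDF to
:func:`scipy.io.netcdf_file` (ANDI-MS files are netCDF-3 classic).  mzML is
parsed directly with :mod:`lxml` — the controlled-vocabulary machinery a
generic mzML stack drags in is unnecessary for the handful of terms a
quantification pipeline needs (scan time, MS level, spectrum representation,
the two binary arrays) and would require network access.  A minimal mzML 1.1
writer is included so synthetic projects can be materialized on disk in a
standard format.
"""

from __future__ import annotations

import base64
import logging
import struct
import tempfile
import zipfile
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mzxml as _pyt_mzxml
from scipy.io import netcdf_file

from .annotation import Metabolite, quant_ion_mz
from .errors import (ArchiveError, FormatError, ParseError, ValidationError)

logger = logging.getLogger(__name__)

_RAW_EXTENSIONS = {".mzml": "mzml", ".mzxml": "mzxml",
                   ".cdf": "netcdf", ".nc": "netcdf"}


@dataclass
class Spectrum:
    """One mass spectrum: retention time plus parallel m/z and intensity arrays."""

    rt: float                 # minutes
    mz_values: np.ndarray     # Th, strictly ascending
    intensities: np.ndarray   # arbitrary units, >= 0
    ms_level: int = 1
    mode: str = "profile"     # "profile" | "centroid"

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.mz_values.shape != self.intensities.shape:
            raise ValidationError("m/z and intensity arrays differ in length")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise ValidationError("m/z values must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValidationError("intensities must be non-negative")
        if self.rt < 0:
            raise ValidationError("retention time must be non-negative")


@dataclass
class Run:
    """An ordered sequence of MS1 spectra from one LC-MS acquisition."""

    spectra: List[Spectrum]
    source_path: str = ""
    format: str = "mzml"
    run_id: str = ""

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    @property
    def rts(self) -> np.ndarray:
        return np.array([s.rt for s in self.spectra])


# ---------------------------------------------------------------------------
# retention-time units

def _rt_to_minutes(value, default_unit: str = "minute") -> float:
    unit = getattr(value, "unit_info", None) or default_unit
    v = float(value)
    unit = str(unit).lower()
    if unit.startswith("second") or unit == "s":
        return v / 60.0
    if unit.startswith("millisecond") or unit == "ms":
        return v / 60000.0
    if unit.startswith("minute") or unit == "min":
        return v
    if unit.startswith("hour") or unit == "h":
        return v * 60.0
    logger.warning("unknown RT unit %r; assuming minutes", unit)
    return v


def infer_mode(mz_values: np.ndarray) -> str:
    """Fallback profile/centroid inference when file metadata is absent.

    Profile data samples the m/z axis on a near-uniform grid, so essentially
    every consecutive gap sits near the median gap; centroid sticks leave
    irregular gaps spanning orders of magnitude.  A spectrum is therefore
    called centroid when fewer than 90% of its gaps fall below twice the
    median gap.
    """
    if len(mz_values) < 3:
        return "centroid"
    gaps = np.diff(mz_values)
    median = np.median(gaps)
    if median <= 0:
        return "centroid"
    frac_small = np.mean(gaps < 2.0 * median)
    return "centroid" if frac_small < 0.9 else "profile"


# ---------------------------------------------------------------------------
# readers

def _detect_format(path: Path, format_hint: Optional[str]) -> str:
    if format_hint:
        hint = format_hint.lower()
        if hint not in set(_RAW_EXTENSIONS.values()) | {"zip"}:
            raise FormatError(f"unknown format hint {format_hint!r}")
        return hint
    ext = path.suffix.lower()
    if ext == ".zip":
        return "zip"
    if ext in _RAW_EXTENSIONS:
        return _RAW_EXTENSIONS[ext]
    raise FormatError(f"unsupported raw-data extension {ext!r} ({path.name})")


def read_run(path, format_hint: Optional[str] = None,
             run_id: Optional[str] = None) -> Run:
    """Read an LC-MS run from mzML, mzXML, netCDF or a zip wrapping one of them.

    Returns a :class:`Run` holding only MS1 spectra, sorted by retention time
    in minutes.  Spectra lacking an explicit MS level are assumed to be level
    1 (logged), since single-stage acquisitions frequently omit the tag.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format_hint)
    if fmt == "zip":
        return _read_zip(path, run_id)
    reader = {"mzml": _read_mzml, "mzxml": _read_mzxml,
              "netcdf": _read_netcdf}[fmt]
    spectra = reader(path)
    if not spectra:
        raise ParseError(f"{path}: no MS1 spectra found")
    return Run(spectra=spectra, source_path=str(path), format=fmt,
               run_id=run_id or path.stem)


def _read_zip(path: Path, run_id: Optional[str]) -> Run:
    with zipfile.ZipFile(path) as zf:
        members = [m for m in zf.namelist()
                   if Path(m).suffix.lower() in _RAW_EXTENSIONS]
        if len(members) != 1:
            raise ArchiveError(
                f"{path}: zip must contain exactly one supported raw file, "
                f"found {len(members)}")
        member = members[0]
        with tempfile.TemporaryDirectory() as tmp:
            extracted = Path(zf.extract(member, tmp))
            run = read_run(extracted, run_id=run_id or Path(member).stem)
    run.source_path = str(path)
    return run


def _local(tag) -> str:
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) else ""


def _cv_params(element) -> dict:
    """accession -> attribute dict for the direct cvParam children."""
    return {child.get("accession"): dict(child.attrib)
            for child in element if _local(child.tag) == "cvParam"}


def _decode_binary_array(bda) -> Optional[np.ndarray]:
    """Decode one mzML binaryDataArray; returns None for non-m/z/intensity
    arrays."""
    params = _cv_params(bda)
    if "MS:1000514" in params:
        kind = "mz"
    elif "MS:1000515" in params:
        kind = "intensity"
    else:
        return None
    dtype = np.float32 if "MS:1000521" in params else np.float64
    compressed = "MS:1000574" in params
    binary = next((c for c in bda if _local(c.tag) == "binary"), None)
    raw = base64.b64decode((binary.text or "").strip()) \
        if binary is not None else b""
    if compressed:
        raw = zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem, path: Path) -> Optional[Spectrum]:
    params = _cv_params(elem)
    level = params.get("MS:1000511", {}).get("value")
    if level is None:
        logger.info("%s: spectrum without ms level; assuming MS1", path.name)
        level = 1
    if int(level) != 1:
        return None
    if "MS:1000127" in params:
        mode = "centroid"
    elif "MS:1000128" in params:
        mode = "profile"
    else:
        mode = None
    rt = 0.0
    arrays = {}
    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "scan":
            scan_params = _cv_params(child)
            if "MS:1000016" in scan_params:
                p = scan_params["MS:1000016"]
                unit = p.get("unitName") or (
                    "minute" if p.get("unitAccession") == "UO:0000031"
                    else "second")
                rt = _rt_to_minutes(float(p["value"]), unit)
        elif tag == "binaryDataArray":
            decoded = _decode_binary_array(child)
            if decoded is not None:
                arrays[decoded[0]] = decoded[1]
    mz = arrays.get("mz", np.empty(0))
    inten = arrays.get("intensity", np.empty(0))
    if mode is None:
        mode = infer_mode(mz)
        logger.info("spectrum mode absent from metadata; inferred %r", mode)
    return Spectrum(rt=rt, mz_values=mz, intensities=inten, ms_level=1,
                    mode=mode)


def _read_mzml(path: Path) -> List[Spectrum]:
    # parsed directly with lxml: the installed pyteomics needs the psims
    # controlled-vocabulary package (and hence the network) for mzML
    spectra = []
    try:
        for _, elem in etree.iterparse(str(path), tag="{*}spectrum"):
            spectrum = _parse_mzml_spectrum(elem, path)
            if spectrum is not None:
                spectra.append(spectrum)
            elem.clear()
    except ValidationError:
        raise
    except etree.XMLSyntaxError as exc:
        raise ParseError(
            f"{path}: mzML parse failed at line {exc.lineno}: {exc}") from exc
    except Exception as exc:
        raise ParseError(f"{path}: mzML parse failed: {exc}") from exc
    return spectra


def _read_mzxml(path: Path) -> List[Spectrum]:
    spectra = []
    try:
        with _pyt_mzxml.read(str(path)) as reader:
            for entry in reader:
                level = entry.get("msLevel", 1)
                if int(level) != 1:
                    continue
                rt = _rt_to_minutes(entry["retentionTime"], "minute")
                mz = np.asarray(entry["m/z array"], dtype=float)
                inten = np.asarray(entry["intensity array"], dtype=float)
                mode = "centroid" if entry.get("centroided") else (
                    "profile" if entry.get("centroided") is not None
                    else infer_mode(mz))
                spectra.append(Spectrum(rt=rt, mz_values=mz,
                                        intensities=inten, mode=mode))
    except ValidationError:
        raise
    except Exception as exc:
        raise ParseError(f"{path}: mzXML parse failed: {exc}") from exc
    return spectra


def _read_netcdf(path: Path) -> List[Spectrum]:
    try:
        nc = netcdf_file(str(path), "r", mmap=False)
    except Exception as exc:
        raise ParseError(f"{path}: netCDF parse failed: {exc}") from exc
    try:
        required = ("scan_acquisition_time", "mass_values",
                    "intensity_values", "scan_index")
        for name in required:
            if name not in nc.variables:
                raise ParseError(f"{path}: missing netCDF variable {name!r}")
        times = np.asarray(nc.variables["scan_acquisition_time"][:],
                           dtype=float)
        unit = getattr(nc.variables["scan_acquisition_time"], "units",
                       b"seconds")
        if isinstance(unit, bytes):
            unit = unit.decode("ascii", "replace")
        mass = np.asarray(nc.variables["mass_values"][:], dtype=float)
        inten = np.asarray(nc.variables["intensity_values"][:], dtype=float)
        index = np.asarray(nc.variables["scan_index"][:], dtype=int)
    finally:
        nc.close()
    bounds = np.append(index, mass.size)
    spectra = []
    for i, t in enumerate(times):
        lo, hi = bounds[i], bounds[i + 1]
        order = np.argsort(mass[lo:hi], kind="stable")
        mz = mass[lo:hi][order]
        spectra.append(Spectrum(rt=_rt_to_minutes(t, unit or "seconds"),
                                mz_values=mz,
                                intensities=inten[lo:hi][order],
                                mode=infer_mode(mz)))
    return spectra


# ---------------------------------------------------------------------------
# writers (synthetic projects and fixtures)

def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack("<%dd" % len(values), *map(float, values))
    return base64.b64encode(raw).decode("ascii")

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0" id="{run_id}">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_SPECTRUM = """      <spectrum index="{index}" id="scan={scan}" defaultArrayLength="{npts}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{ms_level}"/>
        <cvParam cvRef="MS" accession="{mode_acc}" name="{mode_name}" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{rt}" unitCvRef="UO" unitAccession="{unit_acc}" unitName="{unit_name}"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{mz_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{int_len}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def write_mzml(run: Run, path, rt_unit: str = "minute") -> None:
    """Write a Run as minimal mzML 1.1 (64-bit, uncompressed binary arrays).

    ``rt_unit`` selects how scan start times are encoded ("minute" or
    "second"); values are converted so the decoded run is unit-invariant.
    """
    if rt_unit not in ("minute", "second"):
        raise ValueError("rt_unit must be 'minute' or 'second'")
    unit_acc = "UO:0000031" if rt_unit == "minute" else "UO:0000010"
    parts = [_MZML_HEADER.format(run_id=escape(run.run_id or "run"),
                                 count=len(run.spectra))]
    for i, s in enumerate(run.spectra):
        rt = s.rt if rt_unit == "minute" else s.rt * 60.0
        mz_b64 = _b64_doubles(s.mz_values)
        int_b64 = _b64_doubles(s.intensities)
        mode_acc, mode_name = (("MS:1000127", "centroid spectrum")
                               if s.mode == "centroid"
                               else ("MS:1000128", "profile spectrum"))
        parts.append(_MZML_SPECTRUM.format(
            index=i, scan=i + 1, npts=len(s.mz_values), ms_level=s.ms_level,
            mode_acc=mode_acc, mode_name=mode_name,
            rt=repr(float(rt)), unit_acc=unit_acc, unit_name=rt_unit,
            mz_len=len(mz_b64), mz_b64=mz_b64,
            int_len=len(int_b64), int_b64=int_b64))
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts), encoding="utf-8")


def write_andi_netcdf(run: Run, path) -> None:
    """Write a Run as ANDI-MS style netCDF-3 (scan times in seconds)."""
    counts = [len(s.mz_values) for s in run.spectra]
    total = int(np.sum(counts))
    nc = netcdf_file(str(path), "w")
    try:
        nc.createDimension("scan_number", len(run.spectra))
        nc.createDimension("point_number", total)
        t = nc.createVariable("scan_acquisition_time", "d", ("scan_number",))
        t.units = b"Seconds"
        t[:] = np.array([s.rt * 60.0 for s in run.spectra])
        idx = nc.createVariable("scan_index", "i", ("scan_number",))
        idx[:] = np.concatenate([[0], np.cumsum(counts)[:-1]]).astype(np.int32)
        pc = nc.createVariable("point_count", "i", ("scan_number",))
        pc[:] = np.array(counts, dtype=np.int32)
        mass = nc.createVariable("mass_values", "d", ("point_number",))
        mass[:] = np.concatenate([s.mz_values for s in run.spectra]) \
            if total else np.empty(0)
        inten = nc.createVariable("intensity_values", "d", ("point_number",))
        inten[:] = np.concatenate([s.intensities for s in run.spectra]) \
            if total else np.empty(0)
    finally:
        nc.close()


def zip_raw_file(raw_path, zip_path) -> None:
    """Wrap a single raw file in a zip archive (the supported transport form)."""
    with zipfile.ZipFile(zip_path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.write(raw_path, Path(raw_path).name)


# ---------------------------------------------------------------------------
# quantification-ion list

_ION_CORE_COLUMNS = ["name", "quant_mz", "molecular_weight", "expected_rt",
                     "is_internal_standard", "ionisation_mode",
                     "pubchem", "kegg", "hmdb"]


def read_ion_list(path) -> List[Metabolite]:
    """Read a quantification-ion list CSV into Metabolite records.

    Required columns: ``name``, ``quant_mz``, ``expected_rt``,
    ``is_internal_standard``.  A row may leave ``quant_mz`` empty if it
    provides ``molecular_weight`` (the quantifier is then derived from the
    ionisation mode); a row with neither is rejected.  At most one row may be
    flagged as the internal standard.  Extra columns ride along as opaque
    metadata and survive :func:`write_ion_list`.
    """
    df = pd.read_csv(path)
    required = {"name", "quant_mz", "expected_rt", "is_internal_standard"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ion list missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("%s: ion list contains a header but no compounds", path)
        return []
    extras = [c for c in df.columns if c not in _ION_CORE_COLUMNS]
    metabolites = []
    for _, row in df.iterrows():
        mode = row.get("ionisation_mode")
        mode = mode if isinstance(mode, str) and mode else "positive"
        mw = row.get("molecular_weight")
        mw = float(mw) if pd.notna(mw) else None
        qmz = row["quant_mz"]
        if pd.isna(qmz):
            if mw is None:
                raise ValidationError(
                    f"{row['name']}: neither quant_mz nor molecular_weight "
                    f"given; cannot derive a quantifier ion")
            qmz = quant_ion_mz(mw, mode)
        ids = {k: str(row[k]) for k in ("pubchem", "kegg", "hmdb")
               if k in df.columns and pd.notna(row.get(k))}
        ert = row["expected_rt"]
        metabolites.append(Metabolite(
            name=str(row["name"]),
            quant_mz=float(qmz),
            molecular_weight=mw,
            expected_rt=float(ert) if pd.notna(ert) else None,
            is_internal_standard=bool(row["is_internal_standard"]),
            ionisation_mode=mode,
            ids=ids,
            extra={c: row[c] for c in extras if pd.notna(row[c])}))
    n_is = sum(m.is_internal_standard for m in metabolites)
    if n_is > 1:
        raise ValidationError(
            f"ion list flags {n_is} internal standards; at most one allowed")
    return metabolites


def write_ion_list(metabolites: Iterable[Metabolite], path) -> None:
    """Write Metabolites back to the ion-list CSV dialect (lossless round-trip)."""
    rows = []
    for m in metabolites:
        row = {"name": m.name, "quant_mz": m.quant_mz,
               "molecular_weight": m.molecular_weight,
               "expected_rt": m.expected_rt,
               "is_internal_standard": m.is_internal_standard,
               "ionisation_mode": m.ionisation_mode}
        row.update({k: m.ids.get(k) for k in ("pubchem", "kegg", "hmdb")
                    if k in m.ids})
        row.update(m.extra)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
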
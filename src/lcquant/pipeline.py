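"""End-to-end orchestration: calibration, quantification, comparison, export.

The batch workflow mirrors interactive targeted quantification: standards
are processed first to fit per-metabolite calibration curves (with the warp
of each run to the reference RT frame estimated along the way), then sample
runs are processed, the warped expected RT picks a peak per metabolite, the
chosen best-fit curve is inverted, and the resulting concentration table —
keyed by database IDs — is exported as CSV for downstream metabolomics
tools.  Every automatic choice is recorded as a flag on the cell so a
reviewer can find the cells that need eyes: ``not_highest`` (a taller peak
sat in the search window), ``out_of_window`` (no peak found),
``extrapolated`` (outside the calibration range) and ``manual`` (analyst
override).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from .alignment import (PeakSuggestion, RTWarp, fit_rt_warp, identity_warp,
                        override_selection, suggest_peak)
from .annotation import Metabolite
from .calibration import (CalibrationCurve, FAMILIES, MIN_STANDARDS,
                          StandardLevel, fit_calibration, invert,
                          normalize_is, suggest_best_fit)
from .errors import LcquantError, ValidationError
from .ms_io import Run, read_run
from .preprocess import (Chromatogram, Peak, ProcessingConfig, build_eics,
                         deconvolve)

logger = logging.getLogger(__name__)


@dataclass
class AlignmentParams:
    """RANSAC alignment settings; the seed makes the whole pipeline
    reproducible."""

    iterations: int = 1000
    inlier_threshold: float = 0.05   # minutes
    rt_pre_tolerance: float = 1.0    # minutes
    rt_window: float = 0.5           # minutes, suggestion + red-flag range
    seed: int = 0


@dataclass
class ProjectConfig:
    """A full quantification project: inputs, design and parameters."""

    metabolites: List[Metabolite]
    standards_design: Dict[str, Dict[str, float]]  # run -> {met -> umol/L}
    sample_ids: List[str]
    runs: Dict[str, Union[Run, str, Path]]
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    weighting: Optional[str] = None

    def __post_init__(self) -> None:
        names = {m.name for m in self.metabolites}
        for rid, design in self.standards_design.items():
            missing = set(design) - names
            if missing:
                raise ValidationError(
                    f"standards design for {rid} names compounds absent "
                    f"from the ion list: {sorted(missing)}")

    @property
    def internal_standard(self) -> Optional[Metabolite]:
        for m in self.metabolites:
            if m.is_internal_standard:
                return m
        return None

    @property
    def analytes(self) -> List[Metabolite]:
        return [m for m in self.metabolites if not m.is_internal_standard]

    def get_run(self, run_id: str) -> Run:
        run = self.runs[run_id]
        if isinstance(run, Run):
            return run
        return read_run(run, run_id=run_id)


@dataclass
class ProcessedRun:
    """Per-run preprocessing products: one EIC and peak list per target."""

    run_id: str
    chromatograms: Dict[float, Chromatogram]
    peaks: Dict[float, List[Peak]]

    @property
    def all_peaks(self) -> List[Peak]:
        return [p for plist in self.peaks.values() for p in plist]


def process_run(run: Run, targets: Sequence[float],
                config: ProcessingConfig) -> ProcessedRun:
    """Centroid, extract EICs and deconvolve one run for the target ions."""
    chroms = build_eics(run, targets, config)
    return ProcessedRun(
        run_id=run.run_id,
        chromatograms={c.target_mz: c for c in chroms},
        peaks={c.target_mz: deconvolve(c, config) for c in chroms})


@dataclass
class CalibrationResult:
    """Fitted curves, chosen families, warps and the per-run selections."""

    curves: Dict[str, Dict[str, CalibrationCurve]]   # met -> family -> curve
    best_family: Dict[str, str]
    warps: Dict[str, RTWarp]
    selections: Dict[Tuple[str, str], PeakSuggestion]  # (met, run)
    standard_areas: pd.DataFrame     # met x standard run, normalized areas
    is_normalized: bool = False

    def best_curve(self, metabolite: str) -> CalibrationCurve:
        return self.curves[metabolite][self.best_family[metabolite]]

    def report(self) -> pd.DataFrame:
        """Calibration report: one row per metabolite and family."""
        rows = []
        for met, fams in self.curves.items():
            for fam, cv in fams.items():
                rows.append(dict(
                    metabolite=met, family=fam, best=fam == self.best_family[met],
                    a0=cv.a0, a1=cv.a1, a2=cv.a2, a3=cv.a3,
                    r_squared=cv.r_squared, r_squared_log=cv.r_squared_log,
                    n_standards=cv.n_standards, c_min=cv.c_min,
                    c_max=cv.c_max, is_normalized=cv.is_normalized))
        return pd.DataFrame(rows)


def _reference_peaks(config: ProjectConfig) -> List[Tuple[float, float]]:
    refs = []
    for m in config.metabolites:
        if m.expected_rt is None:
            raise ValidationError(
                f"{m.name}: expected RT missing; seed it from a standard "
                f"run before calibrating")
        refs.append((m.quant_mz, m.expected_rt))
    return refs


def _suggest_all(config: ProjectConfig, processed: ProcessedRun,
                 warp: RTWarp) -> Dict[str, PeakSuggestion]:
    out = {}
    for m in config.metabolites:
        peaks = processed.peaks.get(m.quant_mz, [])
        out[m.name] = suggest_peak(m.expected_rt, warp, peaks,
                                   config.alignment.rt_window)
    return out


def _warp_for_run(config: ProjectConfig, processed: ProcessedRun,
                  reference: List[Tuple[float, float]],
                  run_index: int) -> RTWarp:
    ap = config.alignment
    return fit_rt_warp(reference, processed.all_peaks,
                       rt_pre_tolerance=ap.rt_pre_tolerance,
                       mz_tolerance=config.processing.mz_tolerance,
                       iterations=ap.iterations,
                       inlier_threshold=ap.inlier_threshold,
                       seed=ap.seed * 100003 + run_index)


def run_calibration(config: ProjectConfig) -> CalibrationResult:
    """Process all standard runs and fit every admissible curve family.

    The first standard run defines the reference RT frame (it is where
    expected RTs were seeded), so it gets the identity warp; every other
    standard is RANSAC-warped onto it.  Metabolites with fewer than two
    usable standard points are excluded with a warning rather than failing
    the whole calibration.
    """
    if not config.standards_design:
        raise ValidationError("no standard runs in the project design")
    reference = _reference_peaks(config)
    is_met = config.internal_standard
    standard_ids = list(config.standards_design)
    warps: Dict[str, RTWarp] = {}
    selections: Dict[Tuple[str, str], PeakSuggestion] = {}
    areas: Dict[str, Dict[str, float]] = {m.name: {}
                                          for m in config.analytes}
    targets = [m.quant_mz for m in config.metabolites]
    for idx, rid in enumerate(standard_ids):
        processed = process_run(config.get_run(rid), targets,
                                config.processing)
        warp = identity_warp() if idx == 0 else _warp_for_run(
            config, processed, reference, idx)
        warps[rid] = warp
        suggestions = _suggest_all(config, processed, warp)
        for met, sug in suggestions.items():
            selections[(met, rid)] = sug
        is_area = None
        if is_met is not None:
            is_sug = suggestions[is_met.name]
            if is_sug.peak is None:
                logger.warning("standard %s: internal standard not found; "
                               "its areas are unusable", rid)
                continue
            is_area = is_sug.peak.area
        for m in config.analytes:
            sug = suggestions[m.name]
            if sug.peak is None:
                continue
            area = sug.peak.area
            if is_area is not None:
                area = normalize_is(area, is_area, rid)
            areas[m.name][rid] = area

    curves: Dict[str, Dict[str, CalibrationCurve]] = {}
    best: Dict[str, str] = {}
    for m in config.analytes:
        levels = []
        for rid in standard_ids:
            conc = config.standards_design.get(rid, {}).get(m.name)
            area = areas[m.name].get(rid)
            if conc is None or area is None:
                continue
            levels.append(StandardLevel(concentration=conc, area=area))
        usable = [lv for lv in levels if lv.concentration > 0]
        if len(usable) < 2:
            logger.warning("%s: only %d usable standard(s); excluded from "
                           "calibration", m.name, len(usable))
            continue
        fitted = {}
        for fam in FAMILIES:
            pts = usable if fam in ("logarithmic", "power") else levels
            if fam in ("logarithmic", "power") and len(usable) < len(levels):
                logger.warning("%s: zero-concentration standards excluded "
                               "from the %s fit", m.name, fam)
            try:
                fitted[fam] = fit_calibration(
                    fam, pts, is_normalized=is_met is not None,
                    weighting=config.weighting)
            except LcquantError as exc:
                logger.info("%s: %s fit skipped (%s)", m.name, fam, exc)
        if not fitted:
            logger.warning("%s: no curve family could be fitted; excluded",
                           m.name)
            continue
        curves[m.name] = fitted
        best[m.name] = suggest_best_fit(list(fitted.values()))
    area_df = pd.DataFrame(areas).T.reindex(
        [m.name for m in config.analytes])
    return CalibrationResult(curves=curves, best_family=best, warps=warps,
                             selections=selections, standard_areas=area_df,
                             is_normalized=is_met is not None)


FLAG_NAMES = ("not_highest", "out_of_window", "extrapolated", "manual",
              "normalization_error")


@dataclass
class ConcentrationTable:
    """Metabolites x samples concentrations (umol/L) with per-cell flags."""

    metabolites: List[Metabolite]
    sample_ids: List[str]
    values: pd.DataFrame                       # met x sample, NaN = missing
    flags: Dict[Tuple[str, str], Set[str]] = field(default_factory=dict)

    def cell_flags(self, metabolite: str, sample: str) -> Set[str]:
        return self.flags.get((metabolite, sample), set())


def run_quantification(config: ProjectConfig,
                       calibration: CalibrationResult,
                       overrides: Optional[Dict[Tuple[str, str],
                                                Tuple[float, float]]] = None
                       ) -> ConcentrationTable:
    """Quantify all sample runs against the fitted calibration.

    ``overrides`` maps (metabolite, run) to manual integration bounds in
    minutes; those cells are integrated manually and flagged ``manual``.
    If an internal standard is configured but missing from a run, every
    cell of that run is marked missing with a ``normalization_error`` flag
    — without the IS there is no valid area scale for the run.
    """
    if not calibration.curves:
        raise LcquantError("calibration produced no usable curves")
    overrides = overrides or {}
    reference = _reference_peaks(config)
    is_met = config.internal_standard
    targets = [m.quant_mz for m in config.metabolites]
    quantified = [m for m in config.analytes if m.name in calibration.curves]
    values = pd.DataFrame(np.nan, index=[m.name for m in quantified],
                          columns=list(config.sample_ids))
    flags: Dict[Tuple[str, str], Set[str]] = {}
    n_std = len(config.standards_design)
    for sidx, rid in enumerate(config.sample_ids):
        processed = process_run(config.get_run(rid), targets,
                                config.processing)
        warp = _warp_for_run(config, processed, reference, n_std + sidx)
        calibration.warps[rid] = warp
        suggestions = _suggest_all(config, processed, warp)
        is_area = None
        if is_met is not None:
            is_sug = suggestions[is_met.name]
            if is_sug.peak is None:
                logger.warning("sample %s: internal standard missing; all "
                               "cells marked missing", rid)
                for m in quantified:
                    flags[(m.name, rid)] = {"normalization_error"}
                continue
            is_area = is_sug.peak.area
        for m in quantified:
            cell_flags: Set[str] = set()
            sug = suggestions[m.name]
            calibration.selections[(m.name, rid)] = sug
            if (m.name, rid) in overrides:
                chrom = processed.chromatograms[m.quant_mz]
                peak = override_selection(sug, overrides[(m.name, rid)],
                                          chrom)
                cell_flags.add("manual")
            else:
                if sug.peak is None:
                    flags[(m.name, rid)] = {"out_of_window"}
                    continue
                peak = sug.peak
                if sug.flag_not_highest:
                    cell_flags.add("not_highest")
            area = peak.area
            if is_area is not None:
                area = normalize_is(area, is_area, rid)
            try:
                conc, extrapolated = invert(calibration.best_curve(m.name),
                                            area)
            except LcquantError as exc:
                logger.warning("%s in %s: inversion failed (%s)", m.name,
                               rid, exc)
                flags[(m.name, rid)] = cell_flags | {"out_of_window"}
                continue
            if extrapolated:
                cell_flags.add("extrapolated")
            values.loc[m.name, rid] = conc
            if cell_flags:
                flags[(m.name, rid)] = cell_flags
    return ConcentrationTable(metabolites=quantified,
                              sample_ids=list(config.sample_ids),
                              values=values, flags=flags)


# ---------------------------------------------------------------------------
# comparison

DEFAULT_BIN_EDGES = (0.0, 5.0, 10.0, 15.0)


def relative_error_table(a: ConcentrationTable, b: ConcentrationTable,
                         bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
                         ) -> pd.DataFrame:
    """Bin the relative errors of table ``a`` against reference ``b``.

    Relative error per cell is |c_a - c_b| / c_b * 100.  The returned frame
    has one row per bin (the last bin is open-ended) plus an ``excluded``
    row counting reference cells at zero; percentages sum to 100 over the
    bins.
    """
    if list(a.values.index) != list(b.values.index) \
            or list(a.values.columns) != list(b.values.columns):
        raise ValidationError("tables must cover the same metabolites and "
                              "samples, in the same order")
    ca = a.values.to_numpy(dtype=float).ravel()
    cb = b.values.to_numpy(dtype=float).ravel()
    both = np.isfinite(ca) & np.isfinite(cb)
    zero_ref = both & (cb == 0)
    ok = both & (cb != 0)
    rel = np.abs(ca[ok] - cb[ok]) / cb[ok] * 100.0
    edges = list(bin_edges) + [np.inf]
    rows = []
    total = len(rel)
    for lo, hi in zip(edges[:-1], edges[1:]):
        count = int(np.sum((rel >= lo) & (rel < hi)))
        label = f"{lo:g}%-{hi:g}%" if np.isfinite(hi) else f">{lo:g}%"
        rows.append(dict(bin=label, count=count,
                         percentage=100.0 * count / total if total else 0.0))
    rows.append(dict(bin="excluded (reference zero)",
                     count=int(zero_ref.sum()), percentage=np.nan))
    return pd.DataFrame(rows)


def relative_errors(a: ConcentrationTable,
                    b: ConcentrationTable) -> pd.DataFrame:
    """Long-format per-cell relative errors (%), for external clustering."""
    rows = []
    for met in a.values.index:
        for smp in a.values.columns:
            cb = b.values.loc[met, smp]
            ca = a.values.loc[met, smp]
            if np.isfinite(ca) and np.isfinite(cb) and cb != 0:
                rows.append(dict(metabolite=met, sample=smp,
                                 relative_error=abs(ca - cb) / cb * 100.0))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# export

def export_csv(table: ConcentrationTable, path,
               id_db: str = "name") -> None:
    """Write the concentration table as ID-keyed CSV.

    The first column carries the compound identifier in the chosen
    namespace (``pubchem``/``kegg``/``hmdb``/``name``); rows lacking that
    ID fall back to the compound name with a warning.  Flags go to a
    sibling ``<stem>.flags.csv`` so the data matrix stays numeric for
    downstream tools.
    """
    if id_db not in ("pubchem", "kegg", "hmdb", "name"):
        raise ValidationError(f"unknown ID namespace {id_db!r}")
    ids = []
    for m in table.metabolites:
        if id_db == "name":
            ids.append(m.name)
        elif id_db in m.ids:
            ids.append(m.ids[id_db])
        else:
            logger.warning("%s lacks a %s ID; exporting its name instead",
                           m.name, id_db)
            ids.append(m.name)
    out = table.values.copy()
    out.insert(0, "id", ids)
    out.to_csv(path, index=False)
    flag_rows = [dict(metabolite=met, sample=smp,
                      flags=";".join(sorted(fl)))
                 for (met, smp), fl in sorted(table.flags.items()) if fl]
    flags_path = Path(path).with_suffix(".flags.csv")
    pd.DataFrame(flag_rows,
                 columns=["metabolite", "sample", "flags"]).to_csv(
        flags_path, index=False)


def read_concentration_csv(path) -> pd.DataFrame:
    """Read an exported concentration CSV back as an id-indexed matrix."""
    df = pd.read_csv(path)
    return df.set_index("id")
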
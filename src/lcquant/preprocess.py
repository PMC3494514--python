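"""Raw-data filtering, centroiding, EIC construction and peak deconvolution.

Processing runs in three steps: (i) optional Savitzky-Golay smoothing,
(ii) centroiding of profile spectra above a noise level, and (iii) extraction
of one chromatogram per quantifier m/z, which is then split into peaks at
local intensity minima.  Only the target m/z values on the ion list are
traced — a deliberate speed filter, since targeted quantification never needs
untargeted mass traces.

A pure local-minimum rule over-segments noisy chromatograms, so a minimum is
accepted as a border only when it is deep enough relative to the adjacent
apexes (``min_valley_ratio``).  Three named presets (fast / default /
thorough) bundle the parameters in order of increasing detection sensitivity;
every field remains individually overridable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
from scipy.signal import savgol_filter

from .errors import LcquantError, RangeError
from .ms_io import Run, Spectrum

logger = logging.getLogger(__name__)


@dataclass
class Chromatogram:
    """Extracted-ion chromatogram: intensity vs RT for one quantifier m/z."""

    target_mz: float
    mz_tolerance: float
    rts: np.ndarray          # minutes, strictly increasing
    intensities: np.ndarray  # >= 0
    run_id: str = ""

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.rts.size > 1 and not np.all(np.diff(self.rts) > 0):
            raise LcquantError("chromatogram RTs must be strictly increasing")


@dataclass
class Peak:
    """A detected chromatographic peak on one EIC."""

    apex_rt: float
    rt_start: float
    rt_end: float
    height: float
    area: float      # intensity * minutes
    target_mz: float
    run_id: str = ""
    manual: bool = False


@dataclass
class ProcessingConfig:
    """All tunable parameters of the three processing steps.

    sg_window / sg_order:
        Savitzky-Golay smoothing applied to each EIC before border detection;
        window 0 disables smoothing.  Peak heights and areas are always
        measured on the raw trace.
    noise_level:
        Centroiding threshold in intensity units; profile points at or below
        it are ignored.
    mz_tolerance:
        Half-width (Th) of the EIC extraction window around each target m/z.
    max_scan_gap / split_on_gaps:
        When gap splitting is enabled, a trace ends after this many
        consecutive empty scans; off by default (EICs carry explicit zeros).
    min_valley_ratio:
        A local minimum separates two peaks only if its intensity is at most
        this fraction of the smaller adjacent apex height.
    min_peak_height:
        Peaks shorter than this (raw trace) are discarded.
    """

    sg_window: int = 7
    sg_order: int = 2
    noise_level: float = 0.0
    mz_tolerance: float = 0.1
    max_scan_gap: int = 3
    split_on_gaps: bool = False
    min_valley_ratio: float = 0.66
    min_peak_height: float = 0.0
    preset: str = "default"

    def __post_init__(self) -> None:
        if self.sg_window and (self.sg_window % 2 == 0
                               or self.sg_order >= self.sg_window):
            raise LcquantError("sg_window must be odd and > sg_order")
        if self.mz_tolerance <= 0:
            raise LcquantError("mz_tolerance must be positive")
        if not 0 < self.min_valley_ratio <= 1:
            raise LcquantError("min_valley_ratio must be in (0, 1]")


#: Named parameter bundles, ordered by detection sensitivity.
PRESETS: Dict[str, dict] = {
    "fast": dict(sg_window=0, sg_order=0, min_valley_ratio=0.5,
                 preset="fast"),
    "default": dict(sg_window=7, sg_order=2, min_valley_ratio=0.66,
                    preset="default"),
    "thorough": dict(sg_window=11, sg_order=3, min_valley_ratio=0.8,
                     preset="thorough"),
}


def preset_config(name: str, **overrides) -> ProcessingConfig:
    """Build a ProcessingConfig from a preset name plus per-field overrides."""
    if name not in PRESETS:
        raise LcquantError(f"unknown preset {name!r}; "
                           f"choose from {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    cfg = ProcessingConfig(**params)
    logger.info("preset %r -> %s", name, cfg)
    return cfg


# ---------------------------------------------------------------------------
# step (i): smoothing

def smooth_sg(values: Sequence[float], window: int, order: int) -> np.ndarray:
    """Savitzky-Golay smoothing with mirrored edge padding.

    Reproduces polynomials up to ``order`` exactly in the interior, which is
    what makes it the standard chromatographic filter: peak apex positions
    and heights of well-sampled peaks are nearly unbiased.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window < 1:
        raise LcquantError("smoothing window must be odd and positive")
    if order >= window:
        raise LcquantError("polynomial order must be below the window size")
    if len(values) < window:
        raise LcquantError("sequence shorter than the smoothing window")
    return savgol_filter(values, window, order, mode="mirror")


# ---------------------------------------------------------------------------
# step (ii): centroiding

def centroid(spectrum: Spectrum, noise_level: float) -> Spectrum:
    """Reduce a profile spectrum to centroid sticks above a noise level.

    Each output stick sits at one local maximum of the profile whose summit
    exceeds ``noise_level``; its m/z is the intensity-weighted mean over that
    maximum's contiguous above-noise neighbourhood (split at interior minima
    when several maxima share a run), and its intensity is the summit value.
    """
    if spectrum.mode == "centroid":
        return spectrum
    mz = spectrum.mz_values
    inten = spectrum.intensities
    above = inten > noise_level
    out_mz: List[float] = []
    out_int: List[float] = []
    n = len(mz)
    i = 0
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < n and above[j]:
            j += 1
        _centroid_region(mz[i:j], inten[i:j], out_mz, out_int)
        i = j
    order = np.argsort(out_mz, kind="stable")
    return Spectrum(rt=spectrum.rt,
                    mz_values=np.asarray(out_mz)[order],
                    intensities=np.asarray(out_int)[order],
                    ms_level=spectrum.ms_level, mode="centroid")


def _centroid_region(mz: np.ndarray, inten: np.ndarray,
                     out_mz: List[float], out_int: List[float]) -> None:
    """Emit one centroid per local maximum of a contiguous above-noise run."""
    n = len(mz)
    if n == 1:
        out_mz.append(mz[0])
        out_int.append(inten[0])
        return
    maxima = [k for k in range(n)
              if (k == 0 or inten[k] > inten[k - 1])
              and (k == n - 1 or inten[k] >= inten[k + 1])]
    if len(maxima) == 1:
        w = inten.sum()
        out_mz.append(float(np.dot(mz, inten) / w))
        out_int.append(float(inten.max()))
        return
    # several maxima in one run: split at the interior minima between them;
    # the valley point joins neither side, keeping weighted means unbiased
    borders = []
    for a, b in zip(maxima, maxima[1:]):
        borders.append(a + int(np.argmin(inten[a:b + 1])))
    starts = [0] + [b + 1 for b in borders]
    ends = [b for b in borders] + [n]
    for s, e in zip(starts, ends):
        if e <= s:
            continue
        seg_mz, seg_int = mz[s:e], inten[s:e]
        out_mz.append(float(np.dot(seg_mz, seg_int) / seg_int.sum()))
        out_int.append(float(seg_int.max()))


# ---------------------------------------------------------------------------
# step (iii): chromatogram construction

def build_eics(run: Run, targets: Sequence[float],
               config: ProcessingConfig) -> List[Chromatogram]:
    """Extract one chromatogram per target m/z from a run.

    Profile spectra are centroided first.  For every MS1 spectrum the
    contribution to a target's trace is the summed intensity of centroids
    within ``mz_tolerance``; spectra with no match contribute an explicit
    zero, so each EIC covers the full, uniform RT grid of the run.
    """
    if not run.spectra:
        raise LcquantError("empty run")
    if not len(targets):
        raise LcquantError("no target m/z values")
    targets = np.asarray(targets, dtype=float)
    rts = np.empty(len(run.spectra))
    matrix = np.zeros((len(run.spectra), len(targets)))
    for si, spec in enumerate(run.spectra):
        cs = centroid(spec, config.noise_level)
        rts[si] = cs.rt
        if len(cs.mz_values) == 0:
            continue
        lo = np.searchsorted(cs.mz_values, targets - config.mz_tolerance,
                             side="left")
        hi = np.searchsorted(cs.mz_values, targets + config.mz_tolerance,
                             side="right")
        for ti in range(len(targets)):
            if hi[ti] > lo[ti]:
                matrix[si, ti] = cs.intensities[lo[ti]:hi[ti]].sum()
    # duplicate RTs (ties on the grid) would break strict monotonicity
    keep = np.concatenate([[True], np.diff(rts) > 0])
    return [Chromatogram(target_mz=float(t), mz_tolerance=config.mz_tolerance,
                         rts=rts[keep], intensities=matrix[keep, ti],
                         run_id=run.run_id)
            for ti, t in enumerate(targets)]


# ---------------------------------------------------------------------------
# integration

def integrate_area(chrom: Chromatogram, rt_start: float,
                   rt_end: float) -> float:
    """Trapezoidal peak area over [rt_start, rt_end] in intensity-minutes.

    Bounds may fall between scans; the trace is linearly interpolated at the
    exact bounds so the integral is additive over adjacent intervals.
    """
    if rt_start >= rt_end:
        raise RangeError("rt_start must be below rt_end")
    if rt_start < chrom.rts[0] - 1e-12 or rt_end > chrom.rts[-1] + 1e-12:
        raise RangeError(
            f"bounds [{rt_start}, {rt_end}] outside the chromatogram span "
            f"[{chrom.rts[0]}, {chrom.rts[-1]}]")
    inner = (chrom.rts > rt_start) & (chrom.rts < rt_end)
    xs = np.concatenate([[rt_start], chrom.rts[inner], [rt_end]])
    ys = np.interp(xs, chrom.rts, chrom.intensities)
    return float(np.trapezoid(ys, xs))


# ---------------------------------------------------------------------------
# deconvolution

def _local_minima(y: np.ndarray) -> List[int]:
    """Interior local minima; plateau minima yield their leftmost index."""
    mins = []
    n = len(y)
    k = 1
    while k < n - 1:
        if y[k] > y[k - 1]:
            k += 1
            continue
        j = k
        while j < n - 1 and y[j + 1] == y[k]:
            j += 1
        if y[k] < y[k - 1] and j < n - 1 and y[j + 1] > y[k]:
            mins.append(k)
        k = j + 1
    return mins


def deconvolve(chrom: Chromatogram,
               config: ProcessingConfig) -> List[Peak]:
    """Split an EIC into peaks at local-minimum border points.

    Borders are local minima of the (optionally smoothed) trace; a minimum is
    kept only while its intensity is at most ``min_valley_ratio`` times the
    smaller of the two adjacent apex heights, which suppresses noise-induced
    over-segmentation.  Heights, apexes and areas are measured on the raw
    trace; plateau apexes take the leftmost scan.
    """
    n = len(chrom.rts)
    if n < 3:
        raise LcquantError("chromatogram too short to deconvolve")
    raw = chrom.intensities
    work = raw
    if config.sg_window and n >= config.sg_window:
        work = smooth_sg(raw, config.sg_window, config.sg_order)
    borders = _local_minima(work)
    edges = [0] + borders + [n - 1]
    # iteratively drop the shallowest-valley violation until all borders
    # satisfy the depth rule (apex heights change as segments merge)
    while True:
        interior = edges[1:-1]
        if not interior:
            break
        apexes = [work[a:b + 1].max()
                  for a, b in zip(edges[:-1], edges[1:])]
        worst, worst_excess = None, 0.0
        for bi, b in enumerate(interior):
            limit = config.min_valley_ratio * min(apexes[bi], apexes[bi + 1])
            if work[b] > limit:
                excess = work[b] - limit
                if worst is None or excess > worst_excess:
                    worst, worst_excess = bi, excess
        if worst is None:
            break
        edges.pop(worst + 1)
    peaks = []
    for a, b in zip(edges[:-1], edges[1:]):
        seg = raw[a:b + 1]
        height = float(seg.max())
        if height <= 0 or height < config.min_peak_height:
            continue
        apex = a + int(np.argmax(seg))
        # a segment whose maximum sits on a shared border is the tail of the
        # neighbouring peak, not a peak of its own
        if (apex == a and a != 0) or (apex == b and b != n - 1):
            continue
        peaks.append(Peak(apex_rt=float(chrom.rts[apex]),
                          rt_start=float(chrom.rts[a]),
                          rt_end=float(chrom.rts[b]),
                          height=height,
                          area=integrate_area(chrom, chrom.rts[a],
                                              chrom.rts[b]),
                          target_mz=chrom.target_mz,
                          run_id=chrom.run_id))
    return peaks
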
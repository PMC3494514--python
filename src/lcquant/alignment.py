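"""Retention-time alignment and peak suggestion.

LC retention times drift between runs, and the drift is generally non-linear,
so a constant-offset correction is not enough.  Drift is modelled here as a
warp rt_sample = f(rt_reference) from the family {identity, linear,
quadratic} — quadratic being the smallest non-linear family whose
monotonicity can be checked in closed form — and fitted robustly with RANSAC:
candidate (reference, sample) peak pairs inevitably include wrong matches,
and a least-squares fit would be dragged by them.

Given a fitted warp, the suggested peak for a metabolite is the one whose
apex lies nearest to the predicted RT inside a search window.  Nearest, not
highest: the correct peak for a low-abundance analyte is often small.  The
converse failure mode — snapping to a baseline blip while a taller, correct
peak sits nearby — is exactly what the ``flag_not_highest`` red flag marks
for visual review.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .errors import RangeError
from .preprocess import Chromatogram, Peak, integrate_area

logger = logging.getLogger(__name__)

_MIN_PAIRS = {"quadratic": 3, "linear": 2}


@dataclass
class RTWarp:
    """A fitted reference->sample retention-time mapping."""

    model: str                       # "identity" | "linear" | "quadratic"
    coefficients: np.ndarray         # highest degree first (polyval order)
    inlier_pairs: List[Tuple[float, float]] = field(default_factory=list)
    rmse: float = 0.0
    n_candidates: int = 0

    def __call__(self, rt):
        if self.model == "identity":
            return rt
        return np.polyval(self.coefficients, rt)


@dataclass
class PeakSuggestion:
    """The automatic peak pick for one metabolite in one run, with red flags."""

    peak: Optional[Peak]
    predicted_rt: float
    flag_not_highest: bool = False
    flag_out_of_window: bool = False


def identity_warp() -> RTWarp:
    return RTWarp(model="identity", coefficients=np.array([1.0, 0.0]))


# ---------------------------------------------------------------------------
# candidate pairing and RANSAC

def candidate_pairs(reference_peaks: Sequence[Tuple[float, float]],
                    sample_peaks: Sequence[Peak],
                    rt_pre_tolerance: float,
                    mz_tolerance: float) -> List[Tuple[float, float]]:
    """All (rt_ref, rt_sample) pairs matching in m/z and coarse RT.

    One reference may pair with several sample peaks (and vice versa); RANSAC
    is what sorts the correct correspondence out of the over-complete set.
    """
    pairs = []
    for ref_mz, ref_rt in reference_peaks:
        for p in sample_peaks:
            if (abs(p.target_mz - ref_mz) <= mz_tolerance
                    and abs(p.apex_rt - ref_rt) <= rt_pre_tolerance):
                pairs.append((ref_rt, p.apex_rt))
    return pairs


def _monotone_on(coeffs: np.ndarray, lo: float, hi: float) -> bool:
    deriv = np.polyder(coeffs)
    if len(deriv) == 1:          # linear warp: constant slope
        return deriv[0] > 0
    return np.polyval(deriv, lo) > 0 and np.polyval(deriv, hi) > 0


def _fit_poly(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    return np.polyfit(x, y, degree)


def fit_rt_warp(reference_peaks: Sequence[Tuple[float, float]],
                sample_peaks: Sequence[Peak],
                rt_pre_tolerance: float = 1.0,
                mz_tolerance: float = 0.1,
                iterations: int = 1000,
                inlier_threshold: float = 0.05,
                seed: int = 0) -> RTWarp:
    """Fit the RT warp by RANSAC over candidate peak pairs.

    Repeatedly fits the model on a random minimal pair set and counts pairs
    within ``inlier_threshold`` of the prediction; the consensus-maximal
    model is refit by least squares on all its inliers.  Too few candidate
    pairs degrade the model quadratic -> linear -> identity with a warning
    rather than failing — a run with no usable landmarks still gets the
    identity alignment.  Deterministic for a given seed.
    """
    pairs = candidate_pairs(reference_peaks, sample_peaks,
                            rt_pre_tolerance, mz_tolerance)
    n = len(pairs)
    degree = 2 if n >= _MIN_PAIRS["quadratic"] else (
        1 if n >= _MIN_PAIRS["linear"] else 0)
    if degree == 0:
        logger.warning("only %d candidate pair(s); identity alignment", n)
        warp = identity_warp()
        warp.n_candidates = n
        warp.inlier_pairs = list(pairs)
        return warp
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    distinct = len(np.unique(x))
    if distinct <= degree:
        degree = 1 if distinct >= 2 else 0
        logger.warning("rank-deficient candidate set; degraded to degree %d",
                       degree)
        if degree == 0:
            warp = identity_warp()
            warp.n_candidates = n
            return warp
    rng = np.random.default_rng(seed)
    minimal = degree + 1
    best_mask = None
    best_count = -1
    best_sse = np.inf
    for _ in range(iterations):
        idx = rng.choice(n, size=minimal, replace=False)
        if len(np.unique(x[idx])) < minimal:
            continue
        try:
            coeffs = _fit_poly(x[idx], y[idx], degree)
        except np.linalg.LinAlgError:
            continue
        resid = np.abs(np.polyval(coeffs, x) - y)
        mask = resid <= inlier_threshold
        count = int(mask.sum())
        sse = float((resid[mask] ** 2).sum())
        if count > best_count or (count == best_count and sse < best_sse):
            best_count, best_sse, best_mask = count, sse, mask
    if best_mask is None or best_count < minimal:
        logger.warning("RANSAC found no consensus; identity alignment")
        warp = identity_warp()
        warp.n_candidates = n
        return warp
    coeffs = _fit_poly(x[best_mask], y[best_mask], degree)
    lo, hi = float(x.min()), float(x.max())
    if degree == 2 and not _monotone_on(coeffs, lo, hi):
        logger.warning("quadratic warp non-monotone on [%.2f, %.2f]; "
                       "falling back to linear", lo, hi)
        degree = 1
        coeffs = _fit_poly(x[best_mask], y[best_mask], degree)
    if degree == 1 and coeffs[0] <= 0:
        logger.warning("linear warp has non-positive slope; identity")
        warp = identity_warp()
        warp.n_candidates = n
        return warp
    resid = np.polyval(coeffs, x[best_mask]) - y[best_mask]
    return RTWarp(model="quadratic" if degree == 2 else "linear",
                  coefficients=coeffs,
                  inlier_pairs=[(float(a), float(b)) for a, b
                                in zip(x[best_mask], y[best_mask])],
                  rmse=float(np.sqrt(np.mean(resid ** 2))),
                  n_candidates=n)


# ---------------------------------------------------------------------------
# suggestion and manual override

def suggest_peak(metabolite_rt: float, warp: RTWarp,
                 peaks: Sequence[Peak], rt_window: float) -> PeakSuggestion:
    """Suggest the peak nearest to the warped expected RT within a window.

    ``flag_not_highest`` is raised when a taller peak than the suggestion
    also sits in the window; ``flag_out_of_window`` when the window is empty.
    Independent of the order of ``peaks``; exact RT ties go to the taller
    candidate, then the earlier one.
    """
    if rt_window <= 0:
        raise RangeError("rt_window must be positive")
    predicted = float(warp(metabolite_rt))
    in_window = [p for p in peaks if abs(p.apex_rt - predicted) <= rt_window]
    if not in_window:
        return PeakSuggestion(peak=None, predicted_rt=predicted,
                              flag_out_of_window=True)
    chosen = min(in_window, key=lambda p: (abs(p.apex_rt - predicted),
                                           -p.height, p.apex_rt))
    not_highest = any(p.height > chosen.height for p in in_window)
    return PeakSuggestion(peak=chosen, predicted_rt=predicted,
                          flag_not_highest=not_highest)


def override_selection(suggestion: PeakSuggestion,
                       manual_bounds: Tuple[float, float],
                       chrom: Chromatogram) -> Peak:
    """Replace an automatic pick with manually integrated bounds.

    Returns a Peak flagged ``manual`` whose area is the trapezoidal integral
    over the given bounds and whose height is the raw-trace maximum inside
    them; the analyst's correction for mis-deconvolved or missed peaks.
    """
    rt_start, rt_end = manual_bounds
    area = integrate_area(chrom, rt_start, rt_end)  # validates the bounds
    inside = (chrom.rts >= rt_start) & (chrom.rts <= rt_end)
    if inside.any():
        seg = chrom.intensities[inside]
        height = float(seg.max())
        apex_rt = float(chrom.rts[inside][int(np.argmax(seg))])
    else:   # bounds between two scans: interpolate
        height = float(max(np.interp([rt_start, rt_end],
                                     chrom.rts, chrom.intensities)))
        apex_rt = rt_start
    return Peak(apex_rt=apex_rt, rt_start=float(rt_start),
                rt_end=float(rt_end), height=height, area=area,
                target_mz=chrom.target_mz, run_id=chrom.run_id, manual=True)
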
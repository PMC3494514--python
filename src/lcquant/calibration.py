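"""Calibration-curve fitting, internal-standard normalization and inversion.

Six regression families relate peak area A to concentration C (umol/L):

    linear       A = a0 + a1*C
    logarithmic  A = a0 + a1*ln(C)
    power        A = a0 * C**a1
    exponential  A = a0 * a1**C
    quadratic    A = a0 + a1*C + a2*C^2
    cubic        A = a0 + a1*C + a2*C^2 + a3*C^3

All fits minimise the sum of squared residuals on the area scale.  The three
polynomial families and the logarithmic family are linear in their
parameters and solved directly; power and exponential are initialised by
log-linearisation and refined by non-linear least squares on the area scale
(the log-scale fit alone would minimise relative, not absolute, error).

The theoretical minimum number of standards equals the parameter count:
two for every family except quadratic (three) and cubic (four).  Six
non-zero standards covering the expected range remain the recommendation,
so fits on fewer log a warning.  When an internal standard is defined, all
areas — standards and samples alike — are divided by the IS area of their
run before any fitting, cancelling injection and ionisation variability.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import DomainError, FitError, InversionError, NormalizationError

logger = logging.getLogger(__name__)

FAMILIES = ("linear", "logarithmic", "power", "exponential",
            "quadratic", "cubic")

#: Minimum number of standard levels (distinct concentrations) per family.
MIN_STANDARDS = {"linear": 2, "logarithmic": 2, "power": 2,
                 "exponential": 2, "quadratic": 3, "cubic": 4}

#: Free parameters per family, used by the parsimony tie-break.
PARAM_COUNT = {"linear": 2, "logarithmic": 2, "power": 2,
               "exponential": 2, "quadratic": 3, "cubic": 4}

#: Families requiring strictly positive concentrations.
_POSITIVE_C = {"logarithmic", "power"}

RECOMMENDED_STANDARDS = 6


@dataclass
class StandardLevel:
    """One standard point: known concentration and measured (possibly
    IS-normalized) peak area."""

    concentration: float   # umol/L
    area: float            # intensity*minutes, or dimensionless if normalized


@dataclass
class CalibrationCurve:
    """A fitted area-vs-concentration regression of one family."""

    family: str
    a0: float
    a1: float
    a2: float = 0.0
    a3: float = 0.0
    r_squared: float = float("nan")
    c_min: float = 0.0
    c_max: float = 0.0
    n_standards: int = 0
    is_normalized: bool = False
    r_squared_log: Optional[float] = None   # log-scale R2 for power/exp fits

    def predict(self, concentration):
        """Predicted area at a concentration (vectorised)."""
        c = np.asarray(concentration, dtype=float)
        if self.family == "linear":
            a = self.a0 + self.a1 * c
        elif self.family == "logarithmic":
            a = self.a0 + self.a1 * np.log(c)
        elif self.family == "power":
            a = self.a0 * c ** self.a1
        elif self.family == "exponential":
            a = self.a0 * self.a1 ** c
        elif self.family == "quadratic":
            a = self.a0 + self.a1 * c + self.a2 * c ** 2
        elif self.family == "cubic":
            a = (self.a0 + self.a1 * c + self.a2 * c ** 2
                 + self.a3 * c ** 3)
        else:
            raise FitError(f"unknown family {self.family!r}")
        return float(a) if np.isscalar(concentration) else a

    @property
    def coefficients(self) -> Tuple[float, ...]:
        k = PARAM_COUNT[self.family]
        return (self.a0, self.a1, self.a2, self.a3)[:k]


def normalize_is(analyte_area: float, is_area: float,
                 run_id: str = "") -> float:
    """Divide an analyte area by the internal-standard area of the same run."""
    if is_area <= 0:
        raise NormalizationError(
            f"internal-standard area is {is_area} in run {run_id or '<?>'}; "
            f"cannot normalize")
    return analyte_area / is_area


# ---------------------------------------------------------------------------
# fitting

def _r_squared(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res < 1e-30 else float("-inf")
    return 1.0 - ss_res / ss_tot


def fit_calibration(family: str, standards: Sequence[StandardLevel],
                    is_normalized: bool = False,
                    weighting: Optional[str] = None) -> CalibrationCurve:
    """Least-squares fit of one curve family to standard points.

    ``weighting`` may be ``None`` (unweighted, the default), ``"1/C"`` or
    ``"1/C2"`` for the inverse-concentration weights common in bioanalytical
    validation.  Zero-concentration standards are silently invalid only for
    the logarithmic and power families, where the caller is expected to have
    excluded them; here they raise a domain error.
    """
    if family not in FAMILIES:
        raise FitError(f"unknown family {family!r}")
    pts = [(s.concentration, s.area) for s in standards
           if np.isfinite(s.area)]
    if family in _POSITIVE_C and any(c <= 0 for c, _ in pts):
        raise DomainError(
            f"{family} fit requires strictly positive concentrations")
    c = np.array([p[0] for p in pts])
    a = np.array([p[1] for p in pts])
    n_distinct = len(np.unique(c))
    need = MIN_STANDARDS[family]
    if n_distinct < need:
        raise FitError(
            f"{family} fit needs at least {need} distinct standard "
            f"concentrations, got {n_distinct}")
    if len(pts) < RECOMMENDED_STANDARDS:
        logger.warning("%s fit on %d standards; %d non-zero standards "
                       "covering the range are recommended",
                       family, len(pts), RECOMMENDED_STANDARDS)
    if weighting is None:
        w = np.ones_like(c)
    elif weighting == "1/C":
        w = 1.0 / c
    elif weighting == "1/C2":
        w = 1.0 / c ** 2
    else:
        raise FitError(f"unknown weighting {weighting!r}")
    sw = np.sqrt(w)

    coeffs = _fit_family(family, c, a, sw)
    curve = CalibrationCurve(family=family, **coeffs,
                             c_min=float(c.min()), c_max=float(c.max()),
                             n_standards=len(pts),
                             is_normalized=is_normalized)
    curve.r_squared = _r_squared(a, np.asarray(curve.predict(c)))
    return curve


def _lin_lstsq(design: np.ndarray, target: np.ndarray,
               sw: np.ndarray) -> np.ndarray:
    sol, _, rank, _ = np.linalg.lstsq(design * sw[:, None], target * sw,
                                      rcond=None)
    if rank < design.shape[1]:
        raise FitError("singular design matrix (duplicate or collinear "
                       "standard concentrations)")
    return sol


def _fit_family(family: str, c: np.ndarray, a: np.ndarray,
                sw: np.ndarray) -> dict:
    if family in ("linear", "quadratic", "cubic"):
        degree = {"linear": 1, "quadratic": 2, "cubic": 3}[family]
        design = np.vander(c, degree + 1, increasing=True)
        sol = _lin_lstsq(design, a, sw)
        return {f"a{i}": float(v) for i, v in enumerate(sol)}
    if family == "logarithmic":
        design = np.column_stack([np.ones_like(c), np.log(c)])
        sol = _lin_lstsq(design, a, sw)
        return {"a0": float(sol[0]), "a1": float(sol[1])}
    # power / exponential: log-linearised start, refined on the area scale
    positive = a > 0
    if positive.sum() < 2:
        raise FitError(f"{family} fit needs >= 2 positive areas")
    la = np.log(a[positive])
    if family == "power":
        x = np.log(c[positive])
        model = lambda p, cc: p[0] * cc ** p[1]
    else:
        x = c[positive]
        model = lambda p, cc: p[0] * p[1] ** cc
    design = np.column_stack([np.ones_like(x), x])
    sol, _, rank, _ = np.linalg.lstsq(design, la, rcond=None)
    if rank < 2:
        raise FitError("singular design matrix for log-linearised fit")
    if family == "power":
        p0 = [math.exp(sol[0]), sol[1]]
    else:
        p0 = [math.exp(sol[0]), math.exp(sol[1])]
    r2_log = _r_squared(la, design @ sol)

    def residuals(p):
        return (model(p, c) - a) * sw

    fit = least_squares(residuals, p0, method="lm", max_nfev=10000)
    a0, a1 = (float(v) for v in fit.x)
    if a0 <= 0:
        raise FitError(f"{family} fit converged to non-positive a0={a0}; "
                       f"curve not invertible")
    return {"a0": a0, "a1": a1, "r_squared_log": r2_log}


# ---------------------------------------------------------------------------
# model selection

_PARSIMONY_ORDER = {"linear": 0, "logarithmic": 1, "power": 2,
                    "exponential": 3, "quadratic": 4, "cubic": 5}


def suggest_best_fit(curves: Sequence[CalibrationCurve],
                     tie_tolerance: float = 1e-4) -> str:
    """Pick the family with the best fit.

    Ranks by R^2; families within ``tie_tolerance`` of the best are tied and
    the tie goes to the fewest parameters (then to a fixed family order), so
    a perfectly linear curve is not reported as a degenerate cubic.
    """
    if not curves:
        raise FitError("no fitted curves to choose from")
    best_r2 = max(cv.r_squared for cv in curves)
    tied = [cv for cv in curves if best_r2 - cv.r_squared <= tie_tolerance]
    winner = min(tied, key=lambda cv: (PARAM_COUNT[cv.family],
                                       _PARSIMONY_ORDER[cv.family]))
    return winner.family


# ---------------------------------------------------------------------------
# inversion

def invert(curve: CalibrationCurve, area: float) -> Tuple[float, bool]:
    """Invert a calibration curve: area -> (concentration, extrapolated).

    Closed forms for the four two-parameter families; root selection within
    the calibration range for the quadratic; bracketed numeric root-finding
    on the monotone branch for the cubic.  ``extrapolated`` is true when the
    concentration falls outside [c_min, c_max].
    """
    f = curve.family
    if f == "linear":
        if curve.a1 == 0:
            raise InversionError("flat linear curve (a1 == 0)")
        conc = (area - curve.a0) / curve.a1
    elif f == "logarithmic":
        if curve.a1 == 0:
            raise InversionError("flat logarithmic curve (a1 == 0)")
        conc = math.exp((area - curve.a0) / curve.a1)
    elif f == "power":
        if curve.a0 <= 0 or curve.a1 == 0:
            raise InversionError("power curve not invertible")
        ratio = area / curve.a0
        if ratio <= 0:
            raise DomainError("area/a0 must be positive to invert a power "
                              "curve")
        conc = ratio ** (1.0 / curve.a1)
    elif f == "exponential":
        if curve.a0 <= 0 or curve.a1 <= 0 or curve.a1 == 1.0:
            raise InversionError("exponential curve not invertible")
        ratio = area / curve.a0
        if ratio <= 0:
            raise DomainError("area/a0 must be positive to invert an "
                              "exponential curve")
        conc = math.log(ratio) / math.log(curve.a1)
    elif f == "quadratic":
        conc = _invert_quadratic(curve, area)
    elif f == "cubic":
        conc = _invert_cubic(curve, area)
    else:
        raise InversionError(f"unknown family {f!r}")
    # tolerance keeps floating-point round-off at the range ends unflagged
    tol = 1e-9 * max(1.0, abs(curve.c_max))
    extrapolated = conc < curve.c_min - tol or conc > curve.c_max + tol
    return float(conc), extrapolated


def _invert_quadratic(curve: CalibrationCurve, area: float) -> float:
    if curve.a2 == 0:
        return (area - curve.a0) / curve.a1 if curve.a1 else _raise_flat()
    roots = np.roots([curve.a2, curve.a1, curve.a0 - area])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    if not real:
        raise InversionError(
            f"no real root of the quadratic at area {area}")
    in_range = [r for r in real if curve.c_min <= r <= curve.c_max]
    if in_range:
        # if both roots land in range the curve is not injective there;
        # take the smaller (ascending-branch) root
        return min(in_range)
    def dist(r):
        return max(curve.c_min - r, r - curve.c_max, 0.0)
    return min(real, key=dist)


def _raise_flat():
    raise InversionError("flat quadratic curve (a1 == a2 == 0)")


def _invert_cubic(curve: CalibrationCurve, area: float) -> float:
    lo, hi = 0.0, max(2.0 * curve.c_max, curve.c_max + 1.0)

    def f(cc):
        return curve.predict(cc) - area

    # restrict to the monotone branch covering the calibration range:
    # stationary points of the cubic bound it
    deriv_roots = np.roots([3 * curve.a3, 2 * curve.a2, curve.a1]) \
        if curve.a3 else np.roots([2 * curve.a2, curve.a1]) \
        if curve.a2 else np.array([])
    cuts = sorted({lo, hi} | {float(r.real) for r in np.atleast_1d(deriv_roots)
                              if abs(r.imag) < 1e-9 and lo < r.real < hi})
    segments = list(zip(cuts[:-1], cuts[1:]))
    mid = 0.5 * (curve.c_min + curve.c_max)
    # prefer the segment containing the calibration midpoint
    segments.sort(key=lambda seg: 0 if seg[0] <= mid <= seg[1] else 1)
    for a_, b_ in segments:
        fa, fb = f(a_), f(b_)
        if fa == 0:
            return a_
        if fb == 0:
            return b_
        if fa * fb < 0:
            return float(brentq(f, a_, b_, xtol=1e-12, rtol=1e-12))
    raise InversionError(
        f"no root of the cubic in [0, {hi:.3g}] at area {area}")
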
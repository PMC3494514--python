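"""Synthetic LC-MS projects with known ground truth.

Runs are simulated as Gaussian chromatographic peaks on a uniform scan grid,
rendered into profile-mode spectra with a three-point m/z support per stick,
plus a constant baseline, white Gaussian detector noise, and Poisson-placed
spurious baseline peaks.  Run-to-run retention-time drift is a monotone
quadratic warp rt' = b0 + b1*rt + b2*rt^2 — the non-linear LC drift that
motivates warp-based alignment.  Each simulated peak's area follows the
metabolite's ground-truth calibration family, so recovered concentrations
can be compared against the simulated truth at every stage.

What this emulates: chromatographic drift, detector noise, baseline blips
near true peaks.  What it does not: peak tailing, ion suppression between
co-eluting analytes, isotope envelopes, or m/z miscalibration — conclusions
about those failure modes cannot be drawn from these fixtures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import Metabolite, quant_ion_mz
from .errors import LcquantError
from .ms_io import Run, Spectrum, write_mzml, write_ion_list
from .preprocess import ProcessingConfig

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass
class SimMetabolite:
    """Ground truth for one simulated compound."""

    name: str
    quant_mz: float
    true_rt: float                  # minutes, in reference coordinates
    peak_sigma: float = 0.11        # minutes (~15 s FWHM, typical LC)
    curve_family: str = "linear"
    curve_coeffs: Tuple[float, ...] = (0.0, 3000.0)  # a0, a1[, a2[, a3]]
    is_internal_standard: bool = False

    def truth_area(self, concentration: float) -> float:
        """Peak area implied by the ground-truth calibration family."""
        a = list(self.curve_coeffs) + [0.0] * (4 - len(self.curve_coeffs))
        c = concentration
        fam = self.curve_family
        if fam == "linear":
            return a[0] + a[1] * c
        if fam == "logarithmic":
            return a[0] + a[1] * math.log(c)
        if fam == "power":
            return a[0] * c ** a[1]
        if fam == "exponential":
            return a[0] * a[1] ** c
        if fam == "quadratic":
            return a[0] + a[1] * c + a[2] * c ** 2
        if fam == "cubic":
            return a[0] + a[1] * c + a[2] * c ** 2 + a[3] * c ** 3
        raise LcquantError(f"unknown curve family {fam!r}")


@dataclass
class SimSpec:
    """Full description of a simulated acquisition campaign."""

    metabolites: List[SimMetabolite]
    rt_span: float = 20.0
    scan_interval: float = 0.05
    baseline: float = 0.0
    noise_sd: float = 0.0
    spurious_rate: float = 0.0      # spurious peaks per minute per run
    mz_support: float = 0.012       # profile half-spacing around each stick
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_interval <= 0:
            raise LcquantError("scan_interval must be positive")
        for m in self.metabolites:
            if m.peak_sigma <= 2 * self.scan_interval:
                raise LcquantError(
                    f"{m.name}: peak_sigma must exceed twice the scan "
                    f"interval for the peak to be resolvable")


def apply_warp(rt, coeffs: Tuple[float, float, float]):
    """Evaluate the drift warp rt' = b0 + b1*rt + b2*rt^2."""
    b0, b1, b2 = coeffs
    return b0 + b1 * rt + b2 * rt ** 2


def check_monotone_warp(coeffs: Tuple[float, float, float],
                        rt_span: float) -> None:
    b0, b1, b2 = coeffs
    if b1 <= 0 or b1 + 2 * b2 * rt_span <= 0:
        raise LcquantError(f"warp {coeffs} is not monotone on "
                           f"[0, {rt_span}]")


IDENTITY_DRIFT = (0.0, 1.0, 0.0)


def simulate_run(spec: SimSpec, run_id: str,
                 concentrations: Dict[str, float],
                 drift: Tuple[float, float, float] = IDENTITY_DRIFT,
                 run_index: int = 0) -> Tuple[Run, pd.DataFrame]:
    """Simulate one LC-MS run and its ground-truth peak table.

    Each metabolite with a positive concentration contributes a Gaussian
    peak at ``warp(true_rt)`` whose area follows its truth calibration
    family.  Noise is drawn from a generator seeded by ``(spec.seed,
    run_index)``, so runs are reproducible individually and campaigns as a
    whole.  The truth table lists every placed peak (true and spurious) with
    its RT, height, area and m/z.
    """
    check_monotone_warp(drift, spec.rt_span)
    rng = np.random.default_rng((spec.seed, run_index))
    rts = np.arange(0.0, spec.rt_span, spec.scan_interval)
    n_scans = len(rts)
    mets = spec.metabolites
    n_mets = len(mets)
    traces = np.zeros((n_scans, n_mets))
    truth_rows = []
    true_heights = []
    for mi, m in enumerate(mets):
        conc = concentrations.get(m.name, 0.0)
        if conc <= 0:
            continue
        area = m.truth_area(conc)
        height = area / (m.peak_sigma * _SQRT_2PI)
        apex = float(apply_warp(m.true_rt, drift))
        traces[:, mi] += height * np.exp(
            -0.5 * ((rts - apex) / m.peak_sigma) ** 2)
        true_heights.append(height)
        truth_rows.append(dict(metabolite=m.name, quant_mz=m.quant_mz,
                               apex_rt=apex, height=height, area=area,
                               concentration=conc, kind="true"))
    if spec.spurious_rate > 0 and true_heights:
        ceiling = float(np.percentile(true_heights, 25))
        n_spurious = rng.poisson(spec.spurious_rate * spec.rt_span)
        for _ in range(n_spurious):
            mi = int(rng.integers(n_mets))
            m = mets[mi]
            apex = float(rng.uniform(0.5, spec.rt_span - 0.5))
            height = float(np.exp(rng.uniform(np.log(0.02 * ceiling),
                                              np.log(ceiling))))
            traces[:, mi] += height * np.exp(
                -0.5 * ((rts - apex) / m.peak_sigma) ** 2)
            truth_rows.append(dict(metabolite=m.name, quant_mz=m.quant_mz,
                                   apex_rt=apex, height=height,
                                   area=height * m.peak_sigma * _SQRT_2PI,
                                   concentration=np.nan, kind="spurious"))
    # render profile spectra: three m/z points per metabolite stick
    order = np.argsort([m.quant_mz for m in mets])
    mz_template = np.concatenate(
        [[mets[mi].quant_mz - spec.mz_support, mets[mi].quant_mz,
          mets[mi].quant_mz + spec.mz_support] for mi in order])
    if np.any(np.diff(mz_template) <= 0):
        raise LcquantError("metabolite quantifier ions too close for the "
                           "profile m/z support; increase their spacing")
    weights = np.array([0.5, 1.0, 0.5])
    point_values = np.repeat(traces[:, order], 3, axis=1) \
        * np.tile(weights, n_mets)
    point_values = point_values + spec.baseline
    if spec.noise_sd > 0:
        point_values = point_values + rng.normal(
            0.0, spec.noise_sd, size=point_values.shape)
    np.clip(point_values, 0.0, None, out=point_values)
    spectra = [Spectrum(rt=float(rts[si]), mz_values=mz_template.copy(),
                        intensities=point_values[si], mode="profile")
               for si in range(n_scans)]
    run = Run(spectra=spectra, format="mzml", run_id=run_id)
    return run, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# scenarios

#: One representative truth-coefficient set per calibration family, chosen so
#: areas stay positive and well-conditioned over the standard range 5-100.
_FAMILY_COEFFS = {
    "linear": (0.0, 3000.0),
    "logarithmic": (10000.0, 40000.0),
    "power": (800.0, 1.5),
    "exponential": (20000.0, 1.03),
    "quadratic": (0.0, 2500.0, 12.0),
    "cubic": (0.0, 2400.0, 10.0, 0.08),
}

#: Six non-zero standard levels covering the working range (umol/L).
STANDARD_LEVELS = (5.0, 10.0, 20.0, 40.0, 70.0, 100.0)

SCENARIOS = ("linear_small", "six_family", "crowded_baseline", "paper_scale")


@dataclass
class ProjectTruth:
    """Everything the simulator knows that the pipeline must recover."""

    spec: SimSpec
    drifts: Dict[str, Tuple[float, float, float]]
    sample_truth: pd.DataFrame          # metabolite x sample concentrations
    peak_truth: Dict[str, pd.DataFrame]  # run_id -> placed-peak table


def _spread_mzs(names: Sequence[str], start: float = 90.0,
                step: float = 4.517) -> List[float]:
    return [round(start + i * step, 3) for i in range(len(names))]


def _monotone_drift(rng: np.random.Generator, rt_span: float,
                    amplitude: float = 0.5) -> Tuple[float, float, float]:
    """Random quadratic drift bounded by ``amplitude`` minutes at span end."""
    b2 = float(rng.uniform(-amplitude, amplitude)) / rt_span ** 2
    b1 = float(rng.uniform(0.995, 1.005))
    b0 = float(rng.uniform(-0.1, 0.1))
    if b1 + 2 * b2 * rt_span <= 0.05:
        b2 = 0.0
    return (b0, b1, b2)


def build_sim_spec(scenario: str, seed: int = 0) -> SimSpec:
    """SimSpec for a named scenario (study-condition defaults, not dials)."""
    if scenario == "linear_small":
        mets = [SimMetabolite("met_a", 90.055, 3.0),
                SimMetabolite("met_b", 148.060, 8.0,
                              curve_coeffs=(0.0, 5000.0)),
                SimMetabolite("met_c", 181.071, 14.0,
                              curve_coeffs=(0.0, 1500.0))]
        return SimSpec(metabolites=mets, rt_span=18.0, seed=seed)
    if scenario == "six_family":
        names = list(_FAMILY_COEFFS)
        mzs = _spread_mzs(names)
        mets = [SimMetabolite(f"met_{fam}", mz, 2.0 + 2.8 * i,
                              curve_family=fam,
                              curve_coeffs=_FAMILY_COEFFS[fam])
                for i, (fam, mz) in enumerate(zip(names, mzs))]
        return SimSpec(metabolites=mets, rt_span=20.0, seed=seed)
    if scenario == "crowded_baseline":
        # wide response spread: the weakest analytes sit near the baseline,
        # where spurious blips genuinely compete with the true peak
        names = [f"met_{i}" for i in range(8)]
        mzs = _spread_mzs(names)
        mets = [SimMetabolite(n, mz, 1.5 + 2.2 * i,
                              curve_coeffs=(0.0, 600.0 * (1 + i)))
                for i, (n, mz) in enumerate(zip(names, mzs))]
        spec = SimSpec(metabolites=mets, rt_span=20.0, seed=seed)
        return _with_snr(spec, snr=20.0, spurious_rate=4.0)
    if scenario == "paper_scale":
        names = [f"met_{i:02d}" for i in range(29)]
        mzs = _spread_mzs(names, start=88.0, step=3.913)
        rng = np.random.default_rng(seed)
        rts = np.sort(rng.uniform(1.0, 19.0, size=29))
        # enforce resolvable spacing between neighbouring true RTs
        for i in range(1, 29):
            rts[i] = max(rts[i], rts[i - 1] + 0.35)
        rts = rts / rts[-1] * 19.0
        mets = [SimMetabolite(n, mz, float(rt),
                              curve_coeffs=(0.0,
                                            float(rng.uniform(1500, 6000))))
                for n, mz, rt in zip(names, mzs, rts)]
        spec = SimSpec(metabolites=mets, rt_span=20.0, seed=seed)
        # drift + detector noise only: spurious baseline peaks are the
        # crowded_baseline scenario's stress condition
        return _with_snr(spec, snr=20.0, spurious_rate=0.0)
    raise LcquantError(f"unknown scenario {scenario!r}; "
                       f"choose from {SCENARIOS}")


def _with_snr(spec: SimSpec, snr: float, spurious_rate: float) -> SimSpec:
    """Set the noise floor from the stated signal-to-noise ratio.

    The SNR is referenced to the limiting peak of the campaign — the least
    responsive analyte at the lowest standard level — so the stated SNR
    holds for every quantified peak, not merely the typical one.
    """
    lo = STANDARD_LEVELS[0]
    heights = [m.truth_area(lo) / (m.peak_sigma * _SQRT_2PI)
               for m in spec.metabolites]
    sd = float(min(heights)) / snr
    return replace(spec, noise_sd=sd, baseline=2.0 * sd,
                   spurious_rate=spurious_rate)


def make_project(scenario: str, seed: int = 0,
                 out_dir: Optional[Path] = None,
                 with_internal_standard: bool = False,
                 n_samples: Optional[int] = None):
    """Build a complete synthetic project for a named scenario.

    Returns ``(config, truth)`` where ``config`` is a ready-to-run
    :class:`lcquant.pipeline.ProjectConfig` with in-memory runs and
    ``truth`` is a :class:`ProjectTruth`.  With ``out_dir`` the project is
    additionally materialized on disk: mzML runs, ion list, standards
    design, truth tables.

    Scenario defaults: ``linear_small`` (3 metabolites, 3 standards, 2
    samples, no drift or noise), ``six_family`` (one metabolite per curve
    family, 6 standards, noise-free), ``crowded_baseline`` (8 metabolites,
    drift, SNR 20, one spurious baseline peak per minute), ``paper_scale``
    (29 metabolites, 6 standards, 12 samples, drift, SNR 20).
    """
    from .pipeline import AlignmentParams, ProjectConfig  # cycle-free at call

    spec = build_sim_spec(scenario, seed)
    rng = np.random.default_rng((seed, 987654321))
    if scenario == "linear_small":
        levels = (10.0, 50.0, 100.0)
        n_samples = 2 if n_samples is None else n_samples
        drifted = False
    elif scenario == "six_family":
        levels = STANDARD_LEVELS
        n_samples = 2 if n_samples is None else n_samples
        drifted = False
    elif scenario == "crowded_baseline":
        levels = STANDARD_LEVELS
        n_samples = 6 if n_samples is None else n_samples
        drifted = True
    else:
        levels = STANDARD_LEVELS
        n_samples = 12 if n_samples is None else n_samples
        drifted = True

    if with_internal_standard:
        mz = max(m.quant_mz for m in spec.metabolites) + 9.77
        spec.metabolites.append(SimMetabolite(
            "internal_standard", mz, spec.rt_span - 1.0,
            curve_coeffs=(0.0, 4000.0), is_internal_standard=True))
    analytes = [m for m in spec.metabolites if not m.is_internal_standard]

    standard_ids = [f"std_{i+1}" for i in range(len(levels))]
    sample_ids = [f"sample_{i+1}" for i in range(n_samples)]
    design = {rid: {m.name: float(level) for m in analytes}
              for rid, level in zip(standard_ids, levels)}
    lo, hi = min(levels), max(levels)
    sample_conc = {
        rid: {m.name: float(np.exp(rng.uniform(np.log(1.3 * lo),
                                               np.log(0.85 * hi))))
              for m in analytes}
        for rid in sample_ids}

    drifts: Dict[str, Tuple[float, float, float]] = {}
    runs: Dict[str, Run] = {}
    peak_truth: Dict[str, pd.DataFrame] = {}
    is_conc = 50.0
    for idx, rid in enumerate(standard_ids + sample_ids):
        if idx == 0 or not drifted:
            drift = IDENTITY_DRIFT  # first standard defines the RT frame
        else:
            drift = _monotone_drift(rng, spec.rt_span)
        conc = dict(design.get(rid) or sample_conc[rid])
        if with_internal_standard:
            conc["internal_standard"] = is_conc
        run, truth_df = simulate_run(spec, rid, conc, drift, run_index=idx)
        drifts[rid] = drift
        runs[rid] = run
        peak_truth[rid] = truth_df

    metabolites = [Metabolite(name=m.name, quant_mz=m.quant_mz,
                              expected_rt=m.true_rt,
                              is_internal_standard=m.is_internal_standard)
                   for m in spec.metabolites]
    processing = ProcessingConfig(
        noise_level=spec.baseline + 4.0 * spec.noise_sd
        if spec.noise_sd else 0.0)
    alignment = AlignmentParams(seed=seed)
    if scenario == "crowded_baseline":
        # the crowded fixture searches a wider range so baseline blips fall
        # inside the red-flag window, as they do in crowded real data
        alignment.rt_window = 1.0
    config = ProjectConfig(metabolites=metabolites,
                           standards_design=design,
                           sample_ids=sample_ids,
                           runs=runs,
                           processing=processing,
                           alignment=alignment)
    sample_truth = pd.DataFrame(sample_conc)
    truth = ProjectTruth(spec=spec, drifts=drifts,
                         sample_truth=sample_truth, peak_truth=peak_truth)
    if out_dir is not None:
        _write_project(out_dir, config, truth)
    return config, truth


def _write_project(out_dir, config, truth: ProjectTruth) -> None:
    out = Path(out_dir)
    (out / "runs").mkdir(parents=True, exist_ok=True)
    for rid, run in config.runs.items():
        write_mzml(run, out / "runs" / f"{rid}.mzML")
    write_ion_list(config.metabolites, out / "ion_list.csv")
    pd.DataFrame(config.standards_design).to_csv(out / "standards_design.csv")
    truth.sample_truth.to_csv(out / "sample_truth.csv")
    for rid, df in truth.peak_truth.items():
        df.to_csv(out / "runs" / f"{rid}.truth.csv", index=False)
    (out / "config.txt").write_text(
        "\n".join([f"scenario_seed={truth.spec.seed}",
                   f"scan_interval={truth.spec.scan_interval}",
                   f"noise_sd={truth.spec.noise_sd}",
                   f"baseline={truth.spec.baseline}",
                   f"spurious_rate={truth.spec.spurious_rate}",
                   ""]))
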
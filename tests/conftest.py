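"""Shared fixtures: tiny synthetic runs and chromatograms."""

import numpy as np
import pytest

from lcquant.ms_io import Run, Spectrum
from lcquant.preprocess import Chromatogram, ProcessingConfig


@pytest.fixture
def three_spectrum_run() -> Run:
    """Minimal three-spectrum run at 0.10/0.20/0.30 min."""
    spectra = [
        Spectrum(rt=0.1 * (i + 1),
                 mz_values=np.array([100.0, 150.5, 200.25]),
                 intensities=np.array([10.0, 50.0 + i, 5.0]),
                 mode="centroid")
        for i in range(3)
    ]
    return Run(spectra=spectra, run_id="mini")


def gaussian_chromatogram(apexes, heights, sigma=0.1, span=10.0,
                          dt=0.02, target_mz=100.0, baseline=0.0,
                          noise_sd=0.0, seed=0) -> Chromatogram:
    """Sum-of-Gaussians EIC with optional baseline and white noise."""
    rts = np.arange(0.0, span, dt)
    y = np.full_like(rts, float(baseline))
    for apex, h in zip(np.atleast_1d(apexes), np.atleast_1d(heights)):
        y = y + h * np.exp(-0.5 * ((rts - apex) / sigma) ** 2)
    if noise_sd:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, rts.shape)
        y = np.clip(y, 0.0, None)
    return Chromatogram(target_mz=target_mz, mz_tolerance=0.1,
                        rts=rts, intensities=y, run_id="synthetic")


@pytest.fixture
def single_peak_chrom() -> Chromatogram:
    return gaussian_chromatogram(apexes=5.0, heights=1000.0)


@pytest.fixture
def no_smoothing_config() -> ProcessingConfig:
    return ProcessingConfig(sg_window=0, sg_order=0)
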
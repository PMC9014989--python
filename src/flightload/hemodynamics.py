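"""Canonical double-gamma hemodynamic response function and task regressors.

The HRF here is the standard SPM-style double gamma: a positive gamma density
peaking at 6 s minus a later undershoot peaking at 16 s with a peak/undershoot
amplitude ratio of 6. Regressors are boxcars convolved with this kernel and
peak-normalized so that a sustained task block asymptotes to 1, which puts GLM
β coefficients on the same μM scale as the underlying hemoglobin signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as gamma_dist

from .errors import ConfigurationError

__all__ = ["HRFParams", "canonical_hrf", "task_regressor"]


@dataclass(frozen=True)
class HRFParams:
    peak_s: float = 6.0
    undershoot_s: float = 16.0
    ratio: float = 6.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    duration_s: float = 32.0

    def __post_init__(self):
        if min(self.peak_s, self.undershoot_s, self.ratio, self.dispersion,
               self.undershoot_dispersion, self.duration_s) <= 0:
            raise ConfigurationError("all HRF parameters must be > 0")

    def key(self) -> tuple:
        return (self.peak_s, self.undershoot_s, self.ratio, self.dispersion,
                self.undershoot_dispersion, self.duration_s)


def canonical_hrf(fs: float, params: HRFParams = HRFParams()) -> np.ndarray:
    """Sampled double-gamma HRF kernel at sampling rate ``fs``, max value 1."""
    if fs <= 0:
        raise ConfigurationError("fs must be > 0")
    t = np.arange(0.0, params.duration_s + 1.0 / fs, 1.0 / fs)
    peak = gamma_dist.pdf(t, params.peak_s / params.dispersion, scale=params.dispersion)
    under = gamma_dist.pdf(t, params.undershoot_s / params.undershoot_dispersion,
                           scale=params.undershoot_dispersion)
    h = peak - under / params.ratio
    m = np.max(np.abs(h))
    if m == 0:
        raise ConfigurationError("degenerate HRF kernel")
    return h / m


def task_regressor(onsets, durations, fs: float, n_samples: int,
                   params: HRFParams = HRFParams()) -> np.ndarray:
    """Boxcar(s) convolved with the canonical HRF, peak-normalized.

    Normalization divides by the peak of the response to a sustained boxcar
    (the maximum of the HRF's running integral), so a long task block reaches a
    maximum of exactly 1 shortly after the HRF rise and then settles to a
    plateau slightly below 1 once the undershoot accumulates.
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if durations.size == 1 and onsets.size > 1:
        durations = np.full(onsets.shape, durations[0])
    if onsets.shape != durations.shape:
        raise ConfigurationError("onsets and durations must have matching shapes")
    if np.any(durations < 0):
        raise ConfigurationError("durations must be >= 0")
    box = np.zeros(n_samples)
    for on, dur in zip(onsets, durations):
        i0 = int(round(on * fs))
        i1 = int(round((on + dur) * fs))
        if i0 < 0 or i0 > n_samples:
            raise ConfigurationError(f"onset {on} s outside the run")
        box[i0:min(i1, n_samples)] = 1.0
    h = canonical_hrf(fs, params)
    reg = np.convolve(box, h)[:n_samples]
    peak_gain = float(np.max(np.cumsum(h)))  # peak response to a sustained boxcar
    if peak_gain <= 0:
        raise ConfigurationError("HRF kernel has non-positive sustained-boxcar gain")
    return reg / peak_gain
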
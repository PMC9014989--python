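"""Synthetic physiological signals with known ground truth.

Two generators feed the analysis chain:

* a **tachogram generator** producing RR-interval series whose mean heart
  rate rises with the load step and whose oscillatory structure places known
  power in the LF (≈0.10 Hz, sympathetic-dominated) and HF (≈0.25 Hz,
  parasympathetic/respiratory) bands;
* an **fNIRS forward model** producing ΔHbO/ΔHbR with an HRF-shaped task
  response of known per-channel amplitude β (μM), optional structured noise
  (linear drift, Mayer waves, cardiac pulsation, white noise), and a forward
  modified Beer–Lambert projection to optical density at 760/850 nm.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._streams import rng_from
from .errors import ConfigurationError
from .hemodynamics import HRFParams, task_regressor
from .optics import OpticsConfig
from .series import HemoglobinSeries, OpticalDensitySeries, RRSeries

__all__ = [
    "AutonomicParams", "NoiseModel", "synthesize_rr", "synthesize_activation",
    "add_noise", "mbll_forward",
]


@dataclass(frozen=True)
class AutonomicParams:
    """Tachogram model: mean RR plus LF/HF sinusoids plus white jitter.

    ``load_hr_slope`` is the bpm increase of mean heart rate per load step
    (low→medium→high), the coupling through which mental workload raises HR.
    """

    mean_rr_ms: float = 893.0       # ≈ 67.2 bpm baseline
    lf_amp_ms: float = 35.0
    lf_freq_hz: float = 0.10
    hf_amp_ms: float = 20.0
    hf_freq_hz: float = 0.25
    hf_phase_rad: float = 0.0
    white_sd_ms: float = 30.0
    load_hr_slope: float = 1.2      # bpm per load step

    def __post_init__(self):
        if self.mean_rr_ms <= 0:
            raise ConfigurationError("mean_rr_ms must be > 0")
        if self.lf_amp_ms < 0 or self.hf_amp_ms < 0 or self.white_sd_ms < 0:
            raise ConfigurationError("amplitudes must be >= 0")
        if not (0.04 <= self.lf_freq_hz <= 0.15):
            raise ConfigurationError("lf_freq_hz must lie in [0.04, 0.15] Hz")
        if not (0.15 < self.hf_freq_hz <= 0.40):
            raise ConfigurationError("hf_freq_hz must lie in (0.15, 0.40] Hz")

    def mean_rr_at_load(self, load_step: int) -> float:
        """Load-adjusted mean RR: base HR plus ``load_step`` slope steps."""
        hr = 60000.0 / self.mean_rr_ms + load_step * self.load_hr_slope
        return 60000.0 / hr


def synthesize_rr(params: AutonomicParams, load_step: int = 0,
                  duration_s: float = 180.0, seed: int = 0,
                  condition: str = "") -> RRSeries:
    """Beat sequence RR(t_k) = mean_rr(load) + LF + HF sinusoids + ε.

    Beats accumulate until the cumulative time reaches ``duration_s``; each
    interval is evaluated at the time of its preceding beat.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be > 0")
    if load_step not in (0, 1, 2):
        raise ConfigurationError("load_step must be 0, 1 or 2")
    rng = rng_from(seed, 21)
    mrr = params.mean_rr_at_load(load_step)
    rr = []
    t_ms = 0.0
    while t_ms < duration_s * 1000.0:
        t_s = t_ms / 1000.0
        interval = (
            mrr
            + params.lf_amp_ms * np.sin(2 * np.pi * params.lf_freq_hz * t_s)
            + params.hf_amp_ms * np.sin(2 * np.pi * params.hf_freq_hz * t_s + params.hf_phase_rad)
            + (rng.normal(0.0, params.white_sd_ms) if params.white_sd_ms > 0 else 0.0)
        )
        interval = max(interval, 0.2 * mrr)  # physiological floor against absurd beats
        rr.append(interval)
        t_ms += interval
    return RRSeries.from_intervals(np.asarray(rr), condition=condition)


def synthesize_activation(beta_true, onsets, durations,
                          hrf_params: HRFParams = HRFParams(),
                          fs: float = 2.0, duration_s: float = 240.0,
                          hbr_ratio: float = 1.0 / 3.0,
                          channel_ids=(), condition: str = "") -> HemoglobinSeries:
    """Noise-free hemodynamic response: ΔHbO = β × (boxcar ⊗ HRF) per channel.

    The regressor is peak-normalized so β is the peak ΔHbO in μM; ΔHbR is the
    typical anticorrelated mirror, ``-hbr_ratio`` times ΔHbO.
    """
    if fs <= 0:
        raise ConfigurationError("fs must be > 0")
    beta = np.atleast_1d(np.asarray(beta_true, dtype=float))
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    reg = task_regressor(onsets, durations, fs, n, hrf_params)
    hbo = np.outer(beta, reg)
    return HemoglobinSeries(t_s=t, delta_hbo=hbo, delta_hbr=-hbr_ratio * hbo,
                            channel_ids=tuple(channel_ids), condition=condition)


@dataclass(frozen=True)
class NoiseModel:
    """Additive fNIRS noise: drift + Mayer wave + cardiac pulsation + white.

    Per channel the drift slope is drawn N(0, drift_slope) and the sinusoid
    phases uniformly, from independent seeded streams. At a 2-Hz sampling rate
    a cardiac component above 1 Hz aliases; the generator synthesizes it at
    the aliased frequency ``|f_cardiac - fs·round(f_cardiac/fs)|`` explicitly.
    """

    drift_slope_um_s: float = 0.002
    mayer_amp_um: float = 0.05
    mayer_freq_hz: float = 0.10
    cardiac_amp_um: float = 0.05
    cardiac_freq_hz: float = 1.1
    white_sd_um: float = 0.10

    def __post_init__(self):
        if min(self.drift_slope_um_s, self.mayer_amp_um, self.cardiac_amp_um,
               self.white_sd_um) < 0:
            raise ConfigurationError("noise amplitudes must be >= 0")

    def aliased_cardiac_hz(self, fs: float) -> float:
        return abs(self.cardiac_freq_hz - fs * round(self.cardiac_freq_hz / fs))


def add_noise(hemo: HemoglobinSeries, noise: NoiseModel, seed: int = 0) -> HemoglobinSeries:
    """Add the structured+white noise model to both chromophores, per channel."""
    t = hemo.t_s
    fs = hemo.fs
    f_card = noise.aliased_cardiac_hz(fs)
    hbo = hemo.delta_hbo.copy()
    hbr = hemo.delta_hbr.copy()
    for i in range(hemo.n_channels):
        rng = rng_from(seed, 31, i)
        slope = rng.normal(0.0, noise.drift_slope_um_s)
        ph_m, ph_c = rng.uniform(0, 2 * np.pi, size=2)
        structured = (
            slope * t
            + noise.mayer_amp_um * np.sin(2 * np.pi * noise.mayer_freq_hz * t + ph_m)
            + noise.cardiac_amp_um * np.sin(2 * np.pi * f_card * t + ph_c)
        )
        white_hbo = rng.normal(0.0, noise.white_sd_um, size=t.size) if noise.white_sd_um > 0 else 0.0
        white_hbr = rng.normal(0.0, noise.white_sd_um, size=t.size) if noise.white_sd_um > 0 else 0.0
        hbo[i] += structured + white_hbo
        hbr[i] += -structured / 3.0 + white_hbr
    return HemoglobinSeries(t_s=t, delta_hbo=hbo, delta_hbr=hbr,
                            channel_ids=hemo.channel_ids, condition=hemo.condition)


def mbll_forward(hemo: HemoglobinSeries, optics: OpticsConfig = OpticsConfig()) -> OpticalDensitySeries:
    """Forward modified Beer–Lambert law: concentrations (μM) → ΔOD per wavelength."""
    A = optics.system_matrix()  # wavelengths x (HbO, HbR)
    conc = np.stack([hemo.delta_hbo, hemo.delta_hbr], axis=1)  # ch x 2 x samples
    od = np.einsum("wc,kcs->kws", A, conc)
    return OpticalDensitySeries(t_s=hemo.t_s, delta_od=od,
                                wavelengths_nm=tuple(optics.wavelengths_nm),
                                channel_ids=hemo.channel_ids, condition=hemo.condition)
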
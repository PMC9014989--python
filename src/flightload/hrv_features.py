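"""Heart-rate-variability features from RR-interval series.

Time domain: mean HR (60000 / mean RR, bpm), SDNN (sample standard deviation
of the RR intervals, ms) and RMSSD (root mean square of successive RR
differences, ms). Frequency domain: LF (0.04–0.15 Hz) and HF (0.15–0.40 Hz)
band powers of the tachogram in ms², estimated with a Lomb–Scargle
periodogram evaluated directly on the uneven beat times (no resampling), and
their ratio LF/HF. An alternative cubic-spline + uniform-resample + Welch
path is available for cross-checking.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import lombscargle, welch

from .errors import DataQualityError, InsufficientDataError
from .series import RRSeries

__all__ = ["LF_BAND", "HF_BAND", "HRVFeatures", "clean_rr", "time_domain",
           "frequency_domain", "extract_features"]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class HRVFeatures:
    mean_hr_bpm: float
    sdnn_ms: float
    rmssd_ms: float
    lf_power_ms2: float
    hf_power_ms2: float
    lf_hf_ratio: Optional[float]  # None when HF power is zero

    def as_dict(self) -> dict:
        return {
            "mean_hr_bpm": self.mean_hr_bpm, "sdnn_ms": self.sdnn_ms,
            "rmssd_ms": self.rmssd_ms, "lf_power_ms2": self.lf_power_ms2,
            "hf_power_ms2": self.hf_power_ms2, "lf_hf_ratio": self.lf_hf_ratio,
        }


def clean_rr(rr: RRSeries, max_rel_jump: float = 0.2):
    """Replace artifactual beats by linear interpolation of their neighbors.

    An interval differing from the previously accepted interval by more than
    ``max_rel_jump`` (relative) is replaced by the mean of the accepted
    previous interval and the next raw interval (or the previous alone at the
    series end). Raises :class:`DataQualityError` when the number of flagged
    beats exceeds ⌈20% of the series length⌉; the ceiling keeps a single
    artifact in a very short record from being fatal.

    Returns ``(cleaned RRSeries, n_replaced)``.
    """
    x = rr.rr_ms.copy()
    if x.size == 0:
        raise InsufficientDataError("empty RR series")
    n_replaced = 0
    ref = x[0]  # last accepted (non-artifact) interval
    for k in range(1, x.size):
        if abs(x[k] - ref) > max_rel_jump * ref:
            nxt = x[k + 1] if k + 1 < x.size else ref
            x[k] = 0.5 * (ref + nxt)
            n_replaced += 1
        else:
            ref = x[k]
    if n_replaced > np.ceil(0.2 * x.size):
        raise DataQualityError(
            f"{n_replaced}/{x.size} beats flagged as artifacts (> 20%)"
        )
    return RRSeries.from_intervals(x, condition=rr.condition), n_replaced


def time_domain(rr: RRSeries):
    """(mean HR bpm, SDNN ms, RMSSD ms); SDNN uses the n−1 denominator."""
    x = rr.rr_ms
    if x.size < 3:
        raise InsufficientDataError("need at least 3 RR intervals")
    mean_hr = 60000.0 / float(np.mean(x))
    sdnn = float(np.std(x, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(x) ** 2)))
    return mean_hr, sdnn, rmssd


def _lomb_psd(rr: RRSeries, freqs_hz: np.ndarray) -> np.ndarray:
    """One-sided tachogram PSD in ms²/Hz at the given frequencies.

    Scaling: for even sampling the Lomb–Scargle power of a sinusoid of
    amplitude A is n·A²/4, while its one-sided PSD integrates to A²/2 over a
    resolution bin of width 1/T; hence PSD = P · 2T/n.
    """
    t = rr.t_ms / 1000.0
    x = rr.rr_ms - np.mean(rr.rr_ms)
    T = t[-1] - t[0]
    power = lombscargle(t, x, 2 * np.pi * freqs_hz)
    return power * 2.0 * T / x.size


def frequency_domain(rr: RRSeries, lf_band=LF_BAND, hf_band=HF_BAND,
                     method: str = "lomb"):
    """(LF power ms², HF power ms², LF/HF or None).

    Bands are half-open [lo, hi) so the shared 0.15-Hz edge is counted once.
    ``method='welch'`` is the cross-check path: cubic-spline interpolation of
    the tachogram onto a 4-Hz grid followed by a Welch periodogram.
    """
    if rr.duration_s < 60.0:
        raise InsufficientDataError("need >= 60 s of RR data for band powers")
    if method == "lomb":
        T = (rr.t_ms[-1] - rr.t_ms[0]) / 1000.0
        df = 1.0 / (4.0 * T)
        freqs = np.arange(df, hf_band[1] + 0.05, df)
        psd = _lomb_psd(rr, freqs)
    elif method == "welch":
        fs = 4.0
        t = rr.t_ms / 1000.0
        grid = np.arange(t[0], t[-1], 1.0 / fs)
        x = CubicSpline(t, rr.rr_ms)(grid)
        x = x - np.mean(x)
        nper = min(x.size, int(fs * 120))
        freqs, psd = welch(x, fs=fs, nperseg=nper)
        df = freqs[1] - freqs[0]
    else:
        raise ValueError(f"unknown method {method!r}")

    def band_power(band):
        lo, hi = band
        mask = (freqs >= lo) & (freqs < hi)
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(psd[mask], freqs[mask]))

    lf = band_power(lf_band)
    hf = band_power(hf_band)
    ratio = lf / hf if hf > 0 else None
    return lf, hf, ratio


def extract_features(rr: RRSeries, clean: bool = True,
                     max_rel_jump: float = 0.2, method: str = "lomb") -> HRVFeatures:
    """Full HRV feature set for one run."""
    if clean:
        rr, _ = clean_rr(rr, max_rel_jump)
    mean_hr, sdnn, rmssd = time_domain(rr)
    lf, hf, ratio = frequency_domain(rr, method=method)
    return HRVFeatures(mean_hr_bpm=mean_hr, sdnn_ms=sdnn, rmssd_ms=rmssd,
                       lf_power_ms2=lf, hf_power_ms2=hf, lf_hf_ratio=ratio)
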
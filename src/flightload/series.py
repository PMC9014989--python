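"""In-memory containers for physiological time series and their CSV dialects.

``RRSeries`` holds a beat-to-beat RR tachogram; ``HemoglobinSeries`` and
``OpticalDensitySeries`` hold multichannel fNIRS data on a uniform sampling
grid (2 Hz by default), before and after conversion between optical density
and chromophore concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["RRSeries", "HemoglobinSeries", "OpticalDensitySeries"]


@dataclass(frozen=True)
class RRSeries:
    """RR-interval series for one run.

    ``t_ms[k]`` is the cumulative beat time, i.e. the running sum of
    ``rr_ms[0..k]``; all intervals are strictly positive.
    """

    rr_ms: np.ndarray
    t_ms: np.ndarray
    condition: str = ""

    def __post_init__(self):
        rr = np.asarray(self.rr_ms, dtype=float)
        t = np.asarray(self.t_ms, dtype=float)
        object.__setattr__(self, "rr_ms", rr)
        object.__setattr__(self, "t_ms", t)
        if rr.ndim != 1 or t.shape != rr.shape:
            raise ValidationError("rr_ms and t_ms must be 1-D arrays of equal length")
        if rr.size and not np.all(rr > 0):
            raise ValidationError("all RR intervals must be > 0")
        if rr.size and not np.allclose(t, np.cumsum(rr), rtol=0, atol=1e-6):
            raise ValidationError("t_ms must be the cumulative sum of rr_ms")

    @classmethod
    def from_intervals(cls, rr_ms, condition: str = "") -> "RRSeries":
        rr = np.asarray(rr_ms, dtype=float)
        return cls(rr_ms=rr, t_ms=np.cumsum(rr), condition=condition)

    @property
    def duration_s(self) -> float:
        return float(self.t_ms[-1] / 1000.0) if self.t_ms.size else 0.0

    def to_csv(self, path) -> None:
        pd.DataFrame({"beat_time_ms": self.t_ms, "rr_ms": self.rr_ms}).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, condition: str = "") -> "RRSeries":
        df = pd.read_csv(path)
        for col in ("beat_time_ms", "rr_ms"):
            if col not in df.columns:
                raise ValidationError(f"RR CSV missing column {col!r}")
        return cls(rr_ms=df["rr_ms"].to_numpy(float), t_ms=df["beat_time_ms"].to_numpy(float), condition=condition)


def _check_grid(t_s: np.ndarray) -> float:
    if t_s.ndim != 1 or t_s.size < 2:
        raise ValidationError("need at least two samples on a uniform grid")
    dt = np.diff(t_s)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
        raise ValidationError("sampling grid is not uniform")
    return float(1.0 / dt[0])


@dataclass(frozen=True)
class HemoglobinSeries:
    """ΔHbO / ΔHbR concentration changes (μM), channels × samples, uniform grid."""

    t_s: np.ndarray
    delta_hbo: np.ndarray
    delta_hbr: np.ndarray
    channel_ids: tuple = ()
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        hbo = np.atleast_2d(np.asarray(self.delta_hbo, dtype=float))
        hbr = np.atleast_2d(np.asarray(self.delta_hbr, dtype=float))
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "delta_hbo", hbo)
        object.__setattr__(self, "delta_hbr", hbr)
        _check_grid(t)
        if hbo.shape != hbr.shape or hbo.shape[1] != t.size:
            raise ValidationError("delta_hbo/delta_hbr must be channels x samples matching t_s")
        if not (np.all(np.isfinite(hbo)) and np.all(np.isfinite(hbr))):
            bad = sorted(set(np.where(~np.all(np.isfinite(hbo), axis=1))[0] + 1)
                         | set(np.where(~np.all(np.isfinite(hbr), axis=1))[0] + 1))
            raise ValidationError(f"non-finite hemoglobin values in channels {bad}")
        if not self.channel_ids:
            object.__setattr__(self, "channel_ids", tuple(range(1, hbo.shape[0] + 1)))
        elif len(self.channel_ids) != hbo.shape[0]:
            raise ValidationError("channel_ids length does not match channel count")

    @property
    def fs(self) -> float:
        return _check_grid(self.t_s)

    @property
    def n_channels(self) -> int:
        return self.delta_hbo.shape[0]

    def to_csv(self, path) -> None:
        """Wide CSV fallback: t_s, ch<i>_hbo ..., ch<i>_hbr ...."""
        cols = {"t_s": self.t_s}
        for i, ch in enumerate(self.channel_ids):
            cols[f"ch{ch}_hbo"] = self.delta_hbo[i]
        for i, ch in enumerate(self.channel_ids):
            cols[f"ch{ch}_hbr"] = self.delta_hbr[i]
        pd.DataFrame(cols).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, condition: str = "") -> "HemoglobinSeries":
        df = pd.read_csv(path)
        if "t_s" not in df.columns:
            raise ValidationError("hemoglobin CSV missing column 't_s'")
        hbo_cols = [c for c in df.columns if c.endswith("_hbo")]
        hbr_cols = [c for c in df.columns if c.endswith("_hbr")]
        if not hbo_cols or len(hbo_cols) != len(hbr_cols):
            raise ValidationError("hemoglobin CSV must carry matching ch<i>_hbo / ch<i>_hbr columns")
        ids = tuple(int(c[2:-4]) for c in hbo_cols)
        return cls(
            t_s=df["t_s"].to_numpy(float),
            delta_hbo=df[hbo_cols].to_numpy(float).T,
            delta_hbr=df[hbr_cols].to_numpy(float).T,
            channel_ids=ids,
            condition=condition,
        )


@dataclass(frozen=True)
class OpticalDensitySeries:
    """Optical-density changes, channels × wavelengths × samples (dimensionless)."""

    t_s: np.ndarray
    delta_od: np.ndarray
    wavelengths_nm: tuple = (760.0, 850.0)
    channel_ids: tuple = ()
    condition: str = ""

    def __post_init__(self):
        t = np.asarray(self.t_s, dtype=float)
        od = np.asarray(self.delta_od, dtype=float)
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "delta_od", od)
        object.__setattr__(self, "wavelengths_nm", tuple(float(w) for w in self.wavelengths_nm))
        _check_grid(t)
        if od.ndim != 3 or od.shape[2] != t.size:
            raise ValidationError("delta_od must be channels x wavelengths x samples matching t_s")
        if od.shape[1] != len(self.wavelengths_nm):
            raise ValidationError("wavelength axis does not match wavelengths_nm")
        if not np.all(np.isfinite(od)):
            raise ValidationError("non-finite optical-density values")
        if not self.channel_ids:
            object.__setattr__(self, "channel_ids", tuple(range(1, od.shape[0] + 1)))
        elif len(self.channel_ids) != od.shape[0]:
            raise ValidationError("channel_ids length does not match channel count")

    @property
    def fs(self) -> float:
        return _check_grid(self.t_s)

    @property
    def n_channels(self) -> int:
        return self.delta_od.shape[0]
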
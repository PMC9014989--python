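"""Minimal SNIRF (v1.1) reader/writer for the 8-channel forehead montage.

Writes the standard HDF5 layout (/nirs/data1/dataTimeSeries, one
measurementList entry per channel×wavelength or channel×chromophore,
/nirs/probe/wavelengths, metaDataTags) for either raw ΔOD series
(dataType 1) or processed hemoglobin series (dataType 99999 with
dataTypeLabel "HbO"/"HbR"). The wide-CSV fallback in :mod:`series` carries
the same numbers; both routes feed the analysis chain identically.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .errors import ValidationError
from .optics import OpticsConfig
from .series import HemoglobinSeries, OpticalDensitySeries

__all__ = ["write_snirf", "read_snirf"]

_PROCESSED = 99999


def _write_meta(nirs, optics: OpticsConfig, condition: str):
    meta = nirs.create_group("metaDataTags")
    meta.create_dataset("SubjectID", data="synthetic")
    meta.create_dataset("MeasurementDate", data="unknown")
    meta.create_dataset("MeasurementTime", data="unknown")
    meta.create_dataset("LengthUnit", data="cm")
    meta.create_dataset("TimeUnit", data="s")
    meta.create_dataset("FrequencyUnit", data="Hz")
    meta.create_dataset("Condition", data=condition or "")
    meta.create_dataset("OpticsJSON", data=json.dumps({
        "source_detector_distance_cm": optics.source_detector_distance_cm,
        "dpf": list(optics.dpf),
        "sampling_hz": optics.sampling_hz,
        "extinction_coeffs": {str(k): v for k, v in optics.extinction_coeffs.items()},
    }))


def _write_probe(nirs, optics: OpticsConfig, n_channels: int):
    probe = nirs.create_group("probe")
    probe.create_dataset("wavelengths", data=np.asarray(optics.wavelengths_nm, dtype=float))
    # schematic forehead geometry: sources on a line, detectors between
    xs = np.arange(n_channels, dtype=float) * optics.source_detector_distance_cm
    probe.create_dataset("sourcePos2D", data=np.column_stack([xs, np.zeros(n_channels)]))
    probe.create_dataset("detectorPos2D",
                         data=np.column_stack([xs, np.full(n_channels, optics.source_detector_distance_cm)]))


def write_snirf(series, optics: OpticsConfig, path) -> None:
    """Write an :class:`OpticalDensitySeries` or :class:`HemoglobinSeries`."""
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.1")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        if isinstance(series, OpticalDensitySeries):
            n_ch, n_wl, n_t = series.delta_od.shape
            cols = series.delta_od.reshape(n_ch * n_wl, n_t).T
            data.create_dataset("dataTimeSeries", data=cols)
            data.create_dataset("time", data=series.t_s)
            idx = 1
            for c in range(n_ch):
                for w in range(n_wl):
                    ml = data.create_group(f"measurementList{idx}")
                    ml.create_dataset("sourceIndex", data=c + 1)
                    ml.create_dataset("detectorIndex", data=c + 1)
                    ml.create_dataset("wavelengthIndex", data=w + 1)
                    ml.create_dataset("dataType", data=1)
                    ml.create_dataset("dataTypeIndex", data=1)
                    idx += 1
            _write_probe(nirs, optics, n_ch)
        elif isinstance(series, HemoglobinSeries):
            n_ch, n_t = series.delta_hbo.shape
            cols = np.vstack([series.delta_hbo, series.delta_hbr]).T
            data.create_dataset("dataTimeSeries", data=cols)
            data.create_dataset("time", data=series.t_s)
            idx = 1
            for label, block in (("HbO", range(n_ch)), ("HbR", range(n_ch))):
                for c in block:
                    ml = data.create_group(f"measurementList{idx}")
                    ml.create_dataset("sourceIndex", data=c + 1)
                    ml.create_dataset("detectorIndex", data=c + 1)
                    ml.create_dataset("wavelengthIndex", data=1)
                    ml.create_dataset("dataType", data=_PROCESSED)
                    ml.create_dataset("dataTypeLabel", data=label)
                    ml.create_dataset("dataTypeIndex", data=1)
                    idx += 1
            _write_probe(nirs, optics, n_ch)
        else:
            raise ValidationError(f"cannot write {type(series).__name__} as SNIRF")
        _write_meta(nirs, optics, series.condition)


def _read_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path):
    """Read a SNIRF file written by :func:`write_snirf`.

    Returns ``(series, optics)`` where the series type is inferred from the
    measurement list (raw OD vs processed hemoglobin).
    """
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValidationError("malformed SNIRF: missing /nirs")
        nirs = f["nirs"]
        if "data1" not in nirs:
            raise ValidationError("malformed SNIRF: missing /nirs/data1")
        data = nirs["data1"]
        if "probe" not in nirs or "wavelengths" not in nirs["probe"]:
            raise ValidationError("malformed SNIRF: missing /nirs/probe/wavelengths")
        wavelengths = tuple(float(w) for w in nirs["probe"]["wavelengths"][()])
        t = np.asarray(data["time"][()], dtype=float)
        Y = np.asarray(data["dataTimeSeries"][()], dtype=float)
        mls = sorted((k for k in data.keys() if k.startswith("measurementList")),
                     key=lambda k: int(k[len("measurementList"):]))
        if not mls:
            raise ValidationError("malformed SNIRF: no measurementList entries")
        meta = nirs["metaDataTags"] if "metaDataTags" in nirs else None
        condition = _read_str(meta["Condition"]) if meta is not None and "Condition" in meta else ""
        optics_kwargs = {}
        if meta is not None and "OpticsJSON" in meta:
            raw = json.loads(_read_str(meta["OpticsJSON"]))
            optics_kwargs = {
                "source_detector_distance_cm": raw["source_detector_distance_cm"],
                "dpf": tuple(raw["dpf"]),
                "sampling_hz": raw["sampling_hz"],
                "extinction_coeffs": {float(k): v for k, v in raw["extinction_coeffs"].items()},
            }
        first_type = int(data[mls[0]]["dataType"][()])
        if first_type == _PROCESSED:
            labels = [_read_str(data[k]["dataTypeLabel"]) for k in mls]
            hbo_idx = [i for i, l in enumerate(labels) if l == "HbO"]
            hbr_idx = [i for i, l in enumerate(labels) if l == "HbR"]
            if not hbo_idx or len(hbo_idx) != len(hbr_idx):
                raise ValidationError("malformed SNIRF: unmatched HbO/HbR measurement lists")
            optics = OpticsConfig(wavelengths_nm=wavelengths,
                                  n_channels=len(hbo_idx), **optics_kwargs)
            series = HemoglobinSeries(t_s=t, delta_hbo=Y[:, hbo_idx].T,
                                      delta_hbr=Y[:, hbr_idx].T, condition=condition)
        else:
            chans = sorted({int(data[k]["sourceIndex"][()]) for k in mls})
            n_ch, n_wl = len(chans), len(wavelengths)
            od = np.empty((n_ch, n_wl, t.size))
            for col, k in enumerate(mls):
                ml = data[k]
                c = chans.index(int(ml["sourceIndex"][()]))
                w = int(ml["wavelengthIndex"][()]) - 1
                od[c, w] = Y[:, col]
            optics = OpticsConfig(wavelengths_nm=wavelengths, n_channels=n_ch, **optics_kwargs)
            series = OpticalDensitySeries(t_s=t, delta_od=od, wavelengths_nm=wavelengths,
                                          condition=condition)
    return series, optics
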
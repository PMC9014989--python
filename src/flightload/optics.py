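"""Continuous-wave NIRS optics configuration and the modified Beer–Lambert law.

The modified Beer–Lambert law (MBLL) relates the optical-density change at
wavelength λ to chromophore concentration changes::

    ΔOD(λ) = [ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR] · d · DPF(λ)

with d the source–detector separation (cm), DPF the differential pathlength
factor, ε in cm⁻¹·M⁻¹ and concentrations in M. Concentrations in this package
are carried in μM, so the 1e-6 M/μM conversion is folded into the system
matrix. The default extinction coefficients follow the compiled in-vivo
tabulation of W. B. Gratzer / S. Prahl commonly shipped with NIRS toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["OpticsConfig", "DEFAULT_EXTINCTION"]

# ε [chromophore][wavelength] in cm^-1 / M, rows (HbO, HbR), columns (760, 850) nm.
DEFAULT_EXTINCTION = {
    760.0: {"hbo": 1486.6, "hbr": 3843.7},
    850.0: {"hbo": 2526.4, "hbr": 1798.6},
}


@dataclass(frozen=True)
class OpticsConfig:
    """Acquisition geometry and conversion constants of the 8-channel forehead band.

    Defaults mirror the recording setup modeled throughout the package:
    two wavelengths (760 / 850 nm), 3.5 cm source–detector separation,
    2 Hz sampling, eight channels over the prefrontal cortex, and a
    differential pathlength factor of 6.0 at both wavelengths.
    """

    wavelengths_nm: tuple = (760.0, 850.0)
    source_detector_distance_cm: float = 3.5
    dpf: tuple = (6.0, 6.0)
    extinction_coeffs: dict = field(default_factory=lambda: {
        w: dict(v) for w, v in DEFAULT_EXTINCTION.items()
    })
    sampling_hz: float = 2.0
    n_channels: int = 8

    def __post_init__(self):
        if self.source_detector_distance_cm <= 0:
            raise ConfigurationError("source-detector distance must be > 0")
        if self.sampling_hz <= 0:
            raise ConfigurationError("sampling_hz must be > 0")
        if len(self.dpf) != len(self.wavelengths_nm):
            raise ConfigurationError("need one DPF per wavelength")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        for w in self.wavelengths_nm:
            if float(w) not in {float(k) for k in self.extinction_coeffs}:
                raise ConfigurationError(f"no extinction coefficients for {w} nm")
        # fail fast on a non-invertible wavelength pair
        self.system_matrix()

    def extinction_matrix(self) -> np.ndarray:
        """ε matrix, rows = wavelengths, columns = (HbO, HbR), in cm^-1/M."""
        rows = []
        for w in self.wavelengths_nm:
            coef = self.extinction_coeffs[float(w)]
            rows.append([coef["hbo"], coef["hbr"]])
        return np.asarray(rows, dtype=float)

    def system_matrix(self) -> np.ndarray:
        """Full MBLL matrix A with ΔOD = A @ (ΔHbO, ΔHbR) for ΔHb in μM.

        A[λ, c] = ε_c(λ) · d · DPF(λ) · 1e-6. Raises if the wavelength pair is
        singular or ill-conditioned (condition number > 1e6).
        """
        eps = self.extinction_matrix()
        scale = self.source_detector_distance_cm * np.asarray(self.dpf, dtype=float)
        A = eps * scale[:, None] * 1e-6
        cond = np.linalg.cond(A)
        if not np.isfinite(cond) or cond > 1e6:
            pair = tuple(self.wavelengths_nm)
            raise ConfigurationError(
                f"extinction system for wavelengths {pair} nm is singular or "
                f"ill-conditioned (condition number {cond:.3g})"
            )
        return A

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.system_matrix()))
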
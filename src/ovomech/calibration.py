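"""Cantilever spring-constant calibration.

Two methods are implemented:

* **thermal noise** — equipartition on the variance of the thermally excited
  deflection: ``k = correction * k_B * T / <d^2>``. The default correction
  0.817 is the first-flexural-mode optical-lever convention; instruments
  differ, so it is configurable.
* **spring-on-spring** — pressing a reference spring of known stiffness
  ``k_ref`` and reading the deflection-per-displacement slope ``s = d/z``.
  The force balance ``k d = k_ref (z - d)`` inverts to
  ``k = k_ref (1 - s) / s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend

__all__ = [
    "ThermalRecord",
    "SpringOnSpringRecord",
    "thermal_noise_k",
    "spring_on_spring_k",
    "BOLTZMANN_J_PER_K",
]

BOLTZMANN_J_PER_K = 1.380649e-23


@dataclass(frozen=True)
class ThermalRecord:
    """Deflection time series (nm) recorded off-resonance on a hard surface."""

    d: np.ndarray  # nm
    sample_rate: float  # Hz
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if len(self.d) < 4096:
            raise ValueError("thermal record needs >= 4096 samples")
        if not 273.0 <= self.temperature <= 330.0:
            raise ValueError("temperature must be in [273, 330] K")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be > 0")


@dataclass(frozen=True)
class SpringOnSpringRecord:
    """Deflection-per-displacement slope measured on a reference spring."""

    slope: float  # unitless, in (0, 1)
    k_ref: float  # N/m

    def __post_init__(self) -> None:
        if not 0.0 < self.slope < 1.0:
            raise ValueError("slope must be in (0, 1) — unphysical otherwise")
        if not self.k_ref > 0:
            raise ValueError("k_ref must be > 0")


def thermal_noise_k(rec: ThermalRecord, correction: float = 0.817) -> float:
    """Spring constant (N/m) from equipartition of thermal deflection noise.

    The series is linearly detrended before taking the variance, so slow
    drift does not inflate ``<d^2>``.
    """
    d_m = detrend(rec.d) * 1e-9  # nm -> m
    var = float(np.var(d_m))
    if var <= 0.0:
        raise ValueError("zero variance: no thermal motion recorded")
    return correction * BOLTZMANN_J_PER_K * rec.temperature / var


def spring_on_spring_k(rec: SpringOnSpringRecord) -> float:
    """Spring constant (N/m) from the reference-spring force balance."""
    return rec.k_ref * (1.0 - rec.slope) / rec.slope


def spring_on_spring_slope(k: float, k_ref: float) -> float:
    """Forward model: slope d/z = k_ref / (k + k_ref) for ideal springs."""
    if not (k > 0 and k_ref > 0):
        raise ValueError("stiffnesses must be > 0")
    return k_ref / (k + k_ref)
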
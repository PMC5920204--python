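"""Physical constants and phase/velocity conversions for Doppler OCT.

Doppler OCT measures axial velocity from the phase shift of the complex
interferometric signal between A-lines. For a phase shift ``theta``
accumulated over one A-line interval ``dT``, the axial velocity is

    v = theta * lambda0 / (4 * pi * n * dT)

with ``lambda0`` the center wavelength in vacuum and ``n`` the sample
refractive index. The detectable phase range of a two-point (adjacent
A-line) measurement is bounded below by the system phase stability (the
standard deviation of the adjacent-pair phase on a static sample) and
above by pi (phase wrapping), which defines the conventional velocity
dynamic range.

This module holds the acquisition constants, the phase/velocity
conversions, the Doppler-angle correction, and analytic calculators for
the dynamic range and the theoretical minimum-detectable-velocity
("detection floor") of the estimators implemented in
:mod:`doppleroct.estimators`:

* conventional estimator with N averaged adjacent-pair measurements:
  floor = v_min / sqrt(N),
* complex regression over a window of m A-lines: the measured phase
  accumulates over m-1 intervals, so floor = v_min / (m - 1),

optionally inflated by sqrt(SNR_high / SNR_low) when the signal-to-noise
ratio is reduced (phase noise scales as 1/sqrt(SNR)).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "DopplerConfig",
    "VelocityRange",
    "EstimatorKind",
    "EstimatorSpec",
    "phase_to_velocity",
    "velocity_to_phase",
    "angle_correct",
    "conventional_range",
    "detection_floor",
]


@dataclass(frozen=True)
class DopplerConfig:
    """Acquisition constants of the OCT system.

    Parameters
    ----------
    center_wavelength_m
        Center wavelength of the swept source in vacuum (m).
    refractive_index
        Refractive index of the sample medium (dimensionless).
    aline_interval_s
        Time between two adjacent A-lines (s).
    doppler_angle_deg
        Angle between the flow axis and the imaging beam (degrees);
        axial velocity = true velocity * cos(angle).
    phase_stability_rad
        Standard deviation of the adjacent-pair phase measured on a
        static sample (rad); sets the two-point velocity floor.
    """

    center_wavelength_m: float = 1315e-9
    refractive_index: float = 1.38
    aline_interval_s: float = 594e-9
    doppler_angle_deg: float = 80.0
    phase_stability_rad: float = 0.096

    def __post_init__(self) -> None:
        for name in ("center_wavelength_m", "refractive_index", "aline_interval_s",
                     "phase_stability_rad"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not (0.0 <= self.doppler_angle_deg < 90.0):
            raise ValueError(
                f"doppler_angle_deg must lie in [0, 90), got {self.doppler_angle_deg!r}")
        if not self.phase_stability_rad < math.pi:
            raise ValueError(
                f"phase_stability_rad must be < pi, got {self.phase_stability_rad!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "DopplerConfig":
        """Build a config from the flat key-value file schema.

        Recognized keys: ``wavelength_m``, ``refractive_index``,
        ``aline_interval_s``, ``doppler_angle_deg``, ``phase_stability_rad``.
        Missing keys keep their defaults; unknown keys raise.
        """
        key_map = {
            "wavelength_m": "center_wavelength_m",
            "refractive_index": "refractive_index",
            "aline_interval_s": "aline_interval_s",
            "doppler_angle_deg": "doppler_angle_deg",
            "phase_stability_rad": "phase_stability_rad",
        }
        kwargs = {}
        for key, value in mapping.items():
            if key not in key_map:
                raise ValueError(f"unknown config key: {key!r}")
            kwargs[key_map[key]] = float(value)
        return cls(**kwargs)


@dataclass(frozen=True)
class VelocityRange:
    """Closed interval of detectable axial speeds (m/s)."""

    v_min: float
    v_max: float

    def __post_init__(self) -> None:
        if not (0 < self.v_min < self.v_max):
            raise ValueError(
                f"require 0 < v_min < v_max, got ({self.v_min!r}, {self.v_max!r})")


class EstimatorKind(str, enum.Enum):
    """Phase-shift estimator families."""

    CONVENTIONAL_AVG = "conventional_avg"
    COMPLEX_REGRESSION = "complex_regression"


@dataclass(frozen=True)
class EstimatorSpec:
    """An estimator choice: kind plus its size parameter.

    ``n_points`` is the number of averaged adjacent-pair measurements N
    for the conventional estimator, and the regression window length m
    for complex regression.
    """

    kind: EstimatorKind
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", EstimatorKind(self.kind))
        if self.n_points < 2:
            raise ValueError(f"n_points must be >= 2, got {self.n_points!r}")

    @property
    def label(self) -> str:
        if self.kind is EstimatorKind.CONVENTIONAL_AVG:
            return f"cnv{self.n_points}"
        return f"cmpreg{self.n_points}"


def _velocity_per_radian(config: DopplerConfig) -> float:
    """Axial speed per radian of per-interval phase: lambda0/(4 pi n dT)."""
    return config.center_wavelength_m / (
        4.0 * math.pi * config.refractive_index * config.aline_interval_s)


def phase_to_velocity(delta_phi, config: DopplerConfig = DopplerConfig()):
    """Convert a per-interval phase shift (rad) to axial velocity (m/s).

    ``delta_phi`` is the phase accumulated over ONE adjacent-A-line
    interval. Scalar or array input; signed, linear in the phase.
    """
    delta_phi = np.asarray(delta_phi, dtype=float)
    if not np.all(np.isfinite(delta_phi)):
        raise ValueError("delta_phi must be finite")
    out = delta_phi * _velocity_per_radian(config)
    return float(out) if out.ndim == 0 else out


def velocity_to_phase(velocity_mps, config: DopplerConfig = DopplerConfig()):
    """Inverse of :func:`phase_to_velocity`: axial velocity to per-interval phase."""
    velocity_mps = np.asarray(velocity_mps, dtype=float)
    if not np.all(np.isfinite(velocity_mps)):
        raise ValueError("velocity must be finite")
    out = velocity_mps / _velocity_per_radian(config)
    return float(out) if out.ndim == 0 else out


def angle_correct(v_axial, doppler_angle_deg: float):
    """Correct an axial velocity for the Doppler angle: v / cos(angle)."""
    if not (0.0 <= doppler_angle_deg < 90.0):
        raise ValueError(
            f"Doppler angle must lie in [0, 90) degrees, got {doppler_angle_deg!r}")
    return v_axial / math.cos(math.radians(doppler_angle_deg))


def conventional_range(config: DopplerConfig = DopplerConfig()) -> VelocityRange:
    """Dynamic range of the conventional two-point method.

    The lower bound converts the phase-stability floor, the upper bound
    converts pi (the wrapping limit).
    """
    return VelocityRange(
        v_min=phase_to_velocity(config.phase_stability_rad, config),
        v_max=phase_to_velocity(math.pi, config),
    )


def detection_floor(spec: EstimatorSpec,
                    config: DopplerConfig = DopplerConfig(),
                    snr_attenuation_factor: float = 1.0) -> float:
    """Theoretical minimum detectable axial velocity (m/s) of an estimator.

    ``snr_attenuation_factor`` is sqrt(SNR_high / SNR_low): 1 for the
    reference (high SNR) condition, sqrt(10) when the linear SNR is
    reduced tenfold (a 20-dB attenuation of the sample power). Phase
    noise scales with this factor, and so does the floor.
    """
    if not (math.isfinite(snr_attenuation_factor) and snr_attenuation_factor >= 1.0):
        raise ValueError(
            f"snr_attenuation_factor must be >= 1, got {snr_attenuation_factor!r}")
    v_min_base = conventional_range(config).v_min
    if spec.kind is EstimatorKind.CONVENTIONAL_AVG:
        return v_min_base / math.sqrt(spec.n_points) * snr_attenuation_factor
    # Complex regression over m points: the phase accumulates over m-1
    # intervals, so the same absolute phase floor maps to an (m-1)-fold
    # smaller per-interval phase, hence velocity.
    return v_min_base / (spec.n_points - 1) * snr_attenuation_factor
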
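"""Evanescent-field optics for objective-type TIRF microscopy.

Total internal reflection of the excitation beam at the glass--medium
interface produces an evanescent wave whose intensity decays exponentially
with height ``z`` above the coverslip::

    I(z) = I_0 * exp(-z / d_p)

with penetration depth

    d_p = lambda / (4 * pi * sqrt(n1^2 sin^2(theta) - n2^2))

where ``lambda`` is the excitation wavelength, ``theta`` the incident
angle, ``n1`` the glass index and ``n2`` the medium index.  Inverting the
decay turns the background-corrected mean head intensity of a tracked cell
into its distance from the surface, which is how a TIRF movie yields a
z-coordinate for every detection.

Near-field emission effects and polarization are neglected: intensity is
treated as a pure exponential in ``z``.  All public angles are degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "OpticalConfig",
    "critical_angle",
    "max_incident_angle",
    "penetration_depth",
    "intensity_ratio_at_depth",
    "depth_from_intensity",
    "DEFAULT_DETECTABILITY_RATIO",
]

#: Relative-intensity cutoff below which a fluorophore is treated as
#: undetectable.  exp(-(1200 - 10)/549) ~ 0.114: with d_p = 549 nm this
#: reproduces an imaging range of roughly 1.2 um above the coverslip.
DEFAULT_DETECTABILITY_RATIO = 0.1124


class TotalInternalReflectionError(ValueError):
    """Raised when the requested geometry supports no evanescent field."""


def critical_angle(n_medium: float, n_glass: float) -> float:
    """Critical angle of total internal reflection, in degrees.

    Parameters
    ----------
    n_medium : float
        Refractive index of the liquid medium (n2).
    n_glass : float
        Refractive index of the coverslip glass (n1); must satisfy
        ``n_glass >= n_medium`` for total internal reflection to exist.
    """
    if n_medium <= 0 or n_glass <= 0:
        raise ValueError("refractive indices must be positive")
    if n_medium > n_glass:
        raise TotalInternalReflectionError(
            f"no total internal reflection: n_medium={n_medium} > n_glass={n_glass}"
        )
    return math.degrees(math.asin(n_medium / n_glass))


def max_incident_angle(numerical_aperture: float, n_glass: float) -> float:
    """Largest incident angle the objective can deliver, in degrees.

    The marginal ray of an objective with numerical aperture ``NA``
    immersed against glass of index ``n1`` arrives at ``arcsin(NA/n1)``.
    """
    if numerical_aperture <= 0 or n_glass <= 0:
        raise ValueError("numerical aperture and glass index must be positive")
    if numerical_aperture > n_glass:
        raise ValueError(
            f"NA={numerical_aperture} exceeds glass index {n_glass}; "
            "sin(theta) would exceed 1"
        )
    return math.degrees(math.asin(numerical_aperture / n_glass))


@dataclass
class OpticalConfig:
    """Evanescent-field parameters of one TIRF acquisition.

    Attributes
    ----------
    wavelength_nm : float
        Excitation wavelength, nm.
    n_glass, n_medium : float
        Refractive indices of coverslip (n1) and medium (n2).
    numerical_aperture : float
        Objective NA; bounds the usable incident angle.
    incident_angle_deg : float
        Incident angle actually used; must lie strictly between the
        critical angle and 90 degrees.
    reference_intensity : float
        Background-corrected mean head intensity assigned to a cell at the
        reference depth (the I_0 calibration).  Arbitrary camera units.
    reference_depth_nm : float
        Height above the coverslip at which ``reference_intensity`` is
        observed.  Defaults to 10 nm, the closest approach a swimming cell
        can physically make to the wall.
    """

    wavelength_nm: float
    n_glass: float
    n_medium: float
    numerical_aperture: float
    incident_angle_deg: float
    reference_intensity: float = 1.0
    reference_depth_nm: float = 10.0
    detectability_ratio: float = field(default=DEFAULT_DETECTABILITY_RATIO)

    def __post_init__(self) -> None:
        if not (self.n_glass > self.n_medium > 0):
            raise ValueError(
                f"need n_glass > n_medium > 0, got n1={self.n_glass}, n2={self.n_medium}"
            )
        if not (0 < self.numerical_aperture <= self.n_glass):
            raise ValueError("numerical aperture must lie in (0, n_glass]")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        theta_c = self.critical_angle_deg
        if not (theta_c < self.incident_angle_deg < 90.0):
            raise TotalInternalReflectionError(
                f"incident angle {self.incident_angle_deg} deg must lie strictly "
                f"between the critical angle ({theta_c:.2f} deg) and 90 deg"
            )
        if self.reference_intensity <= 0:
            raise ValueError("reference intensity must be positive")
        if self.reference_depth_nm < 0:
            raise ValueError("reference depth must be non-negative")

    @property
    def critical_angle_deg(self) -> float:
        return critical_angle(self.n_medium, self.n_glass)

    @property
    def max_incident_angle_deg(self) -> float:
        return max_incident_angle(self.numerical_aperture, self.n_glass)

    @property
    def penetration_depth_nm(self) -> float:
        return penetration_depth(self)

    @property
    def max_imaging_depth_nm(self) -> float:
        """Largest depth at which a head is still considered detectable."""
        return depth_from_intensity(
            self.detectability_ratio * self.reference_intensity, self
        )

    def with_reference_intensity(self, i0: float) -> "OpticalConfig":
        """Return a copy calibrated to a new I_0."""
        return OpticalConfig(
            wavelength_nm=self.wavelength_nm,
            n_glass=self.n_glass,
            n_medium=self.n_medium,
            numerical_aperture=self.numerical_aperture,
            incident_angle_deg=self.incident_angle_deg,
            reference_intensity=i0,
            reference_depth_nm=self.reference_depth_nm,
            detectability_ratio=self.detectability_ratio,
        )


def penetration_depth(config: OpticalConfig) -> float:
    """Evanescent-field penetration depth d_p in nm.

    d_p = lambda / (4 pi sqrt(n1^2 sin^2 theta - n2^2)); strictly
    decreasing in the incident angle above the critical angle.
    """
    theta = math.radians(config.incident_angle_deg)
    arg = (config.n_glass * math.sin(theta)) ** 2 - config.n_medium**2
    if arg <= 0:
        raise TotalInternalReflectionError(
            "incident angle at or below the critical angle: no evanescent field"
        )
    return config.wavelength_nm / (4.0 * math.pi * math.sqrt(arg))


def intensity_ratio_at_depth(z_nm, d_p_nm: float):
    """Relative evanescent intensity I(z)/I(0) = exp(-z/d_p).

    Accepts scalars or arrays; ``z`` must be non-negative.
    """
    if d_p_nm <= 0:
        raise ValueError("penetration depth must be positive")
    z = np.asarray(z_nm, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth z must be non-negative")
    out = np.exp(-z / d_p_nm)
    return float(out) if np.isscalar(z_nm) else out


def depth_from_intensity(intensity, config: OpticalConfig):
    """Invert the evanescent decay: intensity -> height above the glass, nm.

    z = z_ref - d_p * ln(I / I_0), so a cell at the reference intensity
    sits at the reference depth (10 nm by default -- the closest approach).
    Intensities above I_0, which arise from noise, clamp to the reference
    depth with a warning rather than producing negative heights.
    """
    d_p = penetration_depth(config)
    i = np.asarray(intensity, dtype=float)
    if np.any(i <= 0):
        raise ValueError("intensity must be positive to infer a depth")
    if np.any(i > config.reference_intensity):
        n_clip = int(np.sum(i > config.reference_intensity))
        logger.warning(
            "%d intensity value(s) above the I_0 calibration; clamping to the "
            "reference depth (%.0f nm)",
            n_clip,
            config.reference_depth_nm,
        )
        i = np.minimum(i, config.reference_intensity)
    z = config.reference_depth_nm - d_p * np.log(i / config.reference_intensity)
    return float(z) if np.isscalar(intensity) else z
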
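"""Elementary acoustic quantities for foliage-echo simulation.

All leaves are modelled as rigid circular discs; the sonar beam is a
separable Gaussian in azimuth and elevation, parameterised directly by its
two-sided -3 dB beamwidths.  Everything here is a pure, vectorised function
of scalars or numpy arrays.

Conventions
-----------
* dB quantities are amplitude-referenced: a linear amplitude ``g`` maps to
  ``20*log10(g)`` dB.
* Ranges are in metres, frequencies in Hz, angles in degrees unless a
  parameter name says otherwise.
* Two-way spherical spreading loss is ``40*log10(r / 1 m)`` (amplitude
  ``1/r**2`` for the round trip).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import j1

__all__ = [
    "Medium",
    "BeamSpec",
    "LeafDisc",
    "beam_gain_db",
    "atmospheric_absorption_db_per_m",
    "two_way_loss_db",
    "disc_backscatter_amplitude",
]


@dataclass(frozen=True)
class Medium:
    """Propagation medium (air).

    Parameters
    ----------
    sound_speed : float
        Speed of sound in m/s.
    temperature : float
        Air temperature in degrees Celsius (used only by the absorption
        model).
    relative_humidity : float
        Relative humidity in percent.
    absorption_enabled : bool
        When False, :func:`atmospheric_absorption_db_per_m` returns 0 and
        propagation is pure spherical spreading.  Absorption is switched on
        by default only where a finite loss budget must terminate at a
        realistic range (domain sizing); echo synthesis defaults to
        spreading only.
    """

    sound_speed: float = 343.0
    temperature: float = 20.0
    relative_humidity: float = 50.0
    absorption_enabled: bool = False

    def __post_init__(self) -> None:
        if self.sound_speed <= 0:
            raise ValueError("sound_speed must be positive")
        if not 0.0 <= self.relative_humidity <= 100.0:
            raise ValueError("relative_humidity must be in [0, 100]")


@dataclass(frozen=True)
class BeamSpec:
    """Gaussian sonar beam, two-sided -3 dB beamwidths in degrees."""

    beamwidth_az: float
    beamwidth_el: float

    def __post_init__(self) -> None:
        if self.beamwidth_az <= 0 or self.beamwidth_el <= 0:
            raise ValueError("beamwidths must be positive")

    @classmethod
    def symmetric(cls, beamwidth: float) -> "BeamSpec":
        return cls(beamwidth, beamwidth)


@dataclass(frozen=True)
class LeafDisc:
    """A single circular leaf scatterer."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-6:
            raise ValueError("normal must be a unit vector")


def beam_gain_db(offset_az, offset_el, beam: BeamSpec):
    """One-way beam gain in dB at the given angular offsets from the axis.

    The beam is the product of two Gaussians, one in azimuth and one in
    elevation; in dB this is a separable quadratic chosen so that the gain
    is exactly -3 dB at half the two-sided beamwidth::

        gain = -3*(2*az/bw_az)**2 - 3*(2*el/bw_el)**2

    Maximum 0 dB on axis.  Accepts scalars or arrays.
    """
    az = np.asarray(offset_az, dtype=float)
    el = np.asarray(offset_el, dtype=float)
    g = -3.0 * (2.0 * az / beam.beamwidth_az) ** 2 \
        - 3.0 * (2.0 * el / beam.beamwidth_el) ** 2
    return g if g.shape else float(g)


def atmospheric_absorption_db_per_m(frequency, medium: Medium):
    """One-way atmospheric absorption coefficient in dB/m (ISO 9613-1).

    Standard-atmosphere closed form (relaxation of O2 and N2 plus classical
    absorption) at the medium's temperature and relative humidity, ambient
    pressure 101.325 kPa.  Returns 0 when ``medium.absorption_enabled`` is
    False.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    if not medium.absorption_enabled:
        z = np.zeros_like(f)
        return z if z.shape else 0.0

    T = medium.temperature + 273.15
    T0 = 293.15
    T01 = 273.16
    pa_pr = 1.0  # ambient / reference pressure

    # saturation vapour pressure ratio and molar water concentration (%)
    psat_pr = 10.0 ** (-6.8346 * (T01 / T) ** 1.261 + 4.6151)
    h = medium.relative_humidity * psat_pr / pa_pr

    fr_o = pa_pr * (24.0 + 4.04e4 * h * (0.02 + h) / (0.391 + h))
    fr_n = pa_pr * (T / T0) ** -0.5 * (
        9.0 + 280.0 * h * np.exp(-4.170 * ((T / T0) ** (-1.0 / 3.0) - 1.0))
    )

    f2 = f * f
    alpha = 8.686 * f2 * (
        1.84e-11 / pa_pr * (T / T0) ** 0.5
        + (T / T0) ** -2.5 * (
            0.01275 * np.exp(-2239.1 / T) / (fr_o + f2 / fr_o)
            + 0.1068 * np.exp(-3352.0 / T) / (fr_n + f2 / fr_n)
        )
    )
    return alpha if alpha.shape else float(alpha)


def two_way_loss_db(range_m, frequency, medium: Medium):
    """Two-way transmission loss in dB at the given range.

    Spherical spreading referenced to 1 m plus (optionally) atmospheric
    absorption over the round trip::

        loss = 40*log10(r) + 2*r*alpha(f)
    """
    r = np.asarray(range_m, dtype=float)
    if np.any(r <= 0):
        raise ValueError("range must be positive")
    loss = 40.0 * np.log10(r)
    alpha = atmospheric_absorption_db_per_m(frequency, medium)
    loss = loss + 2.0 * r * alpha
    return loss if loss.shape else float(loss)


def disc_backscatter_amplitude(frequency, radius, incidence_angle,
                               medium: Medium, mode: str = "cosine"):
    """Monostatic backscattering amplitude of a rigid circular disc.

    ``incidence_angle`` is the angle (degrees) between the disc normal and
    the direction towards the sonar.  Two approximations are available:

    ``cosine``
        ``A = (k*a**2/2) * cos(theta)`` with ``k = 2*pi*f/c`` — the
        high-frequency normal-incidence prefactor modulated by a cosine
        directivity in the incidence angle.
    ``physical_optics``
        ``A = (k*a**2/2) * |cos(theta)| * |2*J1(x)/x|`` with
        ``x = 2*k*a*sin(theta)`` — the Kirchhoff (physical-optics) flat
        plate result, used as a validation oracle for the cosine form.

    Both are dimensionless amplitudes relative to the incident wave at the
    disc, nonnegative, and agree at normal incidence.  Angles outside
    [0, 90] degrees are folded back by the disc's front/back symmetry with
    a warning.
    """
    if mode not in ("cosine", "physical_optics"):
        raise ValueError(f"unknown mode {mode!r}")
    f = np.asarray(frequency, dtype=float)
    a = np.asarray(radius, dtype=float)
    th = np.asarray(incidence_angle, dtype=float)
    if np.any(a < 0):
        raise ValueError("radius must be nonnegative")
    if np.any((th < 0) | (th > 90)):
        warnings.warn("incidence angle outside [0, 90] deg folded by disc "
                      "symmetry", stacklevel=2)

    th_rad = np.deg2rad(th)
    cos_t = np.abs(np.cos(th_rad))
    k = 2.0 * np.pi * f / medium.sound_speed
    amp = 0.5 * k * a ** 2 * cos_t
    if mode == "physical_optics":
        x = 2.0 * k * a * np.abs(np.sin(th_rad))
        # |2 J1(x)/x| with limit 1 at x=0
        with np.errstate(invalid="ignore", divide="ignore"):
            jinc = np.where(x > 1e-12, 2.0 * j1(np.where(x > 1e-12, x, 1.0))
                            / np.where(x > 1e-12, x, 1.0), 1.0)
        amp = amp * np.abs(jinc)
    return amp if amp.shape else float(amp)
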
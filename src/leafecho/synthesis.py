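"""Frequency-domain echo synthesis from disc scatterers.

An echo is predicted by summing, over all leaves within the loss budget,
the complex transfer function of each leaf on a band-limited frequency grid
(default 2000 evenly spaced frequencies across 60-80 kHz), then inverse
transforming the Hanning-windowed band spectrum into a real waveform
sampled at 400 kHz.

For one leaf at range ``r``, incidence angle ``theta`` and beam offsets
``(az, el)``::

    H(f) = g_tx * g_rx * A_disc(f, a, theta) * 10**(-2*r*alpha(f)/20)
           * (1/r**2) * exp(-j * 2*pi * f * 2*r/c)

with the one-way beam gains applied on transmit and receive and the disc
scattered once (monostatic reflection).

Two evaluation paths produce the same spectrum:

* ``direct`` — literal chunked summation of the expression above.
* ``binned`` — leaves are accumulated into round-trip delay bins on the
  output sample grid with a short Taylor expansion of the residual
  fractional-delay phase across the band; the band spectrum is then read
  off full-length FFTs of the binned moments.  This is O(n_leaves) instead
  of O(n_leaves * n_frequencies) and agrees with ``direct`` to better than
  1e-6 relative error (about 1e-3 with absorption enabled, whose band
  dependence joins the same expansion).  It applies whenever the cosine
  disc law is used; physical-optics mode always goes direct.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .acoustics import Medium, atmospheric_absorption_db_per_m, beam_gain_db
from .geometry import (DiscSet, SonarPose, as_disc_set, beam_offsets_deg,
                       incidence_angles_deg)

__all__ = [
    "FrequencyGrid",
    "SonarPose",
    "EchoWaveform",
    "leaf_transfer_function",
    "synthesize_echo",
    "band_to_time",
    "two_way_budget_db",
]

DEFAULT_SAMPLING_RATE = 400e3


@dataclass(frozen=True)
class FrequencyGrid:
    """Uniform frequency grid across the synthesis band.

    The grid is half-open: ``f_m = f_low + m*(f_high - f_low)/n_points``
    for ``m = 0..n_points-1``, so the default 60-80 kHz band with 2000
    points has exactly 10 Hz spacing and every grid frequency coincides
    with a bin of the 40000-point FFT of a 0.1 s record at 400 kHz.
    """

    f_low: float = 60e3
    f_high: float = 80e3
    n_points: int = 2000

    def __post_init__(self) -> None:
        if not self.f_low < self.f_high:
            raise ValueError("need f_low < f_high")
        if self.n_points < 2:
            raise ValueError("need at least 2 grid points")

    @property
    def spacing(self) -> float:
        return (self.f_high - self.f_low) / self.n_points

    @property
    def frequencies(self) -> np.ndarray:
        return self.f_low + self.spacing * np.arange(self.n_points)

    @property
    def center(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    def full_record_bins(self, sampling_rate: float) -> tuple[int, int]:
        """(n_full, k0): full-FFT length and the band's first bin index.

        Raises if the band is above Nyquist or does not align with the
        full FFT bins.
        """
        if self.f_high > sampling_rate / 2:
            raise ValueError("band edge above Nyquist for this rate")
        n_full = sampling_rate / self.spacing
        k0 = self.f_low / self.spacing
        if abs(n_full - round(n_full)) > 1e-6 or abs(k0 - round(k0)) > 1e-6:
            raise ValueError("grid spacing must divide the sampling rate "
                             "and the band edge")
        return int(round(n_full)), int(round(k0))


@dataclass
class EchoWaveform:
    """A synthesised echo: real samples plus its band spectrum.

    ``spectrum`` is the raw (un-windowed) complex sum of leaf transfer
    functions on ``grid``; ``samples`` is the Hanning-windowed inverse
    transform at ``sampling_rate``.
    """

    samples: np.ndarray
    sampling_rate: float
    spectrum: np.ndarray
    grid: FrequencyGrid = field(default_factory=FrequencyGrid)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sampling_rate


def two_way_budget_db(discs: DiscSet, pose: SonarPose, medium: Medium,
                      frequency: float | None = None):
    """Two-way loss plus two-way beam attenuation for each disc, in dB.

    ``loss = 40*log10(r) + 2*r*alpha(f) + 2*|beam_gain|``; discs in the
    back half-space of the sonar get an infinite budget (they are never
    within any finite threshold).  ``frequency`` defaults to 70 kHz and
    only matters when absorption is enabled.
    """
    discs = as_disc_set(discs)
    az, el, rng, front = beam_offsets_deg(discs.centers, pose)
    with np.errstate(divide="ignore"):
        loss = 40.0 * np.log10(np.where(rng > 0, rng, np.inf))
    if medium.absorption_enabled:
        alpha = atmospheric_absorption_db_per_m(
            frequency if frequency is not None else 70e3, medium)
        loss = loss + 2.0 * rng * alpha
    gain = beam_gain_db(az, el, pose.beam)
    budget = loss - 2.0 * gain          # gain <= 0, so this adds |gain|
    return np.where(front, budget, np.inf)


def _leaf_amplitude_factors(discs: DiscSet, pose: SonarPose, medium: Medium):
    """Per-disc f-independent pieces: (B, r) with
    ``H(f) = f * B * exp(-j*2*pi*f*2*r/c)`` under the cosine disc law and
    no absorption.  B collects beam gains, cos(theta) directivity, the
    ``pi*a**2/c`` disc prefactor and ``1/r**2`` spreading.
    """
    az, el, rng, front = beam_offsets_deg(discs.centers, pose)
    theta = incidence_angles_deg(discs, pose)
    g2 = np.where(front, 10.0 ** (2.0 * beam_gain_db(az, el, pose.beam)
                                  / 20.0), 0.0)
    cos_t = np.cos(np.deg2rad(theta))
    with np.errstate(divide="ignore", invalid="ignore"):
        B = np.where(rng > 0,
                     g2 * np.pi * discs.radii ** 2 * cos_t
                     / (medium.sound_speed * rng ** 2), 0.0)
    return B, rng


def leaf_transfer_function(leaf, pose: SonarPose,
                           grid: FrequencyGrid | None = None,
                           medium: Medium | None = None,
                           mode: str = "cosine") -> np.ndarray:
    """Complex transfer function of a single leaf on the frequency grid."""
    grid = grid or FrequencyGrid()
    medium = medium or Medium()
    discs = as_disc_set([leaf] if not isinstance(leaf, DiscSet) else leaf)
    H = _transfer_matrix(discs, pose, grid, medium, mode)
    return H[0] if H.shape[0] == 1 else H


def _transfer_matrix(discs: DiscSet, pose: SonarPose, grid: FrequencyGrid,
                     medium: Medium, mode: str = "cosine") -> np.ndarray:
    """(N, n_points) transfer functions; exact per-leaf evaluation."""
    from .acoustics import disc_backscatter_amplitude

    az, el, rng, front = beam_offsets_deg(discs.centers, pose)
    if np.any(rng < 1.0):
        warnings.warn("leaf closer than 1 m: far-field assumption violated",
                      stacklevel=2)
    theta = incidence_angles_deg(discs, pose)
    f = grid.frequencies
    g2 = np.where(front, 10.0 ** (2.0 * beam_gain_db(az, el, pose.beam)
                                  / 20.0), 0.0)
    amp = disc_backscatter_amplitude(f[None, :], discs.radii[:, None],
                                     theta[:, None], medium, mode=mode)
    with np.errstate(divide="ignore", invalid="ignore"):
        spread = np.where(rng > 0, 1.0 / rng ** 2, 0.0)
    H = g2[:, None] * spread[:, None] * amp
    if medium.absorption_enabled:
        alpha = atmospheric_absorption_db_per_m(f, medium)
        H = H * 10.0 ** (-2.0 * rng[:, None] * alpha[None, :] / 20.0)
    tau = 2.0 * rng / medium.sound_speed
    H = H * np.exp(-2j * np.pi * f[None, :] * tau[:, None])
    return H


def _sum_direct(discs: DiscSet, pose: SonarPose, grid: FrequencyGrid,
                medium: Medium, mode: str, chunk: int = 2048) -> np.ndarray:
    total = np.zeros(grid.n_points, dtype=complex)
    for i in range(0, len(discs), chunk):
        sub = DiscSet(discs.centers[i:i + chunk], discs.normals[i:i + chunk],
                      discs.radii[i:i + chunk])
        total += _transfer_matrix(sub, pose, grid, medium, mode).sum(axis=0)
    return total


def _sum_binned(discs: DiscSet, pose: SonarPose, grid: FrequencyGrid,
                medium: Medium, sampling_rate: float,
                n_taylor: int | None = None) -> np.ndarray:
    """Delay-binned evaluation of the cosine-law spectrum (see module doc).

    Round-trip delays are split into an integer output-sample delay and a
    sub-sample residual.  Each leaf's residual frequency dependence across
    the band — the fractional-delay phase, and (when enabled) the deviation
    of atmospheric absorption from its band-centre value, fitted by a
    quadratic in frequency — is expanded in Taylor terms about the band
    centre.  Worst-case relative truncation error is ~2e-8 without
    absorption and below 1e-3 with it (far leaves only).
    """
    n_full, k0 = grid.full_record_bins(sampling_rate)
    B, rng = _leaf_amplitude_factors(discs, pose, medium)
    keep = (B != 0) & (rng > 0)
    B, rng = B[keep], rng[keep]
    if B.size == 0:
        return np.zeros(grid.n_points, dtype=complex)

    tau = 2.0 * rng / medium.sound_speed
    dt = 1.0 / sampling_rate
    n_bin = np.round(tau / dt).astype(int) % n_full
    delta = tau - np.round(tau / dt) * dt
    fc = grid.center
    f = grid.frequencies
    df = f - fc

    # per-leaf exponent of the residual band dependence:
    # exp(a*x + b*x**2), x = f - fc
    a = -2j * np.pi * delta
    if medium.absorption_enabled:
        # two-way amplitude factor exp(-q(f)*r), q = alpha*ln(10)/10;
        # quadratic fit of q across the band
        q = atmospheric_absorption_db_per_m(f, medium) * np.log(10.0) / 10.0
        Q2, Q1, Q0 = np.polyfit(df, q, 2)
        B = B * np.exp(-Q0 * rng)
        a = a - Q1 * rng
        b = -Q2 * rng
        n_taylor = n_taylor or 9
    else:
        b = np.zeros_like(rng)
        n_taylor = n_taylor or 5

    w = B * np.exp(-2j * np.pi * fc * delta)
    # coefficients of exp(a*x + b*x**2) = sum_k c_k x^k via the recursion
    # (k+1) c_{k+1} = a c_k + 2 b c_{k-1}
    G = np.zeros(grid.n_points, dtype=complex)
    c_prev = np.zeros_like(w)
    c_curr = np.ones_like(w)
    for k in range(n_taylor):
        M_w = w * c_curr
        M = (np.bincount(n_bin, weights=M_w.real, minlength=n_full)
             + 1j * np.bincount(n_bin, weights=M_w.imag, minlength=n_full))
        G += np.fft.fft(M)[k0:k0 + grid.n_points] * df ** k
        c_next = (a * c_curr + 2.0 * b * c_prev) / (k + 1.0)
        c_prev, c_curr = c_curr, c_next
    return f * G


def band_to_time(spectrum: np.ndarray, grid: FrequencyGrid | None = None,
                 sampling_rate: float = DEFAULT_SAMPLING_RATE) -> np.ndarray:
    """Convert a band spectrum to a real waveform at the output rate.

    The band spectrum is multiplied by a Hanning window of its own length,
    embedded at its physical bin positions in a conjugate-symmetric full
    spectrum with the same bin spacing, and inverse transformed.  The
    default grid yields a 40000-sample (0.1 s) record at 400 kHz.
    """
    grid = grid or FrequencyGrid()
    spectrum = np.asarray(spectrum)
    if spectrum.shape != (grid.n_points,):
        raise ValueError("spectrum length must match the grid")
    n_full, k0 = grid.full_record_bins(sampling_rate)
    half = np.zeros(n_full // 2 + 1, dtype=complex)
    half[k0:k0 + grid.n_points] = spectrum * np.hanning(grid.n_points)
    return np.fft.irfft(half, n=n_full)


def synthesize_echo(leaves, pose: SonarPose,
                    grid: FrequencyGrid | None = None,
                    medium: Medium | None = None,
                    loss_threshold_db: float | None = 80.0,
                    mode: str = "cosine",
                    method: str = "auto",
                    sampling_rate: float = DEFAULT_SAMPLING_RATE
                    ) -> EchoWaveform:
    """Synthesise the echo of a disc cloud seen from a sonar pose.

    Leaves whose two-way loss plus two-way beam attenuation exceeds
    ``loss_threshold_db`` are excluded (pass None to skip the filter; back
    half-space leaves contribute nothing either way); the rest are summed
    coherently in the frequency domain and inverse transformed.

    ``method`` is ``direct``, ``binned`` or ``auto`` (binned for large
    clouds whenever the cosine law with no absorption makes it applicable).
    """
    grid = grid or FrequencyGrid()
    medium = medium or Medium()
    discs = as_disc_set(leaves)

    if len(discs) and loss_threshold_db is not None:
        budget = two_way_budget_db(discs, pose, medium, grid.center)
        discs = discs.select(budget <= loss_threshold_db)

    binned_ok = mode == "cosine"
    if method == "auto":
        method = "binned" if (binned_ok and len(discs) > 2000) else "direct"
    if method == "binned" and not binned_ok:
        raise ValueError("binned synthesis requires the cosine disc law")

    if len(discs) == 0:
        spectrum = np.zeros(grid.n_points, dtype=complex)
    elif method == "binned":
        spectrum = _sum_binned(discs, pose, grid, medium, sampling_rate)
    elif method == "direct":
        spectrum = _sum_direct(discs, pose, grid, medium, mode)
    else:
        raise ValueError(f"unknown method {method!r}")

    samples = band_to_time(spectrum, grid, sampling_rate)
    return EchoWaveform(samples, sampling_rate, spectrum, grid)
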
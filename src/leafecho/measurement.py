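"""Signal-processing utilities for physical leaf/disc measurements.

Covers the excitation and analysis chain of an impulse-response
measurement rig: maximum-length-sequence (MLS) pulses, recovery of the
impulse response by circular cross-correlation, sub-sample peak refinement
by parabolic interpolation of the envelope, the equivalent-radius
conversion for measured leaf areas, and the scalar least-squares fit of
disc-model predictions to measured target strengths.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.signal import hilbert

__all__ = [
    "MLSConfig",
    "generate_mls",
    "mls_impulse_response",
    "refine_peak",
    "aggregate_target_strength",
    "equivalent_radius",
    "fit_scale",
    "load_leaf_radius_table",
]


@dataclass(frozen=True)
class MLSConfig:
    """Maximum-length-sequence excitation parameters.

    ``taps`` are the feedback tap positions of the shift register
    (exponents of the characteristic polynomial, highest first); the
    default octic polynomial x^8 + x^6 + x^5 + x^4 + 1 is primitive over
    GF(2), giving the full period 2**8 - 1 = 255.  At 500 kHz that is a
    0.51 ms pulse.
    """

    register_length: int = 8
    taps: tuple[int, ...] = (8, 6, 5, 4)
    sampling_rate: float = 500e3

    @property
    def period(self) -> int:
        return 2 ** self.register_length - 1

    @property
    def pulse_duration(self) -> float:
        return self.period / self.sampling_rate


def generate_mls(config: MLSConfig | None = None) -> np.ndarray:
    """One period of a maximum-length sequence mapped to +-1.

    Runs a Fibonacci LFSR from the all-ones state; if the register returns
    to its start state before 2**m - 1 steps the tap set is not primitive
    and a ValueError is raised.
    """
    config = config or MLSConfig()
    m = config.register_length
    if max(config.taps) != m:
        raise ValueError("highest tap must equal the register length")
    # right-shift Galois form: on a 1 output bit, xor in the polynomial's
    # lower-degree terms and feed the top bit
    mask = (1 << (m - 1))
    for t in config.taps:
        if t != m:
            mask |= 1 << (t - 1)
    state = (1 << m) - 1
    start = state
    out = np.empty(config.period, dtype=int)
    for i in range(config.period):
        out[i] = state & 1
        lsb = state & 1
        state >>= 1
        if lsb:
            state ^= mask
        if state == start and i < config.period - 1:
            raise ValueError("tap set is not primitive: register cycle of "
                             f"length {i + 1} < {config.period}")
    return 2 * out - 1


def mls_impulse_response(recording: np.ndarray,
                         mls: np.ndarray) -> np.ndarray:
    """Recover an impulse response by circular cross-correlation.

    For a periodic MLS drive, one period of the recorded response
    circularly cross-correlated with the sequence and normalised by
    (period + 1) approximates the system's periodic impulse response.
    """
    recording = np.asarray(recording, dtype=float)
    mls = np.asarray(mls, dtype=float)
    if recording.shape != mls.shape:
        raise ValueError("recording must be one MLS period long")
    n = len(mls)
    xc = np.fft.irfft(np.fft.rfft(recording) * np.conj(np.fft.rfft(mls)),
                      n=n)
    return xc / (n + 1)


def refine_peak(impulse_response: np.ndarray,
                window: int = 11) -> tuple[float, float]:
    """Sub-sample peak location and amplitude of an impulse response.

    The envelope (Hilbert magnitude) is computed, an ``window``-point
    segment centred on the discrete maximum is fitted with a 2nd-order
    polynomial in least squares, and the parabola's vertex is returned as
    ``(peak_time_samples, peak_amplitude)``.  A maximum too close to an
    edge clips the window with a warning.
    """
    x = np.asarray(impulse_response, dtype=float)
    if len(x) < window:
        raise ValueError(f"need at least {window} samples")
    env = np.abs(hilbert(x))
    i0 = int(np.argmax(env))
    half = window // 2
    lo, hi = i0 - half, i0 + half + 1
    if lo < 0 or hi > len(env):
        warnings.warn("peak near record edge: fit window clipped",
                      stacklevel=2)
        lo, hi = max(lo, 0), min(hi, len(env))
    t = np.arange(lo, hi, dtype=float)
    c2, c1, c0 = np.polyfit(t - i0, env[lo:hi], 2)
    if c2 >= 0:     # degenerate (flat or concave-up): keep the discrete max
        return float(i0), float(env[i0])
    dt = -c1 / (2.0 * c2)
    amp = c0 + c1 * dt + c2 * dt * dt
    return float(i0 + dt), float(amp)


def aggregate_target_strength(peak_amplitudes) -> float:
    """Median of refined peak amplitudes across repeated echoes.

    The median (not the mean) across all impulse-response maxima of the
    repeated measurements represents a target's acoustic strength.
    """
    vals = np.asarray(list(peak_amplitudes), dtype=float)
    if vals.size == 0:
        raise ValueError("need at least one peak amplitude")
    return float(np.median(vals))


def equivalent_radius(leaf_area):
    """Radius (same length unit) of the circle with the leaf's area."""
    area = np.asarray(leaf_area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("leaf area must be positive")
    r = np.sqrt(area / np.pi)
    return r if r.shape else float(r)


def fit_scale(predictions, measurements) -> tuple[float, float]:
    """Scalar least-squares fit of model predictions to measurements.

    Returns ``(scale, r_squared)`` where ``scale`` minimises
    ``sum((measurements - scale*predictions)**2)`` (closed form
    ``sum(m*p)/sum(p*p)``) and ``r_squared`` is the coefficient of
    determination about the measurement mean.
    """
    p = np.asarray(predictions, dtype=float)
    m = np.asarray(measurements, dtype=float)
    if p.shape != m.shape or p.size < 2:
        raise ValueError("need equal-length arrays of at least 2 points")
    denom = float(np.sum(p * p))
    if denom == 0:
        raise ValueError("predictions must not be all zero")
    scale = float(np.sum(m * p)) / denom
    ss_res = float(np.sum((m - scale * p) ** 2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return scale, r2


def load_leaf_radius_table() -> pd.DataFrame:
    """Packaged table of equivalent leaf radii (cm) across tree species."""
    with resources.files("leafecho.data").joinpath(
            "leaf_equivalent_radii.csv").open() as fh:
        return pd.read_csv(fh)
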
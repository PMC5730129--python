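"""Deterministic toy inputs for testing and demonstration.

Everything here is generated in code from a seed — no stored data.  Each
fixture embeds its own ground truth (window means, expected arrival times,
true peak position) so assertions never have to re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acoustics import BeamSpec
from .geometry import DiscSet, SonarPose

__all__ = [
    "make_envelope_with_window_means",
    "LeafScene",
    "make_leaf_scene",
    "PeakSignal",
    "make_peak_signal",
]


def make_envelope_with_window_means(means, samples_per_window: int
                                    ) -> np.ndarray:
    """Piecewise-constant envelope whose per-window means are exact.

    Window ``i`` of length ``samples_per_window`` holds the constant value
    ``means[i]``, so any windowed-mean statistic sees exactly ``means``.
    """
    means = np.asarray(means, dtype=float)
    if np.any(means < 0):
        raise ValueError("envelope means must be nonnegative")
    if samples_per_window < 1:
        raise ValueError("samples_per_window must be >= 1")
    return np.repeat(means, samples_per_window)


@dataclass
class LeafScene:
    """Discs on known bearings with ground-truth round-trip delays."""

    leaves: DiscSet
    pose: SonarPose
    expected_delays: np.ndarray         # seconds, per leaf
    sound_speed: float


def make_leaf_scene(ranges, incidence_angles=None, radii=None,
                    beamwidth: float = 60.0,
                    sound_speed: float = 343.0) -> LeafScene:
    """Discs placed on the sonar axis at the given ranges.

    ``incidence_angles`` tilt each disc normal away from the sonar
    direction (degrees, default 0 = facing the sonar); ``radii`` default
    to 2 cm.  Ground-truth arrival times ``2*r/c`` are attached.
    """
    ranges = np.atleast_1d(np.asarray(ranges, dtype=float))
    n = len(ranges)
    if np.any(ranges < 1.0):
        raise ValueError("ranges must be >= 1 m (far field)")
    angles = np.zeros(n) if incidence_angles is None else \
        np.atleast_1d(np.asarray(incidence_angles, dtype=float))
    radii = np.full(n, 0.02) if radii is None else \
        np.atleast_1d(np.asarray(radii, dtype=float))

    centers = np.zeros((n, 3))
    centers[:, 0] = ranges
    th = np.deg2rad(angles)
    # tilt normals in the x-z plane: angle 0 faces the sonar (-x)
    normals = np.column_stack([-np.cos(th), np.zeros(n), np.sin(th)])
    pose = SonarPose((0.0, 0.0, 0.0), (1.0, 0.0, 0.0),
                     BeamSpec.symmetric(beamwidth))
    return LeafScene(DiscSet(centers, normals, radii), pose,
                     2.0 * ranges / sound_speed, sound_speed)


@dataclass
class PeakSignal:
    """A sampled envelope peak with its true sub-sample vertex."""

    samples: np.ndarray
    true_peak_time: float               # samples
    true_peak_amplitude: float


def make_peak_signal(n: int = 101, peak_time: float = 50.3,
                     peak_amplitude: float = 1.0, width: float = 8.0,
                     carrier_cycles_per_sample: float = 0.25,
                     noise_db: float | None = None,
                     seed=None) -> PeakSignal:
    """Carrier burst under a Gaussian envelope with a known vertex.

    Optionally adds white noise ``noise_db`` below the peak (e.g. -60).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float)
    env = peak_amplitude * np.exp(-0.5 * ((t - peak_time) / width) ** 2)
    x = env * np.cos(2.0 * np.pi * carrier_cycles_per_sample
                     * (t - peak_time))
    if noise_db is not None:
        x = x + peak_amplitude * 10.0 ** (noise_db / 20.0) \
            * rng.standard_normal(n)
    return PeakSignal(x, peak_time, peak_amplitude)
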
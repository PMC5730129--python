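"""File formats: disc clouds as CSV/JSON, waveforms as WAV, skeletons as PLY.

WAV files are 32-bit float at the waveform's sampling rate (400 kHz by
default), written with :mod:`scipy.io.wavfile`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .geometry import DiscSet
from .synthesis import EchoWaveform

__all__ = [
    "discs_to_csv", "discs_from_csv", "discs_to_json", "discs_from_json",
    "write_wav", "read_wav", "skeleton_to_ply", "spectrum_to_csv",
]

_DISC_COLUMNS = ["x", "y", "z", "nx", "ny", "nz", "radius"]


def _disc_frame(discs: DiscSet) -> pd.DataFrame:
    return pd.DataFrame(
        np.column_stack([discs.centers, discs.normals, discs.radii]),
        columns=_DISC_COLUMNS)


def discs_to_csv(discs: DiscSet, path) -> None:
    _disc_frame(discs).to_csv(path, index=False)


def discs_from_csv(path) -> DiscSet:
    df = pd.read_csv(path)
    return DiscSet(df[["x", "y", "z"]].to_numpy(),
                   df[["nx", "ny", "nz"]].to_numpy(),
                   df["radius"].to_numpy())


def discs_to_json(discs: DiscSet, path) -> None:
    payload = {"discs": _disc_frame(discs).to_dict(orient="records")}
    Path(path).write_text(json.dumps(payload, indent=1))


def discs_from_json(path) -> DiscSet:
    payload = json.loads(Path(path).read_text())
    df = pd.DataFrame(payload["discs"])
    return DiscSet(df[["x", "y", "z"]].to_numpy(),
                   df[["nx", "ny", "nz"]].to_numpy(),
                   df["radius"].to_numpy())


def write_wav(path, waveform, sampling_rate: float | None = None) -> None:
    """Write a waveform (array or EchoWaveform) as 32-bit float WAV."""
    if isinstance(waveform, EchoWaveform):
        samples, rate = waveform.samples, waveform.sampling_rate
    else:
        samples = np.asarray(waveform, dtype=float)
        rate = sampling_rate or 400e3
    wavfile.write(path, int(round(rate)), samples.astype(np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    """Read a WAV file; returns (samples as float64, sampling rate in Hz).

    Integer PCM is rescaled to [-1, 1]; float data is returned as is.
    """
    rate, raw = wavfile.read(path)
    samples = np.asarray(raw, dtype=float)
    if np.issubdtype(raw.dtype, np.integer):
        samples = samples / np.iinfo(raw.dtype).max
    return samples, float(rate)


def spectrum_to_csv(path, spectrum: np.ndarray, frequencies: np.ndarray
                    ) -> None:
    pd.DataFrame({"frequency_hz": frequencies,
                  "re": np.real(spectrum),
                  "im": np.imag(spectrum)}).to_csv(path, index=False)


def skeleton_to_ply(tree, path) -> None:
    """Write the branch skeleton as an ASCII PLY line set."""
    segs = tree.segments
    verts = np.concatenate([[s.start, s.end] for s in segs])
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {len(verts)}",
        "property float x", "property float y", "property float z",
        f"element edge {len(segs)}",
        "property int vertex1", "property int vertex2",
        "end_header",
    ]
    for v in verts:
        lines.append(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f}")
    for i in range(len(segs)):
        lines.append(f"{2 * i} {2 * i + 1}")
    Path(path).write_text("\n".join(lines) + "\n")
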
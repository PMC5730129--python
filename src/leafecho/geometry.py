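"""Disc-cloud container and sonar-pose geometry.

A foliage is a set of circular discs stored struct-of-arrays for vectorised
acoustics; :class:`DiscSet` converts to and from lists of
:class:`~leafecho.acoustics.LeafDisc` for scalar-level work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustics import BeamSpec, LeafDisc

__all__ = ["DiscSet", "SonarPose", "beam_offsets_deg", "incidence_angles_deg"]


@dataclass
class DiscSet:
    """A cloud of circular disc scatterers (vectorised).

    Attributes
    ----------
    centers : (N, 3) float array, metres
    normals : (N, 3) float array, unit vectors
    radii : (N,) float array, metres
    """

    centers: np.ndarray
    normals: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=float))
        self.radii = np.atleast_1d(np.asarray(self.radii, dtype=float))
        n = len(self.radii)
        if self.centers.shape != (n, 3) or self.normals.shape != (n, 3):
            raise ValueError("inconsistent DiscSet array shapes")

    def __len__(self) -> int:
        return len(self.radii)

    @classmethod
    def empty(cls) -> "DiscSet":
        return cls(np.empty((0, 3)), np.empty((0, 3)), np.empty(0))

    @classmethod
    def from_discs(cls, discs) -> "DiscSet":
        if len(discs) == 0:
            return cls.empty()
        return cls(np.array([d.center for d in discs], dtype=float),
                   np.array([d.normal for d in discs], dtype=float),
                   np.array([d.radius for d in discs], dtype=float))

    def to_discs(self) -> list[LeafDisc]:
        return [LeafDisc(tuple(c), tuple(n), float(r))
                for c, n, r in zip(self.centers, self.normals, self.radii)]

    def select(self, mask) -> "DiscSet":
        return DiscSet(self.centers[mask], self.normals[mask],
                       self.radii[mask])

    def transformed(self, rotation: np.ndarray | None = None,
                    translation=(0.0, 0.0, 0.0)) -> "DiscSet":
        """Rigidly transform the cloud (rotation then translation)."""
        c, n = self.centers, self.normals
        if rotation is not None:
            R = np.asarray(rotation, dtype=float)
            c = c @ R.T
            n = n @ R.T
        return DiscSet(c + np.asarray(translation, dtype=float), n,
                       self.radii.copy())

    @staticmethod
    def concatenate(sets) -> "DiscSet":
        sets = [s for s in sets if len(s)]
        if not sets:
            return DiscSet.empty()
        return DiscSet(np.concatenate([s.centers for s in sets]),
                       np.concatenate([s.normals for s in sets]),
                       np.concatenate([s.radii for s in sets]))


def as_disc_set(leaves) -> DiscSet:
    """Coerce a DiscSet or an iterable of LeafDisc into a DiscSet."""
    if isinstance(leaves, DiscSet):
        return leaves
    return DiscSet.from_discs(list(leaves))


@dataclass(frozen=True)
class SonarPose:
    """Monostatic sonar: position, aim direction, and beam widths."""

    position: tuple[float, float, float]
    aim: tuple[float, float, float]
    beam: BeamSpec = field(default_factory=lambda: BeamSpec.symmetric(50.0))

    def __post_init__(self) -> None:
        aim = np.asarray(self.aim, dtype=float)
        nrm = np.linalg.norm(aim)
        if nrm == 0:
            raise ValueError("aim must be a nonzero vector")
        object.__setattr__(self, "aim", tuple(aim / nrm))

    def frame(self) -> np.ndarray:
        """Right-handed orthonormal beam frame (x=aim, y=left, z=up).

        The beam 'up' axis is the projection of world z onto the plane
        perpendicular to the aim; for a vertical aim, world x seeds the
        frame instead.
        """
        x = np.asarray(self.aim, dtype=float)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(x, ref)) > 0.999:
            ref = np.array([1.0, 0.0, 0.0])
        y = np.cross(ref, x)
        y /= np.linalg.norm(y)
        z = np.cross(x, y)
        return np.stack([x, y, z])


def beam_offsets_deg(points: np.ndarray, pose: SonarPose):
    """Azimuth/elevation offsets (deg) of world points in the beam frame.

    Returns ``(az, el, range, in_front)``.  Azimuth is the angle in the
    beam's horizontal plane, elevation the angle out of it; ``in_front``
    marks points in the forward half-space of the sonar (points behind
    receive no beam gain by convention).
    """
    p = np.atleast_2d(points) - np.asarray(pose.position, dtype=float)
    R = pose.frame()
    local = p @ R.T
    rng = np.linalg.norm(local, axis=1)
    x, y, z = local[:, 0], local[:, 1], local[:, 2]
    horiz = np.hypot(x, y)
    az = np.rad2deg(np.arctan2(y, x))
    el = np.rad2deg(np.arctan2(z, horiz))
    return az, el, rng, x > 0


def incidence_angles_deg(discs: DiscSet, pose: SonarPose):
    """Angle (deg, in [0, 90]) between each disc normal and the sonar.

    The monostatic incidence angle is measured between the disc normal and
    the unit vector from the disc towards the sonar; the disc's front/back
    symmetry folds it into [0, 90].
    """
    to_sonar = np.asarray(pose.position, dtype=float) - discs.centers
    r = np.linalg.norm(to_sonar, axis=1)
    r = np.where(r > 0, r, 1.0)
    cosang = np.abs(np.einsum("ij,ij->i", discs.normals, to_sonar) / r)
    return np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
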
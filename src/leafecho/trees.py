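"""Biomimetic L-system tree models with attached leaf discs.

Two species are modelled:

* **Eastern white pine** (*Pinus strobus*): a monopodial bifurcating
  L-system grown to level 13.  One child of every branch continues the
  mother's direction (the stem), the other deviates by a branching angle
  that shrinks linearly from 90 deg at the first level to 20 deg at the
  13th.  Needles are represented by bundles of small discs placed spirally
  around the distal end of every terminal branch.
* **Ginkgo** (*Ginkgo biloba*): a ternary L-system grown to level 8.  Each
  branching produces one central child (contraction 0.83) and two side
  children deviating 50 deg to opposite sides (contraction 0.62).  Leaves
  (large discs) sit on short-shoot nodes spaced evenly along every branch.

Finally, because a single L-system realisation looks sparser than a real
tree, the whole tree is unioned with a copy of itself rotated about the
vertical axis (:func:`densify_by_copy`).

The deviating-child plane is the plane through the mother branch
perpendicular to the plane spanned by the mother and its own mother
("the branch two growth levels prior").  Where that rule is degenerate
(mother parallel to grandmother, which happens along every monopodial
stem), the previous branching plane is rotated by 90 deg about the branch
axis, which spreads successive side branches around the stem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import DiscSet

__all__ = [
    "SpeciesParams",
    "BranchSegment",
    "TreeModel",
    "pine_params",
    "ginkgo_params",
    "grow_pine",
    "grow_ginkgo",
    "place_pine_needles",
    "place_ginkgo_leaves",
    "densify_by_copy",
    "build_tree",
]

GOLDEN_ANGLE_DEG = 137.5


@dataclass(frozen=True)
class SpeciesParams:
    """All tunable parameters of one species' L-system and leaf placement.

    Lengths in metres, angles in degrees.
    """

    species: str
    branching_type: str               # "bifurcation" | "ternary"
    max_level: int
    initial_branch_length: float
    contraction_stem: float           # central/stem child
    contraction_side: float           # deviating child(ren)
    angle_start: float                # deviating angle at level 1
    angle_end: float                  # deviating angle at max_level
    # pine needle placement
    n_bundles: int = 30
    bundle_length: float = 0.15
    needle_zone: float = 0.045
    bundle_angle: float = 75.0
    discs_per_bundle: int = 5
    cube_edge: float = 0.01
    spiral_increment: float = GOLDEN_ANGLE_DEG
    # ginkgo leaf placement
    nodes_per_branch: int = 4
    leaves_per_node: int = 4
    tip_box: tuple[float, float, float] = (0.10, 0.10, 0.20)
    inbranch_scale: float = 0.10
    inbranch_weight: float = 0.1
    # leaf disc radii
    radius_mean: float = 0.0
    radius_sd: float = 0.0
    # densification
    copy_rotation_deg: float = 180.0
    copy_raise: bool = False

    def __post_init__(self) -> None:
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")
        for c in (self.contraction_stem, self.contraction_side):
            if not 0.0 < c < 1.0:
                raise ValueError("contraction ratios must be in (0, 1)")
        for a in (self.angle_start, self.angle_end):
            if not 0.0 <= a <= 90.0:
                raise ValueError("branching angles must be in [0, 90] deg")

    def deviation_angle(self, level: int) -> float:
        """Deviating-child branching angle used at the given mother level.

        Linear interpolation between ``angle_start`` at level 1 and
        ``angle_end`` at ``max_level``.
        """
        if self.max_level == 1:
            return self.angle_start
        frac = (level - 1) / (self.max_level - 1)
        return self.angle_start + frac * (self.angle_end - self.angle_start)


def pine_params(max_level: int = 13,
                initial_branch_length: float = 1.6) -> SpeciesParams:
    """Eastern white pine preset (bifurcating, level 13, 2 mm needle discs)."""
    return SpeciesParams(
        species="pine", branching_type="bifurcation", max_level=max_level,
        initial_branch_length=initial_branch_length,
        contraction_stem=0.9, contraction_side=0.7,
        angle_start=90.0, angle_end=20.0,
        radius_mean=0.002, radius_sd=0.0002,
        copy_rotation_deg=180.0, copy_raise=False,
    )


def ginkgo_params(max_level: int = 8,
                  initial_branch_length: float = 2.0) -> SpeciesParams:
    """Ginkgo preset (ternary, level 8, 2.5 cm leaf discs)."""
    return SpeciesParams(
        species="ginkgo", branching_type="ternary", max_level=max_level,
        initial_branch_length=initial_branch_length,
        contraction_stem=0.83, contraction_side=0.62,
        angle_start=50.0, angle_end=50.0,
        radius_mean=0.025, radius_sd=0.0025,
        copy_rotation_deg=90.0, copy_raise=True,
    )


@dataclass
class BranchSegment:
    """One branch of the skeleton, from ``start`` to ``end``."""

    start: np.ndarray
    end: np.ndarray
    level: int
    parent: int | None
    is_terminal: bool

    @property
    def direction(self) -> np.ndarray:
        d = self.end - self.start
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(self.end - self.start))


@dataclass
class TreeModel:
    """An L-system tree: branch skeleton plus attached leaf discs."""

    species: str
    params: SpeciesParams
    segments: list[BranchSegment]
    leaves: DiscSet = field(default_factory=DiscSet.empty)
    max_level: int = 0
    rng_seed: int | None = None

    @property
    def terminal_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.segments)
                         if s.is_terminal], dtype=int)

    def leaf_count(self) -> int:
        return len(self.leaves)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(min, max) corners over branch endpoints and leaf centers."""
        pts = [np.array([s.start for s in self.segments]),
               np.array([s.end for s in self.segments])]
        if len(self.leaves):
            pts.append(self.leaves.centers)
        allp = np.concatenate(pts)
        return allp.min(axis=0), allp.max(axis=0)

    def center(self) -> np.ndarray:
        lo, hi = self.bounding_box()
        return 0.5 * (lo + hi)


def _rotate_about(v: np.ndarray, axis: np.ndarray, angle_deg: float):
    """Rodrigues rotation of v about a unit axis."""
    th = np.deg2rad(angle_deg)
    return (v * np.cos(th) + np.cross(axis, v) * np.sin(th)
            + axis * np.dot(axis, v) * (1.0 - np.cos(th)))


def _grow_skeleton(params: SpeciesParams) -> list[BranchSegment]:
    """Deterministic recursive growth of the branch skeleton.

    Each stack entry carries (start, direction, length, level, parent index,
    parent direction, fallback plane normal).
    """
    root_dir = np.array([0.0, 0.0, 1.0])
    # pseudo-grandparent seeding the first branching plane in the x-z plane
    seed_parent_dir = np.array([0.0, 1.0, 0.0])
    seed_normal = np.array([1.0, 0.0, 0.0])

    segments: list[BranchSegment] = []
    stack = [(np.zeros(3), root_dir, params.initial_branch_length, 1, None,
              seed_parent_dir, seed_normal)]
    while stack:
        start, direction, length, level, parent, pdir, fallback_n = stack.pop()
        end = start + direction * length
        idx = len(segments)
        terminal = level >= params.max_level
        segments.append(BranchSegment(start, end, level, parent, terminal))
        if terminal:
            continue

        cross = np.cross(direction, pdir)
        nc = np.linalg.norm(cross)
        if nc > 1e-9:
            plane_n = cross / nc
        else:
            # degenerate (straight stem): spin the inherited plane by 90 deg
            plane_n = _rotate_about(fallback_n, direction, 90.0)
            plane_n -= np.dot(plane_n, direction) * direction
            plane_n /= np.linalg.norm(plane_n)

        angle = params.deviation_angle(level)
        ca, sa = np.cos(np.deg2rad(angle)), np.sin(np.deg2rad(angle))
        if params.branching_type == "bifurcation":
            children = [
                (direction, params.contraction_stem),
                (ca * direction + sa * plane_n, params.contraction_side),
            ]
        elif params.branching_type == "ternary":
            children = [
                (direction, params.contraction_stem),
                (ca * direction + sa * plane_n, params.contraction_side),
                (ca * direction - sa * plane_n, params.contraction_side),
            ]
        else:
            raise ValueError(
                f"unknown branching_type {params.branching_type!r}")
        for cdir, contraction in children:
            cdir = cdir / np.linalg.norm(cdir)
            stack.append((end, cdir, length * contraction, level + 1, idx,
                          direction, plane_n))
    return segments


def grow_pine(params: SpeciesParams | None = None,
              seed: int | None = None) -> TreeModel:
    """Grow a pine skeleton (no needles yet; growth is deterministic)."""
    params = params or pine_params()
    if params.branching_type != "bifurcation":
        raise ValueError("pine requires a bifurcation L-system")
    return TreeModel("pine", params, _grow_skeleton(params),
                     max_level=params.max_level, rng_seed=seed)


def grow_ginkgo(params: SpeciesParams | None = None,
                seed: int | None = None) -> TreeModel:
    """Grow a ginkgo skeleton (no leaves yet; growth is deterministic)."""
    params = params or ginkgo_params()
    if params.branching_type != "ternary":
        raise ValueError("ginkgo requires a ternary L-system")
    return TreeModel("ginkgo", params, _grow_skeleton(params),
                     max_level=params.max_level, rng_seed=seed)


def _truncated_normal(rng, mean, sd, size):
    """Gaussian draws with nonpositive values redrawn (radius > 0)."""
    out = rng.normal(mean, sd, size)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out <= 0
    return out


def _perp_frame(u: np.ndarray):
    """Orthonormal (e1, e2) perpendicular to each row of unit vectors u."""
    ref = np.tile(np.array([0.0, 0.0, 1.0]), (len(u), 1))
    near_z = np.abs(u[:, 2]) > 0.999
    ref[near_z] = [1.0, 0.0, 0.0]
    e1 = np.cross(ref, u)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u, e1)
    return e1, e2


def place_pine_needles(tree: TreeModel, seed: int | None = None) -> TreeModel:
    """Attach needle discs to every terminal branch of a pine.

    Per terminal branch: ``n_bundles`` bundle origins spirally spaced over
    the distal ``needle_zone`` starting from the tip, each bundle leaving
    the branch at ``bundle_angle`` from the branch axis; each bundle is
    replaced by ``discs_per_bundle`` discs at positions uniform in a cube
    of edge ``cube_edge`` centred on the bundle tip.  The vector from the
    bundle origin to the sampled point lies in the disc plane (the disc
    normal is drawn uniformly among directions perpendicular to it).
    """
    if tree.species != "pine":
        raise ValueError("place_pine_needles requires a pine tree")
    p = tree.params
    rng = np.random.default_rng(seed)

    term = [s for s in tree.segments if s.is_terminal]
    if not term:
        return tree
    starts = np.array([s.start for s in term])
    ends = np.array([s.end for s in term])
    u = ends - starts
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    e1, e2 = _perp_frame(u)

    T, nb, nd = len(term), p.n_bundles, p.discs_per_bundle
    s_axial = np.linspace(0.0, p.needle_zone, nb)           # from the tip
    phi = np.deg2rad(p.spiral_increment) * np.arange(nb)
    ca = np.cos(np.deg2rad(p.bundle_angle))
    sa = np.sin(np.deg2rad(p.bundle_angle))

    # (T, nb, 3) bundle origins and directions
    origins = ends[:, None, :] - s_axial[None, :, None] * u[:, None, :]
    radial = (np.cos(phi)[None, :, None] * e1[:, None, :]
              + np.sin(phi)[None, :, None] * e2[:, None, :])
    vdir = ca * u[:, None, :] + sa * radial
    tips = origins + p.bundle_length * vdir

    # (T, nb, nd, 3) disc centers in a world-axis-aligned cube on each tip
    jitter = rng.uniform(-0.5 * p.cube_edge, 0.5 * p.cube_edge,
                         (T, nb, nd, 3))
    centers = tips[:, :, None, :] + jitter

    # in-plane axis: bundle origin -> sampled point; normal uniform in the
    # perpendicular plane
    w = centers - origins[:, :, None, :]
    w /= np.linalg.norm(w, axis=-1, keepdims=True)
    q = rng.standard_normal((T, nb, nd, 3))
    q -= np.einsum("...i,...i->...", q, w)[..., None] * w
    q /= np.linalg.norm(q, axis=-1, keepdims=True)

    n_total = T * nb * nd
    radii = _truncated_normal(rng, p.radius_mean, p.radius_sd, n_total)
    leaves = DiscSet(centers.reshape(-1, 3), q.reshape(-1, 3), radii)
    return replace(tree, leaves=leaves, rng_seed=seed)


def place_ginkgo_leaves(tree: TreeModel, seed: int | None = None) -> TreeModel:
    """Attach leaf discs to every branch of a ginkgo.

    Four evenly spaced leaf nodes divide each branch into four equal parts
    with one node at the tip.  Tip nodes of terminal branches are oriented
    along the branch and their four leaves are drawn uniformly from a
    ``tip_box`` (long axis along the branch) centred on the node.  All
    other nodes are oriented perpendicular to their branch — the first at
    a random azimuth, each subsequent node rotated 90 deg from its
    predecessor — and their leaves are displaced to alternating sides by
    ``inbranch_scale * (node_direction + inbranch_weight * U[-1,1]^3)``.
    """
    if tree.species != "ginkgo":
        raise ValueError("place_ginkgo_leaves requires a ginkgo tree")
    p = tree.params
    rng = np.random.default_rng(seed)

    segs = tree.segments
    starts = np.array([s.start for s in segs])
    ends = np.array([s.end for s in segs])
    is_term = np.array([s.is_terminal for s in segs])
    u = ends - starts
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    e1, e2 = _perp_frame(u)

    B, nn, nl = len(segs), p.nodes_per_branch, p.leaves_per_node
    fracs = (np.arange(1, nn + 1) / nn)                  # tip node last
    nodes = starts[:, None, :] + fracs[None, :, None] * (ends - starts)[:, None, :]

    # perpendicular node orientations: random first azimuth, +90 deg steps
    psi0 = rng.uniform(0.0, 2.0 * np.pi, B)
    psi = psi0[:, None] + 0.5 * np.pi * np.arange(nn)[None, :]
    ndir = (np.cos(psi)[..., None] * e1[:, None, :]
            + np.sin(psi)[..., None] * e2[:, None, :])   # (B, nn, 3)
    # tip nodes of terminal branches point along the branch
    tip_along = is_term[:, None] & (np.arange(nn) == nn - 1)[None, :]
    ndir = np.where(tip_along[..., None], u[:, None, :], ndir)

    # in-branch leaves: alternating sides plus a weighted random vector
    signs = np.where(np.arange(nl) % 2 == 0, 1.0, -1.0)
    uvec = rng.uniform(-1.0, 1.0, (B, nn, nl, 3))
    disp = p.inbranch_scale * (signs[None, None, :, None] * ndir[:, :, None, :]
                               + p.inbranch_weight * uvec)

    # terminal tip nodes: uniform draw in the tip box (long axis along node)
    box = np.asarray(p.tip_box)
    frac_box = rng.uniform(-0.5, 0.5, (B, nl, 3)) * box[None, None, :]
    t_e1, t_e2 = e1, e2
    tip_disp = (frac_box[..., 0, None] * t_e1[:, None, :]
                + frac_box[..., 1, None] * t_e2[:, None, :]
                + frac_box[..., 2, None] * u[:, None, :])
    disp[:, nn - 1, :, :] = np.where(is_term[:, None, None],
                                     tip_disp, disp[:, nn - 1, :, :])

    centers = nodes[:, :, None, :] + disp
    normals = disp / np.linalg.norm(disp, axis=-1, keepdims=True)
    radii = _truncated_normal(rng, p.radius_mean, p.radius_sd, B * nn * nl)
    leaves = DiscSet(centers.reshape(-1, 3), normals.reshape(-1, 3), radii)
    return replace(tree, leaves=leaves, rng_seed=seed)


def densify_by_copy(tree: TreeModel) -> TreeModel:
    """Union the tree with a rotated copy of itself to increase density.

    The copy is rotated about the vertical axis through the trunk base by
    ``params.copy_rotation_deg`` (180 deg for pine, 90 deg for ginkgo); the
    ginkgo copy is additionally raised by half the initial branch length so
    that branches interleave along the stem.  Leaf and segment counts
    exactly double.
    """
    p = tree.params
    th = np.deg2rad(p.copy_rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    dz = np.array([0.0, 0.0, 0.5 * p.initial_branch_length]) \
        if p.copy_raise else np.zeros(3)

    n0 = len(tree.segments)
    copy_segs = [BranchSegment(R @ s.start + dz, R @ s.end + dz, s.level,
                               None if s.parent is None else s.parent + n0,
                               s.is_terminal)
                 for s in tree.segments]
    leaves = DiscSet.concatenate(
        [tree.leaves, tree.leaves.transformed(rotation=R, translation=dz)])
    return replace(tree, segments=tree.segments + copy_segs, leaves=leaves)


def build_tree(species: str, seed: int | None = None,
               params: SpeciesParams | None = None,
               densify: bool = True) -> TreeModel:
    """Grow a full tree with leaves: skeleton, leaf placement, copy union."""
    if params is None:
        params = pine_params() if species == "pine" else ginkgo_params()
    if species == "pine":
        tree = place_pine_needles(grow_pine(params), seed)
    elif species == "ginkgo":
        tree = place_ginkgo_leaves(grow_ginkgo(params), seed)
    else:
        raise ValueError(f"unknown species {species!r}")
    return densify_by_copy(tree) if densify else tree
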
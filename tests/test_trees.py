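"""L-system growth rules, leaf placement counts, and densification."""

import numpy as np
import pytest

from leafecho.trees import (build_tree, densify_by_copy, ginkgo_params,
                            grow_ginkgo, grow_pine, place_ginkgo_leaves,
                            place_pine_needles, pine_params)


def small_pine(levels):
    return grow_pine(pine_params(max_level=levels,
                                 initial_branch_length=1.0))


def small_ginkgo(levels):
    return grow_ginkgo(ginkgo_params(max_level=levels,
                                     initial_branch_length=1.0))


class TestSkeletonGrowth:
    @pytest.mark.parametrize("levels", [1, 2, 3, 4, 5])
    def test_pine_counts_match_binary_recursion(self, levels):
        tree = small_pine(levels)
        terminals = sum(s.is_terminal for s in tree.segments)
        assert terminals == 2 ** (levels - 1)
        assert len(tree.segments) == 2 ** levels - 1

    @pytest.mark.parametrize("levels", [1, 2, 3, 4, 5])
    def test_ginkgo_counts_match_ternary_recursion(self, levels):
        tree = small_ginkgo(levels)
        terminals = sum(s.is_terminal for s in tree.segments)
        assert terminals == 3 ** (levels - 1)
        assert len(tree.segments) == (3 ** levels - 1) // 2

    def test_pine_angle_schedule_endpoints(self):
        p = pine_params()
        assert p.deviation_angle(1) == pytest.approx(90.0)
        assert p.deviation_angle(13) == pytest.approx(20.0)
        # per-level decrement (90-20)/12 ~ 5.8 deg
        assert p.deviation_angle(1) - p.deviation_angle(2) == \
            pytest.approx(70.0 / 12.0)

    def test_contraction_ratios_along_paths(self):
        tree = small_pine(4)
        for seg in tree.segments:
            if seg.parent is None:
                continue
            parent = tree.segments[seg.parent]
            ratio = seg.length / parent.length
            assert ratio == pytest.approx(0.9) or ratio == pytest.approx(0.7)
            assert seg.level == parent.level + 1
            np.testing.assert_allclose(seg.start, parent.end)

    def test_ginkgo_side_branch_angle_and_contraction(self):
        tree = small_ginkgo(2)
        trunk = tree.segments[0]
        children = [s for s in tree.segments if s.parent == 0]
        assert len(children) == 3
        angles = sorted(np.rad2deg(np.arccos(np.clip(
            np.dot(s.direction, trunk.direction), -1, 1)))
            for s in children)
        assert angles[0] == pytest.approx(0.0, abs=1e-9)
        assert angles[1] == pytest.approx(50.0)
        assert angles[2] == pytest.approx(50.0)
        lengths = sorted(s.length for s in children)
        assert lengths[0] == pytest.approx(0.62)
        assert lengths[1] == pytest.approx(0.62)
        assert lengths[2] == pytest.approx(0.83)

    def test_branch_lengths_positive_and_shrinking(self):
        tree = small_ginkgo(5)
        assert all(s.length > 0 for s in tree.segments)
        for seg in tree.segments:
            if seg.parent is not None:
                assert seg.length < tree.segments[seg.parent].length


class TestPineNeedles:
    def test_disc_count_per_terminal_branch(self):
        tree = place_pine_needles(small_pine(3), seed=0)
        terminals = sum(s.is_terminal for s in tree.segments)
        assert len(tree.leaves) == terminals * 30 * 5

    def test_radius_distribution(self):
        tree = place_pine_needles(small_pine(6), seed=1)
        radii = tree.leaves.radii
        assert radii.mean() == pytest.approx(0.002, rel=0.02)
        assert radii.std() == pytest.approx(0.0002, rel=0.1)
        assert np.all(radii > 0)

    def test_discs_near_their_terminal_branches(self):
        tree = place_pine_needles(small_pine(3), seed=2)
        tips = np.array([s.end for s in tree.segments if s.is_terminal])
        d = np.linalg.norm(tree.leaves.centers[:, None, :]
                           - tips[None, :, :], axis=-1).min(axis=1)
        # bundle length 15 cm + needle zone 4.5 cm + half cube diagonal
        assert np.all(d <= 0.15 + 0.045 + np.sqrt(3) / 2 * 0.01 + 1e-9)

    def test_normals_are_unit_vectors(self):
        tree = place_pine_needles(small_pine(4), seed=3)
        np.testing.assert_allclose(
            np.linalg.norm(tree.leaves.normals, axis=1), 1.0, atol=1e-12)

    def test_reproducible_under_seed(self):
        a = place_pine_needles(small_pine(4), seed=7)
        b = place_pine_needles(small_pine(4), seed=7)
        np.testing.assert_array_equal(a.leaves.centers, b.leaves.centers)
        np.testing.assert_array_equal(a.leaves.radii, b.leaves.radii)


class TestGinkgoLeaves:
    def test_sixteen_leaves_per_terminal_branch(self):
        tree = place_ginkgo_leaves(small_ginkgo(1), seed=0)
        # a single (terminal) branch: 4 nodes x 4 leaves
        assert len(tree.leaves) == 16

    def test_leaves_on_every_branch(self):
        tree = place_ginkgo_leaves(small_ginkgo(3), seed=0)
        assert len(tree.leaves) == len(tree.segments) * 16

    def test_radius_distribution(self):
        tree = place_ginkgo_leaves(small_ginkgo(6), seed=1)
        radii = tree.leaves.radii
        assert radii.mean() == pytest.approx(0.025, rel=0.02)
        assert radii.std() == pytest.approx(0.0025, rel=0.1)

    def test_tip_node_leaves_inside_box(self):
        tree = place_ginkgo_leaves(small_ginkgo(1), seed=4)
        seg = tree.segments[0]
        u = seg.direction
        # tip node leaves are the last 4; box 10x10x20 cm on the tip
        tip_leaves = tree.leaves.centers[-4:]
        rel = tip_leaves - seg.end
        along = rel @ u
        perp = rel - np.outer(along, u)
        assert np.all(np.abs(along) <= 0.10 + 1e-9)
        assert np.all(np.linalg.norm(perp, axis=1) <= np.hypot(0.05, 0.05)
                      + 1e-9)


class TestDensify:
    @pytest.mark.parametrize("species,levels", [("pine", 4), ("ginkgo", 3)])
    def test_exactly_doubles_counts(self, species, levels):
        params = pine_params(max_level=levels) if species == "pine" \
            else ginkgo_params(max_level=levels)
        tree = build_tree(species, seed=0, params=params, densify=False)
        dense = densify_by_copy(tree)
        assert len(dense.segments) == 2 * len(tree.segments)
        assert len(dense.leaves) == 2 * len(tree.leaves)

    def test_pine_copy_is_rotation_by_180(self):
        tree = build_tree("pine", seed=1, params=pine_params(max_level=3),
                          densify=False)
        dense = densify_by_copy(tree)
        n = len(tree.leaves)
        orig, copy = dense.leaves.centers[:n], dense.leaves.centers[n:]
        np.testing.assert_allclose(copy[:, 0], -orig[:, 0], atol=1e-12)
        np.testing.assert_allclose(copy[:, 1], -orig[:, 1], atol=1e-12)
        np.testing.assert_allclose(copy[:, 2], orig[:, 2], atol=1e-12)

    def test_ginkgo_copy_raised_by_half_trunk(self):
        params = ginkgo_params(max_level=3)
        tree = build_tree("ginkgo", seed=1, params=params, densify=False)
        dense = densify_by_copy(tree)
        n = len(tree.leaves)
        dz = dense.leaves.centers[n:, 2].mean() \
            - dense.leaves.centers[:n, 2].mean()
        assert dz == pytest.approx(params.initial_branch_length / 2.0)


class TestFullSizeShape:
    """Bounding-box shape of the full default trees versus field dims."""

    def test_pine_height_and_aspect(self):
        tree = build_tree("pine", seed=0)
        lo, hi = tree.bounding_box()
        height = hi[2]                      # above the trunk base
        assert height == pytest.approx(12.0, rel=0.2)
        horizontal = 0.5 * ((hi[0] - lo[0]) + (hi[1] - lo[1]))
        assert horizontal / height == pytest.approx(13.0 / 12.0, rel=0.2)

    def test_ginkgo_height_and_aspect(self):
        tree = build_tree("ginkgo", seed=0)
        lo, hi = tree.bounding_box()
        height = hi[2]
        assert height == pytest.approx(10.0, rel=0.2)
        horizontal = 0.5 * ((hi[0] - lo[0]) + (hi[1] - lo[1]))
        assert horizontal / height == pytest.approx(7.0 / 10.0, rel=0.2)
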
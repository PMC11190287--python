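"""Grain segmentation against a union-find oracle; fill; threshold sweep."""

import numpy as np
import pytest

from biotex.grains import fill_unindexed, reconstruct_grains, threshold_sweep
from biotex.io import EBSDMap
from biotex.orientation import (
    CrystalSymmetry,
    Orientation,
    misorientation_angle,
)
from biotex.synthetic import TextureRecipe, generate_map
from conftest import constant_map


def axis_angle_quat(axis, deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    h = np.radians(deg) / 2
    return np.concatenate([[np.cos(h)], np.sin(h) * axis])


# ---------------------------------------------------------------------------
# independent oracle: plain-python union-find with the same two-pass rule
# ---------------------------------------------------------------------------

def union_find_grains(emap, threshold):
    """Brute-force two-pass segmentation (4-connected, discard < 2 px)."""
    h, w = emap.height, emap.width
    sym = next(iter(emap.phases.values()))
    q = emap.orientations

    def segment(active):
        parent = list(range(h * w))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)

        for y in range(h):
            for x in range(w):
                k = y * w + x
                if not active[y, x]:
                    continue
                for dy, dx in ((0, 1), (1, 0)):
                    yy, xx = y + dy, x + dx
                    if yy < h and xx < w and active[yy, xx]:
                        ang = misorientation_angle(
                            q[k], q[yy * w + xx], sym)
                        if ang < threshold:
                            union(k, yy * w + xx)
        labels = np.zeros((h, w), dtype=int)
        mapping = {}
        for y in range(h):
            for x in range(w):
                if not active[y, x]:
                    continue
                r = find(y * w + x)
                if r not in mapping:
                    mapping[r] = len(mapping) + 1
                labels[y, x] = mapping[r]
        return labels

    labels = segment(emap.indexed)
    counts = np.bincount(labels.ravel())
    small = {g for g in range(1, counts.size) if counts[g] < 2}
    active = emap.indexed & ~np.isin(labels, list(small) or [-1])
    return segment(active)


def two_block_map(angle_deg=30.0, w=8, h=8):
    q1 = np.array([1.0, 0, 0, 0])
    q2 = axis_angle_quat([0, 0, 1], angle_deg)
    quats = np.empty((h * w, 4))
    for y in range(h):
        for x in range(w):
            quats[y * w + x] = q1 if x < w // 2 else q2
    return EBSDMap(
        orientations=Orientation(quats),
        phase=np.ones((h, w), dtype=int),
        band_contrast=np.full((h, w), 150.0),
        step=0.5,
        phases={1: CrystalSymmetry.hexagonal()},
    )


class TestReconstruct:
    def test_constant_map_is_one_grain(self):
        emap = constant_map([1.0, 0, 0, 0], 10, 10)
        gm = reconstruct_grains(emap, 5.0)
        assert gm.n_grains == 1
        assert np.all(gm.label[emap.indexed] == 1)

    def test_two_half_maps_give_two_grains(self):
        gm = reconstruct_grains(two_block_map(30.0), 5.0)
        assert gm.n_grains == 2
        counts = np.bincount(gm.label.ravel())[1:]
        assert sorted(counts) == [32, 32]

    def test_checkerboard_below_threshold_discarded(self):
        """10-degree checkerboard at threshold 1: every pixel isolated,
        all grains sub-2-pixel, so nothing survives the second pass."""
        h = w = 6
        q1 = np.array([1.0, 0, 0, 0])
        q2 = axis_angle_quat([0, 0, 1], 10.0)
        quats = np.array([q1 if (x + y) % 2 == 0 else q2
                          for y in range(h) for x in range(w)])
        emap = EBSDMap(
            orientations=Orientation(quats),
            phase=np.ones((h, w), dtype=int),
            band_contrast=np.full((h, w), 150.0),
            step=0.5,
            phases={1: CrystalSymmetry.hexagonal()},
        )
        gm = reconstruct_grains(emap, 1.0)
        oracle = union_find_grains(emap, 1.0)
        assert np.array_equal(gm.label, oracle)
        assert gm.n_grains == 0

    @pytest.mark.parametrize("threshold", [1.0, 5.0, 9.0, 13.0, 17.0])
    def test_matches_union_find_oracle_on_synthetic_map(self, threshold):
        recipe = TextureRecipe(c_dispersion=8.0,
                               a_rotation_model=("dispersed", 10.0),
                               patch_noise=3.0, unindexed_fraction=0.3)
        emap, _ = generate_map(recipe, 24, 24, seed=4)
        gm = reconstruct_grains(emap, threshold)
        oracle = union_find_grains(emap, threshold)
        assert np.array_equal(gm.label, oracle)

    def test_deterministic(self, small_map):
        emap, _ = small_map
        a = reconstruct_grains(emap, 9.0)
        b = reconstruct_grains(emap, 9.0)
        assert np.array_equal(a.label, b.label)
        assert a.grains.equals(b.grains)

    def test_positive_threshold_required(self, small_map):
        with pytest.raises(ValueError):
            reconstruct_grains(small_map[0], 0.0)

    def test_pixel_counts_sum_to_assigned(self, small_map):
        emap, _ = small_map
        gm = reconstruct_grains(emap, 9.0)
        assert gm.grains["n_pixels"].sum() == (gm.label > 0).sum()

    def test_within_grain_neighbor_misorientation_below_threshold(self):
        emap = two_block_map(30.0)
        threshold = 5.0
        gm = reconstruct_grains(emap, threshold)
        sym = next(iter(emap.phases.values()))
        q = emap.orientations
        h, w = emap.height, emap.width
        for y in range(h):
            for x in range(w - 1):
                if gm.label[y, x] and gm.label[y, x] == gm.label[y, x + 1]:
                    ang = misorientation_angle(
                        q[y * w + x], q[y * w + x + 1], sym)
                    assert ang < threshold


class TestFill:
    def test_fully_indexed_map_unchanged(self):
        emap = constant_map([1.0, 0, 0, 0], 8, 8)
        gm = reconstruct_grains(emap, 5.0)
        filled = fill_unindexed(gm, emap)
        assert np.array_equal(filled.phase, emap.phase)
        assert np.allclose(filled.orientations.quat,
                           emap.orientations.quat, atol=1e-12)

    def test_interior_hole_gets_grain_mean(self, hex_sym):
        emap = constant_map([1.0, 0, 0, 0], 8, 8)
        phase = emap.phase.copy()
        phase[4, 4] = 0
        emap.phase = phase
        gm = reconstruct_grains(emap, 5.0)
        filled = fill_unindexed(gm, emap)
        assert filled.indexed_fraction == 1.0
        k = 4 * 8 + 4
        ang = misorientation_angle(filled.orientations[k],
                                   Orientation.identity(), hex_sym)
        assert ang < 1e-6

    def test_indexed_pixels_never_modified(self, small_map):
        emap, _ = small_map
        gm = reconstruct_grains(emap, 9.0)
        filled = fill_unindexed(gm, emap)
        idx = emap.indexed.ravel()
        assert np.allclose(filled.orientations.quat[idx],
                           emap.orientations.quat[idx], atol=1e-12)

    def test_modified_count_bounded_by_unindexed(self, small_map):
        emap, _ = small_map
        gm = reconstruct_grains(emap, 9.0)
        filled = fill_unindexed(gm, emap)
        n_modified = (filled.indexed & ~emap.indexed).sum()
        assert n_modified <= (~emap.indexed).sum()


class TestSweep:
    def test_fully_indexed_has_zero_coincidence(self):
        emap = two_block_map(30.0)
        _, table = threshold_sweep(emap, [1.0, 5.0])
        assert np.all(table["boundary_unindexed_fraction"] == 0.0)

    def test_grain_count_non_increasing_without_discards(self):
        """On a noise-free patchwork (every grain >= 2 px at all
        thresholds) higher thresholds only merge grains."""
        recipe = TextureRecipe(c_dispersion=10.0,
                               a_rotation_model=("girdle",),
                               patch_noise=0.0, unindexed_fraction=0.0)
        emap, _ = generate_map(recipe, 24, 24, seed=6)
        _, table = threshold_sweep(emap, [1.0, 5.0, 9.0, 13.0, 17.0])
        n = table["n_grains"].to_numpy()
        assert np.all(np.diff(n) <= 0)

    def test_border_masking_drives_coincidence_above_half(self):
        recipe = TextureRecipe(c_dispersion=8.0,
                               a_rotation_model=("dispersed", 8.0),
                               patch_noise=1.0, unindexed_fraction=0.3,
                               unindexed_mode="patch-border")
        emap, _ = generate_map(recipe, 32, 32, seed=8)
        _, table = threshold_sweep(emap, [5.0])
        assert table["boundary_unindexed_fraction"].iloc[0] > 0.5
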
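"""Tubeness, thresholding, skeletonization and density measurement."""

import itertools

import numpy as np
import pytest

import axonquant as aq
from axonquant.density import (
    Skeleton,
    TubenessMap,
    axon_density,
    default_thresholds,
    skeleton_length,
    skeletonize,
    threshold_tubeness,
    tubeness,
)
from axonquant.stack import VolumeStack

VS = 0.09


def brute_force_length(mask: np.ndarray, voxel_size: float) -> float:
    """O(n^2) oracle: sum over all voxel pairs at Chebyshev distance 1."""
    coords = np.argwhere(mask)
    total = 0.0
    for i, j in itertools.combinations(range(len(coords)), 2):
        d = coords[i] - coords[j]
        if np.max(np.abs(d)) == 1:
            total += np.sqrt((d * d).sum()) * voxel_size
    return total


class TestTubeness:
    def test_constant_stack_scores_zero(self):
        stack = VolumeStack(np.full((24, 24, 24), 80, dtype=np.uint16), VS)
        assert np.all(tubeness(stack).scores == 0)

    def test_sigma_below_voxel_size_rejected(self):
        stack = VolumeStack(np.zeros((24, 24, 24), dtype=np.uint16), VS)
        with pytest.raises(ValueError, match="undersampled"):
            tubeness(stack, sigma_um=0.05)

    def test_ridge_tracks_true_centerline(self, straight_tube):
        """Tubeness argmax within 1 voxel of the centerline for >= 95% of axial positions."""
        line, stack, _ = straight_tube
        tm = tubeness(stack)
        cz, cy = int(round(2.0 / VS)), int(round(2.0 / VS))
        hits = 0
        xs = range(10, 90)  # interior axial positions
        for x in xs:
            plane = tm.scores[:, :, x]
            z, y = np.unravel_index(np.argmax(plane), plane.shape)
            if max(abs(z - cz), abs(y - cy)) <= 1:
                hits += 1
        assert hits / len(xs) >= 0.95

    def test_tube_outscores_isolated_point(self):
        """A line structure scores higher on-centerline than a point of equal peak."""
        vs = VS
        shape = (33, 33, 33)
        line = np.array([[1.44, 1.44, i * vs] for i in range(shape[2])])
        params = aq.SimParams(stack_shape=shape, noise_gaussian_sd=0.0,
                              bouton_rate_per_um=0.0, background_level=0.0, seed=0)
        tube_stack, _ = aq.render_axon_stack([line], params)
        point = np.zeros(shape)
        point[16, 16, 16] = tube_stack.voxels.max()
        point_stack = VolumeStack(point.astype(np.uint16), vs)
        t_tube = tubeness(tube_stack).scores[16, 16, 5:-5].mean()
        t_point = tubeness(point_stack).scores[16, 16, 16]
        assert t_tube > t_point

    def test_rotation_equivariance_on_straight_tubes(self):
        """Mean centerline score of an x-tube matches a z-tube within 10%."""
        shape = (41, 41, 41)
        params = aq.SimParams(stack_shape=shape, noise_gaussian_sd=0.0,
                              bouton_rate_per_um=0.0, seed=0)
        mid = 20 * VS
        along_x = np.array([[mid, mid, i * VS] for i in range(shape[2])])
        along_z = np.array([[i * VS, mid, mid] for i in range(shape[0])])
        sx, _ = aq.render_axon_stack([along_x], params)
        sz, _ = aq.render_axon_stack([along_z], params)
        mx = tubeness(sx).scores[20, 20, 8:-8].mean()
        mz = tubeness(sz).scores[8:-8, 20, 20].mean()
        assert abs(mx - mz) / mz < 0.10


class TestThreshold:
    def _map(self, arr):
        return TubenessMap(np.asarray(arr, dtype=float), 0.32, VS)

    def test_low_above_high_rejected(self):
        with pytest.raises(ValueError):
            threshold_tubeness(self._map(np.zeros((3, 3, 3))), 2.0, 1.0)

    def test_zero_map_gives_empty_foreground(self):
        fg = threshold_tubeness(self._map(np.zeros((4, 4, 4))), 0.0, 0.0)
        assert not fg.any()

    def test_zero_thresholds_keep_strictly_positive_scores(self):
        arr = np.zeros((3, 3, 3))
        arr[1, 1, 1] = 0.5
        fg = threshold_tubeness(self._map(arr), 0.0, 0.0)
        assert fg.sum() == 1 and fg[1, 1, 1]

    def test_above_max_gives_empty_foreground(self):
        arr = np.random.default_rng(0).random((4, 4, 4))
        fg = threshold_tubeness(self._map(arr), arr.max() + 1, arr.max() + 1)
        assert not fg.any()

    def test_hysteresis_matches_flood_fill_oracle(self):
        """Plateau >= high keeps its connected skirt; disconnected skirt drops."""
        arr = np.zeros((5, 5, 5))
        arr[2, 2, 2] = 10.0           # seed plateau
        arr[2, 2, 3] = 4.0            # 26-connected skirt
        arr[2, 3, 4] = 4.0            # skirt of the skirt (diagonal chain)
        arr[0, 0, 0] = 4.0            # disconnected skirt voxel
        fg = threshold_tubeness(self._map(arr), low=3.0, high=8.0)
        # brute-force flood fill from seeds through weak voxels
        weak = arr >= 3.0
        seeds = {(2, 2, 2)}
        frontier = set(seeds)
        while frontier:
            nxt = set()
            for p in frontier:
                for d in itertools.product((-1, 0, 1), repeat=3):
                    q = tuple(np.add(p, d))
                    if all(0 <= q[k] < 5 for k in range(3)) and weak[q] and q not in seeds:
                        seeds.add(q)
                        nxt.add(q)
            frontier = nxt
        expected = np.zeros((5, 5, 5), dtype=bool)
        for p in seeds:
            expected[p] = True
        assert np.array_equal(fg, expected)
        assert not fg[0, 0, 0]

    def test_raising_low_never_grows_foreground(self):
        rng = np.random.default_rng(3)
        arr = rng.random((8, 8, 8))
        tm = self._map(arr)
        high = 0.9
        counts = [threshold_tubeness(tm, low, high).sum() for low in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestSkeleton:
    def test_thick_bar_thins_to_single_line(self):
        mask = np.zeros((9, 9, 30), dtype=bool)
        mask[3:6, 3:6, 2:28] = True
        sk = skeletonize(mask, VS)
        interior = sk.mask[:, :, 5:25]
        assert np.all(interior.sum(axis=(0, 1)) == 1)  # one voxel per axial slice
        assert np.all(sk.mask[mask == 0] == 0)  # skeleton subset of foreground

    def test_empty_mask_gives_empty_skeleton(self):
        sk = skeletonize(np.zeros((5, 5, 5), dtype=bool), VS)
        assert sk.n_voxels == 0 and skeleton_length(sk) == 0.0

    def test_idempotent(self):
        mask = np.zeros((9, 9, 20), dtype=bool)
        mask[3:6, 3:6, 2:18] = True
        sk = skeletonize(mask, VS)
        again = skeletonize(sk.mask, VS)
        assert np.array_equal(sk.mask, again.mask)

    def test_non_binary_input_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            skeletonize(np.full((4, 4, 4), 3), VS)

    def test_torus_skeleton_retains_cycle_and_component(self):
        z, y, x = np.mgrid[0:40, 0:40, 0:40].astype(float) - 19.5
        solid = (np.sqrt(x**2 + y**2) - 10) ** 2 + z**2 <= 3.0**2
        sk = skeletonize(solid, VS)
        coords = np.argwhere(sk.mask)
        # count 26-adjacency edges, components; cycles = E - V + C
        from scipy import ndimage
        _, n_comp = ndimage.label(sk.mask, structure=np.ones((3, 3, 3)))
        edges = 0
        for i, j in itertools.combinations(range(len(coords)), 2):
            if np.max(np.abs(coords[i] - coords[j])) == 1:
                edges += 1
        assert n_comp == 1
        assert edges - len(coords) + n_comp >= 1  # at least one independent cycle


class TestSkeletonLength:
    def test_axis_aligned_chain_analytic(self):
        mask = np.zeros((3, 3, 100), dtype=bool)
        mask[1, 1, :] = True
        assert skeleton_length(Skeleton(mask, VS)) == pytest.approx(99 * VS, abs=1e-9)

    def test_body_diagonal_chain_analytic(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        for i in range(10):
            mask[i, i, i] = True
        assert skeleton_length(Skeleton(mask, VS)) == pytest.approx(
            9 * VS * np.sqrt(3), abs=1e-9
        )

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            mask = rng.random((6, 6, 6)) < 0.15
            got = skeleton_length(Skeleton(mask, VS))
            assert got == pytest.approx(brute_force_length(mask, VS), abs=1e-9)

    def test_invariant_under_axis_permutation(self):
        rng = np.random.default_rng(8)
        mask = rng.random((6, 7, 8)) < 0.2
        base = skeleton_length(Skeleton(mask, VS))
        for perm in itertools.permutations((0, 1, 2)):
            assert skeleton_length(Skeleton(np.transpose(mask, perm), VS)) == pytest.approx(
                base, abs=1e-9
            )

    def test_isolated_voxels_contribute_nothing(self):
        mask = np.zeros((9, 9, 9), dtype=bool)
        mask[0, 0, 0] = mask[4, 4, 4] = mask[8, 8, 8] = True
        assert skeleton_length(Skeleton(mask, VS)) == 0.0


class TestAxonDensity:
    def test_blank_stack_has_zero_density(self):
        stack = VolumeStack(np.full((24, 24, 24), 100, dtype=np.uint16), VS)
        res = axon_density(stack)
        assert res.density_um_per_um3 == 0.0
        assert res.total_length_um == 0.0

    def test_volume_is_product_of_extents(self, clean_stack):
        _, stack, _ = clean_stack
        res = axon_density(stack)
        assert res.stack_volume_um3 == pytest.approx(np.prod(stack.shape) * VS**3)

    def test_recovers_ground_truth_density(self, clean_stack):
        _, stack, truth = clean_stack
        res = axon_density(stack)
        true_density = truth.total_length_um / stack.volume_um3
        assert res.density_um_per_um3 == pytest.approx(true_density, rel=0.15)

    def test_tiling_invariance(self, clean_stack):
        """Duplicating the content (doubling the volume) leaves density unchanged."""
        _, stack, _ = clean_stack
        tiled = VolumeStack(np.concatenate([stack.voxels, stack.voxels], axis=2), VS)
        d1 = axon_density(stack).density_um_per_um3
        d2 = axon_density(tiled).density_um_per_um3
        assert d2 == pytest.approx(d1, rel=0.02)
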
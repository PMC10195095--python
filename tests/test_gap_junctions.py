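"""Cx43 thresholding, membrane isolation, projection, and calibration."""

import numpy as np
import pytest

from myoconduct import (
    CalibrationError,
    GapJunctionMap,
    GridSpec,
    IntensityVolume,
    SegmentVolume,
    build_boundary,
    calibrate_sigma_gj,
    coupled_neighbor_count,
    generate_brick_tissue,
    project_cx43,
    threshold_cx43,
)
from myoconduct.gap_junctions import intensity_mode
from myoconduct.synthetic_tissue import control_spec

G = lambda shape: GridSpec(shape, 1e-6)


class TestThreshold:
    def test_strictly_above_mode_plus_k_sd(self):
        # integer image engineered to a known mode and SD
        rng = np.random.default_rng(0)
        vals = np.full((20, 20, 20), 10, dtype=np.int64)
        vol = IntensityVolume(G((20, 20, 20)), vals.astype(np.int64))
        sd = float(np.std(vals))
        assert sd == 0.0  # constant baseline; now perturb two voxels
        vals[0, 0, 0] = 20
        vals[0, 0, 1] = 0
        vol = IntensityVolume(G((20, 20, 20)), vals)
        mode = intensity_mode(vals)
        sd = float(np.std(vals))
        mask = threshold_cx43(vol, k_sd=4.5)
        expected = vals > mode + 4.5 * sd
        np.testing.assert_array_equal(mask, expected)
        assert mask.sum() == 1  # only the bright outlier

    def test_constant_image_warns_and_is_empty(self):
        vol = IntensityVolume(G((5, 5, 5)), np.full((5, 5, 5), 7.0))
        with pytest.warns(UserWarning):
            mask = threshold_cx43(vol)
        assert not mask.any()

    def test_bright_voxels_recovered_against_histogram_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.integers(0, 6, (30, 30, 30)).astype(np.int64)
        bright = rng.choice(vals.size, 50, replace=False)
        vals.ravel()[bright] = 1000
        vol = IntensityVolume(G((30, 30, 30)), vals)
        # brute-force histogram oracle for the mode
        hist = {}
        for v in vals.ravel():
            hist[int(v)] = hist.get(int(v), 0) + 1
        mode = min(k for k, c in hist.items() if c == max(hist.values()))
        thr = mode + 4.5 * np.std(vals)
        mask = threshold_cx43(vol)
        np.testing.assert_array_equal(mask, vals > thr)
        assert mask.sum() == 50

    def test_float_mode_uses_256_bins(self):
        vals = np.concatenate([np.full(900, 1.0), np.full(100, 250.0)])
        vals = vals.reshape(10, 10, 10)
        # mode bin is the lowest bin; its center is near 1.0
        assert intensity_mode(vals) < 2.0


class TestBoundary:
    def _segments(self, ids):
        return SegmentVolume(G(ids.shape), ids)

    def test_gap3_bricks_end_with_one_voxel_layer(self):
        # 1D profile oracle along the junction axis: dilation fronts meet in
        # the central voxel which stays background and becomes the boundary
        ids = np.zeros((13, 5, 5), np.int32)
        ids[:5] = 1
        ids[8:] = 2
        iso, boundary = build_boundary(self._segments(ids))
        profile = iso.ids[:, 2, 2]
        np.testing.assert_array_equal(profile, [1, 1, 1, 1, 1, 1, 0, 2, 2, 2, 2, 2, 2])
        assert boundary[6, 2, 2]

    def test_touching_bricks_get_one_voxel_gap(self):
        ids = np.zeros((10, 5, 5), np.int32)
        ids[:5] = 1
        ids[5:] = 2
        iso, boundary = build_boundary(self._segments(ids))
        profile = iso.ids[:, 2, 2]
        np.testing.assert_array_equal(profile, [1, 1, 1, 1, 1, 0, 2, 2, 2, 2])
        assert boundary[5, 2, 2]

    def test_single_myocyte_keeps_all_voxels(self):
        ids = np.zeros((9, 9, 9), np.int32)
        ids[3:6, 3:6, 3:6] = 1
        iso, boundary = build_boundary(self._segments(ids))
        # no neighbors: dilation then isolation changes nothing inside
        assert (iso.ids > 0).sum() >= 27
        inner = iso.ids > 0
        import scipy.ndimage as ndi

        shell = ndi.binary_dilation(inner, np.ones((3, 3, 3), bool)) & ~inner
        np.testing.assert_array_equal(boundary, shell)


class TestProjection:
    def _two_bricks(self):
        ids = np.zeros((11, 7, 7), np.int32)
        ids[:5] = 1
        ids[6:] = 2
        iso, boundary = build_boundary(SegmentVolume(G(ids.shape), ids))
        return iso, boundary

    def test_zero_distance_projection(self):
        iso, boundary = self._two_bricks()
        mask = np.zeros(iso.grid.shape, bool)
        mask[5, 3, 3] = True  # exactly on the shared boundary layer
        gj = project_cx43(mask, boundary, iso)
        assert gj.gj_mask[5, 3, 3]
        assert gj.pair_counts == {(1, 2): 1}

    def test_cx43_beyond_1um_dropped(self):
        iso, boundary = self._two_bricks()
        grid = GridSpec(iso.grid.shape, 1e-6)
        iso2 = SegmentVolume(grid, iso.ids)
        mask = np.zeros(grid.shape, bool)
        mask[5, 3, 3] = True
        # a second signal voxel 2 voxels (= 2 um) off the boundary plane
        far = np.zeros(grid.shape, bool)
        far[3, 3, 3] = True  # inside brick 1, 2 um from the x=5 layer
        gj = project_cx43(mask | far, boundary & (np.arange(11) == 5)[:, None, None], iso2)
        assert gj.gj_mask.sum() == 1

    def test_cluster_collapses_to_single_junction_voxel(self):
        iso, boundary = self._two_bricks()
        mask = np.zeros(iso.grid.shape, bool)
        # 7 voxels nearest to the shared boundary voxel (5, 3, 3)
        mask[5, 3, 3] = True
        mask[4, 3, 3] = mask[6, 3, 3] = True
        mask[5, 2, 3] = mask[5, 4, 3] = mask[5, 3, 2] = mask[5, 3, 4] = True
        gj = project_cx43(mask, boundary, iso)
        # projections may land on several boundary voxels of the layer, but
        # the engineered nearest target receives the cluster center
        assert gj.gj_mask[5, 3, 3]
        assert sum(gj.pair_counts.values()) == int(gj.gj_mask.sum())

    def test_max_dist_zero_keeps_only_on_boundary_voxels(self):
        iso, boundary = self._two_bricks()
        mask = np.zeros(iso.grid.shape, bool)
        mask[5, 3, 3] = True  # on boundary
        mask[4, 2, 2] = True  # inside myocyte 1
        gj = project_cx43(mask, boundary, iso, max_dist=0.0)
        assert gj.gj_mask.sum() == 1

    def test_permutation_equivariance_on_separated_tissue(self):
        grid = GridSpec((43, 60, 22), 1e-6)
        t = generate_brick_tissue(control_spec(grid, seed=9))
        mask = t.cx43.values > 0
        iso, boundary = build_boundary(t.segments)
        gj1 = project_cx43(mask, boundary, iso)
        # relabel myocytes in reverse order
        ids = t.segments.ids
        relabeled = np.where(ids > 0, ids.max() + 1 - ids, 0).astype(ids.dtype)
        iso2, boundary2 = build_boundary(SegmentVolume(grid, relabeled))
        gj2 = project_cx43(mask, boundary2, iso2)
        np.testing.assert_array_equal(gj1.gj_mask, gj2.gj_mask)


class TestCalibration:
    def test_unit_arithmetic_at_200nm(self):
        grid = GridSpec((4, 4, 4), 200e-9)
        cal = calibrate_sigma_gj({(1, 2): 1}, grid)
        assert cal.sigma_gj == pytest.approx(6.2, rel=1e-12)
        cal = calibrate_sigma_gj({(1, 2): 62}, grid)
        assert cal.sigma_gj == pytest.approx(0.1, rel=1e-12)

    def test_doubling_counts_halves_sigma(self):
        grid = GridSpec((4, 4, 4), 200e-9)
        a = calibrate_sigma_gj({(1, 2): 5, (2, 3): 7}, grid)
        b = calibrate_sigma_gj({(1, 2): 10, (2, 3): 14}, grid)
        assert b.sigma_gj == pytest.approx(a.sigma_gj / 2)

    def test_pooling_across_stacks(self):
        grid = GridSpec((4, 4, 4), 1e-6)
        cal = calibrate_sigma_gj([{(1, 2): 2}, {(3, 4): 4}], grid)
        assert cal.n_gj_control == 3.0

    def test_no_coupled_pairs_raises(self):
        with pytest.raises(CalibrationError):
            calibrate_sigma_gj({(1, 2): 0}, GridSpec((4, 4, 4), 1e-6))


class TestNeighborCounts:
    def test_chain_of_three(self):
        gj = GapJunctionMap(G((4, 4, 4)), np.zeros((4, 4, 4), bool), {(1, 2): 3, (2, 3): 1})
        counts, mean, sd = coupled_neighbor_count(gj)
        assert counts == {1: 1, 2: 2, 3: 1}
        assert mean == pytest.approx(4 / 3)

    def test_empty_map_with_known_universe(self):
        gj = GapJunctionMap(G((4, 4, 4)), np.zeros((4, 4, 4), bool), {})
        counts, mean, sd = coupled_neighbor_count(gj, all_ids=[1, 2, 3])
        assert counts == {1: 0, 2: 0, 3: 0}
        assert mean == 0.0

    def test_generator_truth_recovered_end_to_end(self):
        grid = GridSpec((43, 120, 22), 1e-6)
        spec = control_spec(grid, seed=5, inclusion_fractions={}, cleft_period_x=0.0)
        t = generate_brick_tissue(spec)
        mask = threshold_cx43(t.cx43)
        iso, boundary = build_boundary(t.segments)
        gj = project_cx43(mask, boundary, iso)
        assert gj.pair_counts == t.truth.pair_counts
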
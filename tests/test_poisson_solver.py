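"""Finite-volume conduction solver: closed forms, conservation, bounds."""

import numpy as np
import pytest

from myoconduct import (
    ConductivityModel,
    GapJunctionMap,
    GridSpec,
    OverlapError,
    SegmentVolume,
    build_model,
    current_and_conductivity,
    estimate_tensor,
    exclude_isolated,
    generate_brick_tissue,
    solve_potential,
)
from myoconduct.synthetic_tissue import truth_gap_junction_map

from .conftest import dense_sigma_dir, tiny_lattice_spec

S = 1e-6
DIRECTIONS = ("normal", "longitudinal", "transverse")


def uniform_model(n=12, sigma=0.86):
    g = GridSpec((n, n, n), S)
    return ConductivityModel(g, np.full(g.shape, sigma))


class TestClosedForms:
    def test_uniform_domain_returns_sigma_in_all_directions(self):
        est = estimate_tensor(uniform_model(), tol=1e-10)
        for v in est.as_dict().values():
            assert v == pytest.approx(0.86, abs=1e-10)

    def test_two_slab_series_equals_harmonic_composition(self):
        sig = np.zeros((3, 20, 3))
        sig[:, :10, :] = 1.0
        sig[:, 10:, :] = 3.0
        m = ConductivityModel(GridSpec((3, 20, 3), S), sig)
        est = estimate_tensor(m, tol=1e-12, directions=("longitudinal",))
        assert est.sigma_myo_l == pytest.approx(20 / (10 / 1 + 10 / 3), abs=1e-10)

    def test_two_slab_node_potentials_match_1d_divider(self):
        # 1D two-resistor divider oracle evaluated at the two nodes
        # flanking the interface (half-voxel offsets from the face)
        sig = np.zeros((3, 20, 3))
        s1, s2 = 1.0, 3.0
        sig[:, :10, :] = s1
        sig[:, 10:, :] = s2
        m = ConductivityModel(GridSpec((3, 20, 3), S), sig)
        phi, res, _ = solve_potential(m, "longitudinal", tol=1e-12)
        current = 2.0 / (10 / s1 + 10 / s2)
        assert phi[1, 9, 1] == pytest.approx(1 - current * 9.5 / s1, abs=1e-9)
        assert phi[1, 10, 1] == pytest.approx(
            1 - current * (10 / s1 + 0.5 / s2), abs=1e-9
        )

    def test_insulating_plane_splits_domain_into_electrode_halves(self):
        sig = np.full((4, 11, 4), 0.5)
        sig[:, 5, :] = 0.0
        m = ConductivityModel(GridSpec((4, 11, 4), S), sig)
        phi, _, _ = solve_potential(m, "longitudinal", tol=1e-10)
        assert np.all(phi[:, :5, :] == 1.0)
        assert np.all(phi[:, 6:, :] == -1.0)
        sol = current_and_conductivity(m, phi, "longitudinal")
        assert sol.sigma_dir == 0.0

    def test_all_zero_model_gives_zero(self):
        m = ConductivityModel(GridSpec((4, 4, 4), S), np.zeros((4, 4, 4)))
        with pytest.warns(UserWarning):
            est = estimate_tensor(m)
        assert est.as_dict() == {"sigma_myo_n": 0.0, "sigma_myo_l": 0.0, "sigma_myo_t": 0.0}


class TestBuildModel:
    def test_sigma_histogram_matches_generator_truth(self):
        spec = tiny_lattice_spec(n_gj_end=4)
        t = generate_brick_tissue(spec)
        gj = truth_gap_junction_map(t)
        m = build_model(t.segments, gj, sigma_cyto=0.86, sigma_gj=0.1)
        n_myo = int((t.segments.ids > 0).sum())
        n_gj = sum(t.truth.pair_counts.values())
        assert int((m.sigma == 0.86).sum()) == n_myo
        assert int((m.sigma == 0.1).sum()) == n_gj
        assert int((m.sigma == 0.0).sum()) == m.grid.n_voxels - n_myo - n_gj

    def test_overlapping_gj_and_myocyte_rejected(self):
        g = GridSpec((4, 4, 4), S)
        ids = np.ones(g.shape, np.int32)
        gj = GapJunctionMap(g, np.ones(g.shape, bool), {})
        with pytest.raises(OverlapError):
            build_model(SegmentVolume(g, ids), gj, sigma_gj=0.1)


class TestExcludeIsolated:
    def test_floating_cube_removed(self):
        sig = np.zeros((10, 10, 10))
        sig[0:10, 4:6, 4:6] = 0.86  # bar bridging the x electrodes
        sig[4:6, 8:10, 8:10] = 0.86  # island not touching either x plane
        m = ConductivityModel(GridSpec((10, 10, 10), S), sig)
        cleaned, removed = exclude_isolated(m, "normal")
        assert removed == 2 * 2 * 2
        assert (cleaned.sigma[4:6, 8:10, 8:10] == 0).all()
        assert (cleaned.sigma[:, 4:6, 4:6] == 0.86).all()

    def test_fully_connected_model_untouched(self):
        m = uniform_model(6)
        cleaned, removed = exclude_isolated(m, "longitudinal")
        assert removed == 0
        np.testing.assert_array_equal(cleaned.sigma, m.sigma)

    def test_one_electrode_component_kept_vs_flood_fill_oracle(self):
        from collections import deque

        sig = np.zeros((9, 5, 5))
        sig[0:4, 1:3, 1:3] = 0.5  # touches only the x=0 electrode
        sig[0:9, 3:5, 3:5] = 0.5  # spans both electrodes
        m = ConductivityModel(GridSpec((9, 5, 5), S), sig)
        cleaned, removed = exclude_isolated(m, "normal")
        assert removed == 0  # both components reachable from an electrode

        # independent BFS flood fill from electrode-touching voxels
        mask = sig > 0
        seeds = [tuple(p) for p in np.argwhere(mask) if p[0] in (0, 8)]
        seen = set(seeds)
        q = deque(seeds)
        while q:
            x, y, z = q.popleft()
            for dx, dy, dz in ((1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)):
                p = (x+dx, y+dy, z+dz)
                if (
                    0 <= p[0] < 9 and 0 <= p[1] < 5 and 0 <= p[2] < 5
                    and mask[p] and p not in seen
                ):
                    seen.add(p)
                    q.append(p)
        reached = np.zeros_like(mask)
        for p in seen:
            reached[p] = True
        np.testing.assert_array_equal(cleaned.sigma > 0, reached)


class TestSolutionProperties:
    def test_plane_currents_conserved(self, control_stack, control_tensor):
        sol = control_tensor.solutions["longitudinal"]
        planes = sol.plane_currents
        assert np.ptp(planes) <= 1e-6 * max(abs(planes).max(), 1e-30)

    def test_max_principle_on_tiny_lattice(self):
        spec = tiny_lattice_spec(n_gj_end=4)
        t = generate_brick_tissue(spec)
        m = build_model(t.segments, truth_gap_junction_map(t), 0.86, 0.1)
        cleaned, _ = exclude_isolated(m, "longitudinal")
        phi, _, _ = solve_potential(cleaned, "longitudinal", tol=1e-12)
        finite = np.isfinite(phi)
        assert finite.any()
        assert phi[finite].min() >= -1.0 - 1e-9
        assert phi[finite].max() <= 1.0 + 1e-9

    def test_monotone_in_any_voxel_sigma_vs_dense_oracle(self):
        rng = np.random.default_rng(3)
        sig = np.where(rng.random((5, 8, 5)) < 0.75, 0.8, 0.0)
        sig[:, 0, :] = 0.8  # guarantee electrode contact
        sig[:, -1, :] = 0.8
        m = ConductivityModel(GridSpec((5, 8, 5), S), sig)
        cleaned, _ = exclude_isolated(m, "longitudinal")
        base = dense_sigma_dir(cleaned.sigma, 1)
        est = estimate_tensor(cleaned, tol=1e-12, directions=("longitudinal",))
        assert est.sigma_myo_l == pytest.approx(base, abs=1e-9)
        # raise one conducting voxel's sigma: effective sigma must not drop
        p = tuple(np.argwhere(cleaned.sigma > 0)[7])
        sig2 = cleaned.sigma.copy()
        sig2[p] *= 2.5
        m2 = ConductivityModel(m.grid, sig2)
        cleaned2, _ = exclude_isolated(m2, "longitudinal")
        est2 = estimate_tensor(cleaned2, tol=1e-12, directions=("longitudinal",))
        assert est2.sigma_myo_l >= est.sigma_myo_l - 1e-12
        assert est2.sigma_myo_l == pytest.approx(dense_sigma_dir(cleaned2.sigma, 1), abs=1e-9)

    def test_scale_invariance(self):
        spec = tiny_lattice_spec(n_gj_end=4)
        t = generate_brick_tissue(spec)
        m = build_model(t.segments, truth_gap_junction_map(t), 0.86, 0.1)
        est1 = estimate_tensor(m, tol=1e-12, directions=("longitudinal",))
        m3 = ConductivityModel(m.grid, 3.0 * m.sigma)
        est3 = estimate_tensor(m3, tol=1e-12, directions=("longitudinal",))
        assert est3.sigma_myo_l == pytest.approx(3.0 * est1.sigma_myo_l, rel=1e-9)

    def test_control_tissue_anisotropy_ordering(self, control_tensor):
        d = control_tensor.as_dict()
        assert d["sigma_myo_l"] > d["sigma_myo_t"] >= d["sigma_myo_n"]

    def test_end_junctions_only_conduct_longitudinally(self):
        from myoconduct import BrickTissueSpec

        # 2x2 columns of bricks so walls interrupt the transverse directions
        spec = BrickTissueSpec(
            grid=GridSpec((7, 9, 7), S),
            myocyte_dims=(4 * S, 3 * S, 3 * S),
            n_gj_end=9,
            n_gj_side=0,
            gj_margin=0,
            seed=5,
        )
        t = generate_brick_tissue(spec)
        m = build_model(t.segments, truth_gap_junction_map(t), 0.86, 0.1)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = estimate_tensor(m, tol=1e-10)
        assert est.sigma_myo_l > 0
        assert est.sigma_myo_n == 0.0
        assert est.sigma_myo_t == 0.0
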
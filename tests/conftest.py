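"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from myoconduct import (
    BrickTissueSpec,
    GridSpec,
    build_boundary,
    build_model,
    calibrate_sigma_gj,
    estimate_tensor,
    generate_brick_tissue,
    project_cx43,
    threshold_cx43,
)
from myoconduct.synthetic_tissue import control_spec


def dense_sigma_dir(sigma: np.ndarray, axis: int) -> float:
    """Node-per-voxel Kirchhoff solve of the conduction network (dense).

    Independent of the package's sparse solver: plain loops assemble the
    conductance matrix with harmonic-mean face conductances and +/-1 V
    electrode links, numpy solves it densely, and the effective
    conductivity follows from the total electrode current. Only for
    fixtures of up to ~1e3 conducting voxels.
    """
    sigma = np.asarray(sigma, float)
    shape = sigma.shape
    pts = np.argwhere(sigma > 0)
    idx = {tuple(p): i for i, p in enumerate(pts)}
    n = len(pts)
    G = np.zeros((n, n))
    b = np.zeros(n)

    def harm(a, c):
        return 2 * a * c / (a + c)

    for p in pts:
        i = idx[tuple(p)]
        for a in range(3):
            q = p.copy()
            q[a] += 1
            tq = tuple(q)
            if q[a] < shape[a] and sigma[tq] > 0:
                j = idx[tq]
                g = harm(sigma[tuple(p)], sigma[tq])
                G[i, i] += g
                G[j, j] += g
                G[i, j] -= g
                G[j, i] -= g
        if p[axis] == 0:
            g = 2 * sigma[tuple(p)]
            G[i, i] += g
            b[i] += g
        if p[axis] == shape[axis] - 1:
            g = 2 * sigma[tuple(p)]
            G[i, i] += g
            b[i] -= g
    phi = np.linalg.solve(G, b)
    current = sum(
        2 * sigma[tuple(p)] * (1.0 - phi[idx[tuple(p)]]) for p in pts if p[axis] == 0
    )
    nax = shape[axis]
    n_cs = sigma.size // nax
    return current * nax / (2 * n_cs)


def tiny_lattice_spec(n_gj_end: int, seed: int = 5) -> BrickTissueSpec:
    """Two 3x4x3 bricks along y in a (3, 9, 3) grid, single column."""
    s = 1e-6
    return BrickTissueSpec(
        grid=GridSpec((3, 9, 3), s),
        myocyte_dims=(4 * s, 3 * s, 3 * s),
        wall_thickness=1,
        n_gj_end=n_gj_end,
        n_gj_side=0,
        gj_margin=0,
        seed=seed,
    )


@pytest.fixture(scope="session")
def control_stack():
    """One control-preset stack run through the full image-based pipeline.

    Grid borders intentionally truncate bricks mid-cell so that all three
    directions have electrode contact.
    """
    grid = GridSpec((59, 100, 47), 1e-6)
    spec = control_spec(grid, seed=7, phase_y=0.2)
    tissue = generate_brick_tissue(spec)
    mask = threshold_cx43(tissue.cx43)
    isolated, boundary = build_boundary(tissue.segments)
    gj = project_cx43(mask, boundary, isolated)
    cal = calibrate_sigma_gj(gj.pair_counts, grid)
    model = build_model(isolated, gj, sigma_cyto=0.86, sigma_gj=cal.sigma_gj)
    return {
        "spec": spec,
        "tissue": tissue,
        "isolated": isolated,
        "boundary": boundary,
        "gj": gj,
        "cal": cal,
        "model": model,
    }


@pytest.fixture(scope="session")
def control_tensor(control_stack):
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return estimate_tensor(control_stack["model"], tol=1e-10)
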
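"""Finite-volume Poisson solver for directional intracellular conductivities.

The intracellular space is modeled as a piecewise-constant conductivity
field over the voxel grid: myocyte voxels carry the cytoplasmic
conductivity, gap-junction voxels the calibrated junction conductivity,
and everything else (extracellular space, vessels, fibroblasts,
myofibroblasts, clefts, uncoupled membrane voxels) is non-conducting.

For each of the three anatomical directions the stationary current
problem ``div(sigma grad(phi)) = 0`` is solved with planar electrodes of
+1 V / -1 V on the opposite faces of the domain and zero-flux conditions
elsewhere. The discretization is the standard flux-conservative 7-point
scheme with harmonic-mean face conductances, which reproduces
series-resistor compositions across axis-aligned interfaces exactly — the
property that lets layered brick lattices validate the solver against a
closed form to solver tolerance. The directional effective conductivity
is the cross-section-averaged axial current density (non-conducting area
contributing zero) divided by the applied field magnitude
``E = 2 V / (n_axis * spacing)``, i.e. a tissue-scale homogenized value.

The symmetric positive-definite system is solved with conjugate gradients
under an additive two-level preconditioner: a Jacobi smoother plus a
direct coarse solve over myocyte-scale aggregates (connected strongly
conducting components and junction clusters, sliced into short slabs
along the field axis). The aggregates capture the slow modes of
gap-junction-dominated conduction — near-constant potentials per cell
with jumps across junctions — keeping iteration counts low even for long
stacks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import sparse
from scipy.sparse import linalg as spla

from .errors import OverlapError, SolverConvergenceError
from .gap_junctions import GapJunctionMap
from .voxel_domain import AXIS_ROLES, GridSpec, SegmentVolume

DIRECTIONS = ("normal", "longitudinal", "transverse")

#: Default cytoplasmic conductivity, S/m (guinea-pig atrial myocytes).
SIGMA_CYTO = 0.86


@dataclass
class ConductivityModel:
    """Scalar conductivity field in S/m; 0 marks non-conducting voxels."""

    grid: GridSpec
    sigma: np.ndarray
    sigma_cyto: float = SIGMA_CYTO
    sigma_gj: float = 0.0

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.sigma.shape != self.grid.shape:
            raise ValueError("sigma shape does not match grid")
        if self.sigma.size and self.sigma.min() < 0:
            raise ValueError("conductivities must be >= 0")


@dataclass
class FieldSolution:
    """Converged field along one direction with solver diagnostics."""

    direction: str
    sigma_dir: float
    E: float
    phi: np.ndarray | None
    residual_norm: float
    iterations: int
    excluded_voxels: int
    plane_currents: np.ndarray  # total axial current (A) through each face plane


@dataclass
class TensorEstimate:
    """Diagonal intracellular conductivity tensor for one stack, S/m."""

    sigma_myo_n: float
    sigma_myo_l: float
    sigma_myo_t: float
    solutions: dict[str, FieldSolution]

    def as_dict(self) -> dict[str, float]:
        return {
            "sigma_myo_n": self.sigma_myo_n,
            "sigma_myo_l": self.sigma_myo_l,
            "sigma_myo_t": self.sigma_myo_t,
        }


def build_model(
    segments: SegmentVolume,
    gj: GapJunctionMap,
    sigma_cyto: float = SIGMA_CYTO,
    sigma_gj: float = 0.0,
) -> ConductivityModel:
    """Assemble the conductivity field from isolated myocytes and junctions.

    ``segments`` must be the *isolated* segmentation (one-voxel membrane
    separation); the gap-junction mask lives inside that separating layer
    and must not overlap myocyte voxels.
    """
    myo = segments.ids > 0
    if np.any(gj.gj_mask & myo):
        raise OverlapError("gap-junction voxels overlap myocyte voxels")
    sigma = np.zeros(segments.grid.shape, dtype=np.float64)
    sigma[myo] = sigma_cyto
    sigma[gj.gj_mask] = sigma_gj
    return ConductivityModel(segments.grid, sigma, sigma_cyto, sigma_gj)


def exclude_isolated(
    model: ConductivityModel, direction: str
) -> tuple[ConductivityModel, int]:
    """Zero out conducting voxels unreachable from either electrode.

    Region growing uses face (6-)connectivity, matching the stencil:
    diagonal contacts carry no current. A component is kept if it touches
    the electrode plane at either end of the axis. Returns the cleaned
    model and the number of voxels removed.
    """
    axis = AXIS_ROLES[direction]
    mask = model.sigma > 0
    lab, _ = ndi.label(mask)  # default structure = 6-connectivity
    first = np.take(lab, 0, axis=axis)
    last = np.take(lab, -1, axis=axis)
    keep = np.union1d(np.unique(first), np.unique(last))
    keep = keep[keep > 0]
    reachable = np.isin(lab, keep)
    removed = int(mask.sum() - reachable.sum())
    if removed == 0:
        return model, 0
    sigma = np.where(reachable, model.sigma, 0.0)
    return ConductivityModel(model.grid, sigma, model.sigma_cyto, model.sigma_gj), removed


def _face_conductances(sigma: np.ndarray, axis: int) -> np.ndarray:
    """Voxel-normalized harmonic-mean conductance on interior faces."""
    sl1 = [slice(None)] * 3
    sl2 = [slice(None)] * 3
    sl1[axis] = slice(None, -1)
    sl2[axis] = slice(1, None)
    s1, s2 = sigma[tuple(sl1)], sigma[tuple(sl2)]
    h = np.zeros_like(s1)
    both = (s1 > 0) & (s2 > 0)
    h[both] = 2.0 * s1[both] * s2[both] / (s1[both] + s2[both])
    return h


class _TwoLevel:
    """Additive two-level preconditioner: Jacobi plus aggregation coarse solve.

    The slow modes of the conduction problem live on the myocyte scale:
    potentials that are nearly constant over (a stretch of) a cell and jump
    across the weak gap-junction links. Aggregates are therefore built
    from the connected components of the strongly conducting voxels
    (``sigma >= 0.5 * sigma_max``, i.e. cytoplasm) and of the weak
    remainder (junction voxels), each sliced into short slabs along the
    field axis so within-cell axial variation is also represented. The
    coarse operator ``P^T A P`` is tiny (one unknown per aggregate slab)
    and factorized directly; the preconditioner is the SPD sum of the
    coarse correction and the Jacobi smoother.
    """

    _SLAB = 4  # slab thickness along the field axis, voxels

    def __init__(self, sigma, mask, axis, perm, mask_p, A, diag):
        smax = sigma.max()
        strong = mask & (sigma >= 0.5 * smax)
        lab_s, k_s = ndi.label(strong)
        lab_w, _ = ndi.label(mask & ~strong)
        agg = np.where(strong, lab_s, np.where(mask, k_s + lab_w, 0)).astype(np.int64)
        nax = sigma.shape[axis]
        slabs = (np.arange(nax) // self._SLAB).astype(np.int64)
        slabs = slabs.reshape([-1 if a == axis else 1 for a in range(3)])
        n_slabs = int(slabs.max()) + 1
        key = np.where(mask, agg * n_slabs + slabs, -1)
        key_u = np.transpose(key, perm)[mask_p]  # in unknown order
        _, inv = np.unique(key_u, return_inverse=True)
        n = len(key_u)
        m = int(inv.max()) + 1
        self._P = sparse.coo_matrix(
            (np.ones(n), (np.arange(n), inv)), shape=(n, m)
        ).tocsr()
        self._coarse = spla.splu((self._P.T @ A @ self._P).tocsc())
        self._diag = diag

    def __call__(self, r: np.ndarray) -> np.ndarray:
        return r / self._diag + self._P @ self._coarse.solve(self._P.T @ r)


def solve_potential(
    model: ConductivityModel,
    direction: str,
    tol: float = 1e-10,
    maxiter: int | None = None,
) -> tuple[np.ndarray, float, int]:
    """Solve ``div(sigma grad(phi)) = 0`` for one electrode direction.

    Dirichlet values of +1 V (low-index plane) and -1 V (high-index plane)
    are imposed on the ghost faces of the first and last voxel layer along
    the axis; all other domain faces are zero-flux. The model must already
    have isolated components excluded for this direction.

    Returns ``(phi, residual_norm, iterations)`` where ``phi`` holds NaN
    on non-conducting voxels. The residual norm is the Euclidean norm of
    the linear-system residual relative to the electrode load ``||b||``
    (the system is assembled in voxel-normalized conductances, so the
    scale is set by ``sigma``, not the voxel size); convergence below
    ``tol`` is required, otherwise :class:`SolverConvergenceError` is
    raised.
    """
    axis = AXIS_ROLES[direction]
    sigma = model.sigma
    conducting = sigma > 0
    phi = np.full(model.grid.shape, np.nan)
    if not conducting.any():
        return phi, 0.0, 0

    # Components touching a single electrode carry no current; their exact
    # solution is the electrode potential. Only electrode-bridging
    # components enter the linear system.
    lab, _ = ndi.label(conducting)
    first_ids = np.unique(np.take(lab, 0, axis=axis))
    last_ids = np.unique(np.take(lab, -1, axis=axis))
    first_ids = first_ids[first_ids > 0]
    last_ids = last_ids[last_ids > 0]
    both = np.intersect1d(first_ids, last_ids)
    phi[np.isin(lab, np.setdiff1d(first_ids, both)) & conducting] = 1.0
    phi[np.isin(lab, np.setdiff1d(last_ids, both)) & conducting] = -1.0
    mask = np.isin(lab, both) & conducting
    n = int(mask.sum())
    if n == 0:
        return phi, 0.0, 0
    sigma = np.where(mask, sigma, 0.0)

    # number unknowns in the padded-column order used by the preconditioner
    perm = [a for a in range(3) if a != axis] + [axis]
    mask_p = np.transpose(mask, perm)
    idx_p = np.full(mask_p.shape, -1, dtype=np.int64)
    idx_p[mask_p] = np.arange(n)
    index = np.transpose(idx_p, np.argsort(perm))

    diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for a in range(3):
        h = _face_conductances(sigma, a)
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[a] = slice(None, -1)
        sl2[a] = slice(1, None)
        i1 = index[tuple(sl1)]
        i2 = index[tuple(sl2)]
        on = h > 0
        i1, i2, hv = i1[on], i2[on], h[on]
        rows.append(i1)
        cols.append(i2)
        vals.append(-hv)
        rows.append(i2)
        cols.append(i1)
        vals.append(-hv)
        diag += np.bincount(i1, weights=hv, minlength=n)
        diag += np.bincount(i2, weights=hv, minlength=n)

    b = np.zeros(n)
    s_first = np.take(sigma, 0, axis=axis)
    s_last = np.take(sigma, -1, axis=axis)
    i_first = np.take(index, 0, axis=axis)
    i_last = np.take(index, -1, axis=axis)
    m0 = s_first > 0
    g0 = 2.0 * s_first[m0]
    diag += np.bincount(i_first[m0], weights=g0, minlength=n)
    b += np.bincount(i_first[m0], weights=g0 * (+1.0), minlength=n)
    m1 = s_last > 0
    g1 = 2.0 * s_last[m1]
    diag += np.bincount(i_last[m1], weights=g1, minlength=n)
    b += np.bincount(i_last[m1], weights=g1 * (-1.0), minlength=n)

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(diag)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()

    M = _TwoLevel(sigma, mask, axis, perm, mask_p, A, diag)
    M_op = spla.LinearOperator((n, n), matvec=M)

    # linear ramp initial guess (in unknown order, which follows mask_p)
    nax = model.grid.shape[axis]
    ramp = 1.0 - 2.0 * (np.arange(nax) + 0.5) / nax
    x0 = np.broadcast_to(ramp, mask_p.shape)[mask_p]

    if maxiter is None:
        maxiter = 20000
    iters = 0

    def _count(_):
        nonlocal iters
        iters += 1

    b_norm = float(np.linalg.norm(b))
    x, info = spla.cg(
        A, b, x0=x0, rtol=0.0, atol=tol * b_norm, maxiter=maxiter, M=M_op, callback=_count
    )
    res = float(np.linalg.norm(b - A @ x)) / b_norm
    if res > tol:
        raise SolverConvergenceError(
            f"CG did not converge for {direction}: relative residual {res:.3e} > "
            f"tol {tol:.1e} after {iters} iterations (info={info}, n={n})"
        )
    np.transpose(phi, perm)[mask_p] = x
    return phi, res, iters


def current_and_conductivity(
    model: ConductivityModel,
    phi: np.ndarray,
    direction: str,
    residual_norm: float = 0.0,
    iterations: int = 0,
    excluded_voxels: int = 0,
) -> FieldSolution:
    """Evaluate axial current density and the directional conductivity.

    The axial current density is taken on voxel faces normal to the field
    axis (harmonic-mean face conductance times the potential jump); for
    each of the ``n_axis + 1`` face planes the mean over the full domain
    cross-section is formed, with non-conducting faces contributing zero.
    The directional conductivity is the average of the per-plane means
    divided by the applied field ``E = 2 / (n_axis * spacing)``; for a
    converged solution the per-plane totals agree to solver tolerance
    (charge conservation), so the averaging is a formality.
    """
    axis = AXIS_ROLES[direction]
    grid = model.grid
    perm = [a for a in range(3) if a != axis] + [axis]
    sig = np.transpose(model.sigma, perm)
    ph = np.transpose(phi, perm)
    n1, n2, nax = sig.shape
    n_cs = n1 * n2
    plane = np.zeros(nax + 1)
    h = _face_conductances(sig, 2)
    on = h > 0
    dphi = np.zeros_like(h)
    dphi[on] = ph[:, :, :-1][on] - ph[:, :, 1:][on]
    plane[1:nax] = (h * dphi).sum(axis=(0, 1))
    m0 = sig[:, :, 0] > 0
    plane[0] = (2.0 * sig[:, :, 0][m0] * (1.0 - ph[:, :, 0][m0])).sum()
    m1 = sig[:, :, -1] > 0
    plane[nax] = (2.0 * sig[:, :, -1][m1] * (ph[:, :, -1][m1] + 1.0)).sum()

    E = 2.0 / (nax * grid.spacing)
    sigma_dir = float(plane.mean() / n_cs * nax / 2.0)
    return FieldSolution(
        direction=direction,
        sigma_dir=sigma_dir,
        E=E,
        phi=phi,
        residual_norm=residual_norm,
        iterations=iterations,
        excluded_voxels=excluded_voxels,
        plane_currents=plane * grid.spacing,  # physical amperes
    )


def estimate_tensor(
    model: ConductivityModel,
    tol: float = 1e-10,
    directions=DIRECTIONS,
    keep_phi: bool = False,
) -> TensorEstimate:
    """Estimate the diagonal conductivity tensor of one stack.

    Runs isolated-element exclusion, the Poisson solve, and the current
    evaluation for each requested direction (normal = x, longitudinal = y,
    transverse = z). Directions without any electrode-connected conducting
    voxels yield 0 S/m with a warning.
    """
    sols: dict[str, FieldSolution] = {}
    for d in directions:
        cleaned, removed = exclude_isolated(model, d)
        if not np.any(cleaned.sigma > 0):
            warnings.warn(
                f"no conducting path candidates for {d} direction; sigma set to 0",
                stacklevel=2,
            )
            sols[d] = FieldSolution(
                direction=d,
                sigma_dir=0.0,
                E=2.0 / (model.grid.shape[AXIS_ROLES[d]] * model.grid.spacing),
                phi=None,
                residual_norm=0.0,
                iterations=0,
                excluded_voxels=removed,
                plane_currents=np.zeros(model.grid.shape[AXIS_ROLES[d]] + 1),
            )
            continue
        phi, res, iters = solve_potential(cleaned, d, tol=tol)
        sol = current_and_conductivity(
            cleaned, phi, d, residual_norm=res, iterations=iters, excluded_voxels=removed
        )
        if not keep_phi:
            sol.phi = None
        sols[d] = sol

    def _get(d):
        return sols[d].sigma_dir if d in sols else float("nan")

    return TensorEstimate(
        sigma_myo_n=_get("normal"),
        sigma_myo_l=_get("longitudinal"),
        sigma_myo_t=_get("transverse"),
        solutions=sols,
    )
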
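"""Synthetic brick-myocyte tissue with known geometry and analytic oracles.

Real cardiac reconstructions come from confocal microscopy; for validating
the conductivity pipeline we instead generate idealized tissue in which
every quantity of interest is known by construction: densely packed
brick-shaped myocytes aligned with the y-axis, separated by one-voxel
extracellular walls, coupled by gap-junction voxel patches placed on
end-to-end and side-to-side faces, optionally interrupted by interlaminar
cleft slabs normal to x and sprinkled with vessel/fibroblast/myofibroblast
inclusions.

For untruncated periodic lattices whose junction patches cover the full
brick-shadow face, every column of the discrete conduction network is an
exact one-dimensional series chain, so the effective conductivity has a
closed form (:func:`analytic_conductivity`) that the numerical solver must
reproduce to solver tolerance. For partial-face patches the closed form
neglects the constriction resistance where current funnels into the patch
and is an upper bound; partial-patch models are validated against a dense
Kirchhoff solve instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AnalyticModelError, TissueSpecError
from .gap_junctions import GapJunctionMap
from .voxel_domain import GridSpec, IntensityVolume, SegmentVolume, TissueLabels

DIRECTIONS = ("normal", "longitudinal", "transverse")


@dataclass(frozen=True)
class BrickTissueSpec:
    """Parameters of a brick-myocyte tissue lattice.

    Parameters
    ----------
    grid
        Target voxel grid.
    myocyte_dims
        Brick dimensions ``(length_y, width_x, height_z)`` in meters; each
        must span at least 3 voxels.
    wall_thickness
        Extracellular gap between bricks, in voxels (>= 1). Gap-junction
        patches are one voxel thick, so only 1-voxel walls conduct.
    stagger_fraction
        Longitudinal offset between adjacent columns in x (running bond),
        as a fraction of the longitudinal period, in [0, 1).
    n_gj_end, n_gj_side
        Coupled gap-junction voxels sampled per realized end-to-end /
        lateral junction face.
    cleft_period_x
        Spacing of interlaminar cleft slabs normal to x, meters (0 = none).
    cleft_thickness
        Cleft slab thickness in voxels.
    inclusion_fractions
        Target volume fractions (0-1) for ``vessel`` / ``fibroblast`` /
        ``myofibroblast`` blocks carved out of the lattice.
    rotation_deg
        In-plane (about z) rotation of the myocyte long axis away from y.
        Supported for geometry only: junction counts must be 0.
    phase_y
        Global longitudinal phase of the lattice, as a fraction of the
        longitudinal period; lets repeated stacks truncate myocytes at
        different positions.
    phase_jitter
        Per-column random longitudinal phase, as a fraction of the
        period (0 = rigid lattice, 1 = fully independent columns). Real
        myocardium has no lateral registration of intercalated-disc
        positions beyond short range, so the tissue presets use 1.
    gj_margin
        In-plane erosion (voxels) of each junction-face sampling region;
        with the default 1, sampled voxels are 26-adjacent to exactly the
        two intended myocytes, so image-based detection recovers the truth
        counts exactly. Use 0 for full-shadow analytic lattices.
    seed
        RNG seed controlling junction sampling and inclusion placement.
    """

    grid: GridSpec
    myocyte_dims: tuple[float, float, float] = (100e-6, 20e-6, 20e-6)
    wall_thickness: int = 1
    stagger_fraction: float = 0.0
    n_gj_end: int = 0
    n_gj_side: int = 0
    cleft_period_x: float = 0.0
    cleft_thickness: int = 1
    inclusion_fractions: dict = field(default_factory=dict)
    rotation_deg: float = 0.0
    phase_y: float = 0.0
    phase_jitter: float = 0.0
    gj_margin: int = 1
    cx43_intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.stagger_fraction < 1.0):
            raise TissueSpecError("stagger_fraction must lie in [0, 1)")
        if self.wall_thickness < 1:
            raise TissueSpecError("wall_thickness must be >= 1 voxel")
        if min(self.n_gj_end, self.n_gj_side, self.gj_margin) < 0:
            raise TissueSpecError("junction counts and margin must be >= 0")
        L, W, H = self.voxel_dims()
        if min(L, W, H) < 3:
            raise TissueSpecError(
                f"myocyte_dims must each span >= 3 voxels, got {(L, W, H)}"
            )
        for k, v in self.inclusion_fractions.items():
            if k not in ("vessel", "fibroblast", "myofibroblast"):
                raise TissueSpecError(f"unknown inclusion class {k!r}")
            if not (0.0 <= v < 1.0):
                raise TissueSpecError(f"inclusion fraction {k}={v} out of range")

    def voxel_dims(self) -> tuple[int, int, int]:
        """Brick dimensions ``(L, W, H)`` in voxels (length, width, height)."""
        ly, wx, hz = self.myocyte_dims
        s = self.grid.spacing
        return (round(ly / s), round(wx / s), round(hz / s))

    def periods(self) -> tuple[int, int, int]:
        """Lattice periods ``(py, px, pz)`` in voxels."""
        L, W, H = self.voxel_dims()
        w = self.wall_thickness
        return (L + w, W + w, H + w)


@dataclass
class TissueTruth:
    """Ground-truth record of a generated tissue."""

    spec: BrickTissueSpec
    pair_voxels: dict[tuple[int, int], np.ndarray]
    n_bricks: int

    @property
    def pair_counts(self) -> dict[tuple[int, int], int]:
        return {p: len(v) for p, v in self.pair_voxels.items() if len(v)}


@dataclass
class SyntheticTissue:
    segments: SegmentVolume
    labels: TissueLabels
    cx43: IntensityVolume
    truth: TissueTruth


def _column_offset(spec: BrickTissueSpec, cix: int, ciz: int) -> int:
    py = spec.periods()[0]
    frac = spec.phase_y + cix * spec.stagger_fraction
    if spec.phase_jitter:
        u = np.random.default_rng((spec.seed, 0x9E3779B9, cix, ciz)).uniform()
        frac += spec.phase_jitter * u
    return int(round((frac % 1.0) * py)) % py


def _enumerate_bricks(spec: BrickTissueSpec):
    """Yield ``(cell, id, (x0, x1), (y0, y1), (z0, z1))`` for realized bricks."""
    nx, ny, nz = spec.grid.shape
    L, W, H = spec.voxel_dims()
    py, px, pz = spec.periods()
    ncx = math.ceil(nx / px)
    ncz = math.ceil(nz / pz)
    out = {}
    next_id = 1
    for cix in range(ncx):
        for ciz in range(ncz):
            off = _column_offset(spec, cix, ciz)
            for ciy in range(-1, math.ceil(ny / py) + 1):
                y0 = off + ciy * py
                ya, yb = max(y0, 0), min(y0 + L, ny)
                xa, xb = cix * px, min(cix * px + W, nx)
                za, zb = ciz * pz, min(ciz * pz + H, nz)
                if ya < yb and xa < xb and za < zb:
                    out[(cix, ciy, ciz)] = (next_id, (xa, xb), (ya, yb), (za, zb))
                    next_id += 1
    return out


def _cleft_slabs(spec: BrickTissueSpec) -> list[tuple[int, int]]:
    """Cleft slab x-ranges, snapped to the nearest inter-myocyte wall plane.

    Interlaminar clefts run between laminae of myocytes, so each slab is
    centered on a lattice wall (a slab through the middle of a myocyte
    would be sealed again by the membrane-layer reconstruction, which
    merges voxels of one and the same cell).
    """
    if spec.cleft_period_x <= 0:
        return []
    nx = spec.grid.shape[0]
    _, W, _ = spec.voxel_dims()
    px = spec.periods()[1]
    wall = spec.wall_thickness
    p = round(spec.cleft_period_x / spec.grid.spacing)
    if p < 1:
        raise TissueSpecError("cleft_period_x below one voxel")
    t = max(spec.cleft_thickness, wall)
    slabs = []
    x = p
    while x < nx:
        k = max(round((x - W) / px), 0)
        ws = k * px + W  # start of the nearest x-wall
        a = ws - (t - wall) // 2
        slab = (max(a, 0), min(a + t, nx))
        if slab[0] < slab[1] and slab not in slabs:
            slabs.append(slab)
        x += p
    return slabs


def _place_inclusions(spec, rng, ids, labels) -> None:
    """Carve random non-overlapping blocks until target fractions are met.

    Blocks overwrite myocyte and wall voxels (never clefts or other
    inclusions); vessels are elongated along y like capillaries.
    """
    total = spec.grid.n_voxels
    occupied = labels.cleft.copy()
    nx, ny, nz = spec.grid.shape
    for cls in ("vessel", "fibroblast", "myofibroblast"):
        target = spec.inclusion_fractions.get(cls, 0.0)
        if target <= 0:
            continue
        mask = getattr(labels, cls)
        placed = 0
        attempts = 0
        while placed < target * total:
            attempts += 1
            if attempts > 200000:
                raise TissueSpecError(f"cannot satisfy inclusion fraction for {cls}")
            if cls == "vessel":
                sx, sy, sz = rng.integers(2, 5), rng.integers(8, 25), rng.integers(2, 5)
            else:
                sx, sy, sz = rng.integers(2, 7, size=3)
            if sx > nx or sy > ny or sz > nz:
                continue
            x = rng.integers(0, nx - sx + 1)
            y = rng.integers(0, ny - sy + 1)
            z = rng.integers(0, nz - sz + 1)
            sl = (slice(x, x + sx), slice(y, y + sy), slice(z, z + sz))
            if occupied[sl].any():
                continue
            mask[sl] = True
            occupied[sl] = True
            ids[sl] = 0
            placed += sx * sy * sz
        setattr(labels, cls, mask)


def _sample_face(rng, cand: np.ndarray, n: int) -> np.ndarray:
    """Uniformly sample up to ``n`` candidate voxels without replacement."""
    if len(cand) == 0 or n == 0:
        return cand[:0]
    k = min(n, len(cand))
    pick = rng.choice(len(cand), size=k, replace=False)
    return cand[np.sort(pick)]


def generate_brick_tissue(spec: BrickTissueSpec) -> SyntheticTissue:
    """Generate a brick-myocyte tissue volume with ground truth.

    The same seed always yields a bit-identical tissue. Myocytes truncated
    at grid borders keep their own IDs. Junction faces clipped by the
    border, clefts or inclusions sample from the surviving candidate
    voxels only (fewer than the nominal count if necessary).
    """
    grid = spec.grid
    nx, ny, nz = grid.shape
    L, W, H = spec.voxel_dims()
    py, px, pz = spec.periods()
    rng = np.random.default_rng(spec.seed)

    if spec.rotation_deg != 0.0:
        if spec.n_gj_end or spec.n_gj_side:
            raise TissueSpecError("junction placement requires rotation_deg == 0")
        if spec.phase_jitter:
            raise TissueSpecError("phase_jitter requires rotation_deg == 0")
        ids = _rotated_ids(spec)
        bricks = {}
    else:
        if spec.n_gj_end > max(W - 2 * spec.gj_margin, 0) * max(H - 2 * spec.gj_margin, 0):
            raise TissueSpecError("n_gj_end exceeds the junction face area")
        side_max = max(L - 2 * spec.gj_margin, 0) * max(
            max(W, H) - 2 * spec.gj_margin, 0
        )
        if spec.n_gj_side > side_max:
            raise TissueSpecError("n_gj_side exceeds the junction face area")
        bricks = _enumerate_bricks(spec)
        ids = np.zeros(grid.shape, dtype=np.int32)
        for bid, (xa, xb), (ya, yb), (za, zb) in bricks.values():
            ids[xa:xb, ya:yb, za:zb] = bid

    labels = TissueLabels.empty(grid)
    for xa, xb in _cleft_slabs(spec):
        labels.cleft[xa:xb, :, :] = True
        ids[xa:xb, :, :] = 0
    _place_inclusions(spec, rng, ids, labels)

    cx43 = np.zeros(grid.shape, dtype=np.float64)
    pair_voxels: dict[tuple[int, int], np.ndarray] = {}
    if spec.rotation_deg == 0.0 and (spec.n_gj_end or spec.n_gj_side):
        if spec.wall_thickness != 1:
            raise TissueSpecError("junction placement requires 1-voxel walls")
        blocked = labels.vessel | labels.fibroblast | labels.myofibroblast | labels.cleft
        for pair, cand in _junction_faces(spec, bricks, ids, blocked):
            n = spec.n_gj_end if pair[2] == "end" else spec.n_gj_side
            chosen = _sample_face(rng, cand, n)
            if len(chosen):
                cx43[chosen[:, 0], chosen[:, 1], chosen[:, 2]] = spec.cx43_intensity
                key = (min(pair[0], pair[1]), max(pair[0], pair[1]))
                pair_voxels[key] = chosen

    truth = TissueTruth(spec, pair_voxels, n_bricks=len(bricks))
    return SyntheticTissue(
        segments=SegmentVolume(grid, ids),
        labels=labels,
        cx43=IntensityVolume(grid, cx43),
        truth=truth,
    )


def _junction_faces(spec, bricks, ids, blocked):
    """Yield ``((id_a, id_b, kind), candidates)`` for every realized face.

    Candidates are wall voxels in the (margin-eroded) overlap shadow whose
    two face-neighbors still belong to the intended bricks and that are
    not claimed by a cleft or inclusion.
    """
    nx, ny, nz = spec.grid.shape
    L, W, H = spec.voxel_dims()
    py, px, pz = spec.periods()
    m = spec.gj_margin

    def cand_from(xr, yr, zr, axis, ida, idb):
        xs = np.arange(max(xr[0], 0), min(xr[1], nx))
        ys = np.arange(max(yr[0], 0), min(yr[1], ny))
        zs = np.arange(max(zr[0], 0), min(zr[1], nz))
        if not (len(xs) and len(ys) and len(zs)):
            return np.empty((0, 3), dtype=np.int64)
        X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        lo = pts.copy()
        hi = pts.copy()
        lo[:, axis] -= 1
        hi[:, axis] += 1
        ok = (
            (lo[:, axis] >= 0)
            & (hi[:, axis] < spec.grid.shape[axis])
            & ~blocked[pts[:, 0], pts[:, 1], pts[:, 2]]
            & (ids[pts[:, 0], pts[:, 1], pts[:, 2]] == 0)
        )
        pts = pts[ok]
        lo, hi = lo[ok], hi[ok]
        ok = (ids[lo[:, 0], lo[:, 1], lo[:, 2]] == ida) & (
            ids[hi[:, 0], hi[:, 1], hi[:, 2]] == idb
        )
        return pts[ok]

    for (cix, ciy, ciz), (ida, _, (ya, _yb), _) in sorted(bricks.items()):
        x0, z0 = cix * px, ciz * pz
        y0 = _column_offset(spec, cix, ciz) + ciy * py
        # end-to-end: next brick in the same column
        nb = bricks.get((cix, ciy + 1, ciz))
        if nb is not None:
            yw = y0 + L
            cand = cand_from(
                (x0 + m, x0 + W - m), (yw, yw + 1), (z0 + m, z0 + H - m), 1, ida, nb[0]
            )
            yield (ida, nb[0], "end"), cand
        # lateral x: overlapping bricks in the next column over x
        xw = x0 + W
        off2 = _column_offset(spec, cix + 1, ciz)
        for ciy2 in range(ciy - 2, ciy + 3):
            nb = bricks.get((cix + 1, ciy2, ciz))
            if nb is None:
                continue
            y02 = off2 + ciy2 * py
            oy0, oy1 = max(y0, y02), min(y0 + L, y02 + L)
            if oy1 <= oy0:
                continue
            cand = cand_from(
                (xw, xw + 1), (oy0 + m, oy1 - m), (z0 + m, z0 + H - m), 0, ida, nb[0]
            )
            yield (ida, nb[0], "side"), cand
        # lateral z: same column, next sheet over z (no stagger in z)
        nb = bricks.get((cix, ciy, ciz + 1))
        if nb is not None:
            zw = z0 + H
            cand = cand_from(
                (x0 + m, x0 + W - m), (y0 + m, y0 + L - m), (zw, zw + 1), 2, ida, nb[0]
            )
            yield (ida, nb[0], "side"), cand


def _rotated_ids(spec: BrickTissueSpec) -> np.ndarray:
    """Voxelize the lattice with the long axis rotated about z."""
    nx, ny, nz = spec.grid.shape
    L, W, H = spec.voxel_dims()
    py, px, pz = spec.periods()
    th = math.radians(spec.rotation_deg)
    x = np.arange(nx) + 0.5 - nx / 2
    y = np.arange(ny) + 0.5 - ny / 2
    z = np.arange(nz) + 0.5
    X, Y = np.meshgrid(x, y, indexing="ij")
    U = math.cos(th) * X + math.sin(th) * Y + nx / 2
    V = -math.sin(th) * X + math.cos(th) * Y + ny / 2
    cix = np.floor(U / px).astype(np.int64)
    in_x = (U - cix * px) < W
    offs = (spec.phase_y + cix * spec.stagger_fraction) % 1.0
    Vs = V - np.round(offs * py)
    ciy = np.floor(Vs / py).astype(np.int64)
    in_y = (Vs - ciy * py) < L
    ciz = np.floor(z / pz).astype(np.int64)
    in_z = (z - ciz * pz) < H
    cix -= cix.min()
    ciy -= ciy.min()
    ciz -= ciz.min()
    ky, kz = int(ciy.max()) + 1, int(ciz.max()) + 1
    code2d = (cix * ky + ciy) * kz + 1  # +ciz added below; +1 reserves 0 for background
    codes = code2d[:, :, None] + ciz[None, None, :]
    inside = (in_x & in_y)[:, :, None] & in_z[None, None, :]
    codes = np.where(inside, codes, 0)
    vals, inv = np.unique(codes, return_inverse=True)
    compact = inv.reshape(codes.shape).astype(np.int32)
    if vals[0] != 0:  # no background voxel at all
        compact += 1
    return compact


def truth_gap_junction_map(tissue: SyntheticTissue) -> GapJunctionMap:
    """Ground-truth gap-junction map straight from the generator record."""
    grid = tissue.segments.grid
    mask = np.zeros(grid.shape, dtype=bool)
    counts: dict[tuple[int, int], int] = {}
    for pair, vox in tissue.truth.pair_voxels.items():
        if len(vox) == 0:
            continue
        mask[vox[:, 0], vox[:, 1], vox[:, 2]] = True
        counts[pair] = counts.get(pair, 0) + len(vox)
    return GapJunctionMap(grid, mask, counts)


def analytic_conductivity(
    spec: BrickTissueSpec,
    direction: str,
    sigma_cyto: float,
    sigma_gj: float,
) -> float:
    """Closed-form effective conductivity of an untruncated brick lattice.

    Along the chosen direction each conducting column is a series chain of
    myocyte spans at ``sigma_cyto`` and one-voxel junction layers whose
    conducting area is the junction voxel count at ``sigma_gj`` (rest
    insulating); the column conductivity is scaled by the conducting
    cross-sectional area fraction. The reduction assumes equipotential
    cross-sections; it matches the discrete network *exactly* when the
    junction patch covers the full brick-shadow face (each column is then
    a true 1D chain), and is an upper bound otherwise (patch constriction
    is neglected). As the brick count grows it approaches the infinite
    periodic lattice value. Returns 0 for multi-brick directions without
    junction voxels and for the normal direction when cleft slabs
    interrupt it.

    Preconditions: zero stagger/phase/rotation, no inclusions, 1-voxel
    walls, and a grid that tiles exactly: along the field direction the
    lattice must end with a brick on both electrodes (``n = k * period -
    1``, or a single brick spanning the axis), and across the field each
    axis must hold whole bricks (``n = k * period`` or ``k * period - 1``).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {DIRECTIONS}")
    if spec.stagger_fraction or spec.phase_y or spec.phase_jitter or spec.rotation_deg:
        raise AnalyticModelError("closed form requires an unstaggered, unrotated lattice")
    if spec.inclusion_fractions and any(spec.inclusion_fractions.values()):
        raise AnalyticModelError("closed form requires a lattice without inclusions")
    if spec.wall_thickness != 1:
        raise AnalyticModelError("closed form requires 1-voxel walls")
    L, W, H = spec.voxel_dims()
    py, px, pz = spec.periods()
    nx, ny, nz = spec.grid.shape

    has_clefts = spec.cleft_period_x > 0
    if direction == "normal":
        if has_clefts:
            return 0.0
        axis, span, period, n_gj = 0, W, px, spec.n_gj_side
        shadow, cross = L * H, ((ny, py, L), (nz, pz, H))
    elif direction == "longitudinal":
        if has_clefts:
            raise AnalyticModelError("cleft slabs are outside the longitudinal closed form")
        axis, span, period, n_gj = 1, L, py, spec.n_gj_end
        shadow, cross = W * H, ((nx, px, W), (nz, pz, H))
    else:
        if has_clefts:
            raise AnalyticModelError("cleft slabs are outside the transverse closed form")
        axis, span, period, n_gj = 2, H, pz, spec.n_gj_side
        shadow, cross = L * W, ((nx, px, W), (ny, py, L))

    n_ax = spec.grid.shape[axis]
    wall = spec.wall_thickness
    n_b = (n_ax + wall) // period
    if n_b * period - wall != n_ax:
        raise AnalyticModelError(
            "field axis must end with a brick on both electrodes (n = k * period - wall)"
        )
    # conducting cross-sectional area fraction from whole bricks across the field
    conducting_cs, total_cs = 1, 1
    for n_t, p_t, b_t in cross:
        k = (n_t + wall) // p_t
        if n_t not in (k * p_t, k * p_t - wall):
            raise AnalyticModelError("cross-section axes must hold whole bricks")
        conducting_cs *= k * b_t
        total_cs *= n_t
    if n_b >= 2 and (n_gj == 0 or sigma_gj == 0.0):
        return 0.0
    # junction layers of the other families lie parallel to the field; when
    # such walls exist their conducting patches are extra bridges the
    # layered reduction does not model
    kx = (nx + wall) // px
    ky = (ny + wall) // py
    kz = (nz + wall) // pz
    parallel = (
        (axis != 1 and spec.n_gj_end > 0 and ky >= 2)
        or (axis != 0 and spec.n_gj_side > 0 and kx >= 2)
        or (axis != 2 and spec.n_gj_side > 0 and kz >= 2)
    )
    if parallel:
        raise AnalyticModelError(
            "junction layers parallel to the field axis are outside the closed form"
        )
    resistance = n_b * span / sigma_cyto
    if n_b >= 2:
        resistance += (n_b - 1) * shadow / (n_gj * sigma_gj)
    return (n_ax / resistance) * conducting_cs / total_cs


def control_spec(grid: GridSpec, seed: int = 0, **overrides) -> BrickTissueSpec:
    """Control-tissue preset: dense packing, both junction families, thin clefts.

    Defaults target the composition of normal left-ventricular myocardium
    at the generator's level of abstraction: 100 x 20 x 20 um myocytes,
    staggered columns, and junction counts that put the gap-junction voxel
    fraction near 0.1% at 1 um spacing.
    """
    base = dict(
        grid=grid,
        myocyte_dims=(100e-6, 20e-6, 20e-6),
        wall_thickness=1,
        stagger_fraction=0.5,
        phase_jitter=1.0,
        n_gj_end=24,
        n_gj_side=6,
        cleft_period_x=50e-6,
        cleft_thickness=1,
        inclusion_fractions={"vessel": 0.02, "fibroblast": 0.01},
        seed=seed,
    )
    base.update(overrides)
    return BrickTissueSpec(**base)


def mi_spec(grid: GridSpec, seed: int = 0, **overrides) -> BrickTissueSpec:
    """Infarct border-zone preset: ~0.4x junction counts, expanded clefts,
    more non-myocyte inclusions (lower Vmyo, higher fibrosis)."""
    base = dict(
        grid=grid,
        myocyte_dims=(100e-6, 20e-6, 20e-6),
        wall_thickness=1,
        stagger_fraction=0.5,
        phase_jitter=1.0,
        n_gj_end=10,
        n_gj_side=2,
        cleft_period_x=40e-6,
        cleft_thickness=3,
        inclusion_fractions={"vessel": 0.03, "fibroblast": 0.03, "myofibroblast": 0.01},
        seed=seed,
    )
    base.update(overrides)
    return BrickTissueSpec(**base)
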
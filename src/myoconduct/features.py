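"""Tissue-composition features, microstructural orientation, and QC.

Composition is reported as volume fractions (percent of stack voxels):
myocytes ``Vmyo``, vessels, fibroblasts, myofibroblasts, and the
extracellular space as the residual

    Ve = 100% - (Vmyo + Vfibro + Vmyofibro + Vvessels),

with clefts counted inside Ve but also reported separately. Fibrosis is
defined relative to the control group: the excess of
``Ve + Vfibro + Vmyofibro`` in a sample over the control-group mean of the
same sum, so the control-group mean of ``Vfibrosis`` is zero by
construction.

Microstructural alignment is summarized by two angles: the deviation of
the mean myocyte long axis from y (``delta_l``) and the deviation of the
largest interlaminar cleft plane's normal from x (``delta_n``). Stacks
with weak alignment (``delta_l > 10`` deg or ``delta_n > 30`` deg) are
flagged for exclusion, since the directional conductivities are only
meaningful in the aligned frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .errors import OverlapError
from .gap_junctions import GapJunctionMap
from .voxel_domain import SegmentVolume, TissueLabels

_CUBE = np.ones((3, 3, 3), dtype=bool)


@dataclass
class TissueFeatures:
    """Per-stack composition and orientation features (fractions in %)."""

    v_myo: float = 0.0
    v_vessels: float = 0.0
    v_fibro: float = 0.0
    v_myofibro: float = 0.0
    v_e: float = 100.0
    v_clefts: float = 0.0
    v_gj: float = 0.0
    v_fibrosis: float | None = None
    delta_l: float | None = None
    delta_n: float | None = None
    no_cleft: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


def extracellular_fraction(
    v_myo: float, v_vessels: float, v_fibro: float, v_myofibro: float
) -> float:
    """Extracellular-space fraction as the residual of the cell classes (%)."""
    return 100.0 - (v_myo + v_fibro + v_myofibro + v_vessels)


def volume_fractions(
    segments: SegmentVolume,
    labels: TissueLabels,
    gj: GapJunctionMap | None = None,
) -> TissueFeatures:
    """Compute the composition fractions of one stack.

    Raises :class:`OverlapError` if the cell-class masks overlap each
    other, the myocytes, or (for clefts) any cell class.
    """
    total = segments.grid.n_voxels
    myo = segments.ids > 0
    cell_masks = {
        "vessel": labels.vessel,
        "fibroblast": labels.fibroblast,
        "myofibroblast": labels.myofibroblast,
    }
    names = list(cell_masks)
    for i, a in enumerate(names):
        if np.any(cell_masks[a] & myo):
            raise OverlapError(f"{a} mask overlaps myocyte voxels")
        for b in names[i + 1 :]:
            if np.any(cell_masks[a] & cell_masks[b]):
                raise OverlapError(f"{a} and {b} masks overlap")
    cells = myo | labels.vessel | labels.fibroblast | labels.myofibroblast
    if np.any(labels.cleft & cells):
        raise OverlapError("cleft mask overlaps cell voxels")

    pct = 100.0 / total
    v_myo = float(myo.sum()) * pct
    v_vessels = float(labels.vessel.sum()) * pct
    v_fibro = float(labels.fibroblast.sum()) * pct
    v_myofibro = float(labels.myofibroblast.sum()) * pct
    return TissueFeatures(
        v_myo=v_myo,
        v_vessels=v_vessels,
        v_fibro=v_fibro,
        v_myofibro=v_myofibro,
        v_e=extracellular_fraction(v_myo, v_vessels, v_fibro, v_myofibro),
        v_clefts=float(labels.cleft.sum()) * pct,
        v_gj=gj.v_gj if gj is not None else 0.0,
    )


def _fibrosis_sum(f: TissueFeatures) -> float:
    return f.v_e + f.v_fibro + f.v_myofibro


def fibrosis_fraction(sample: TissueFeatures, control_group) -> float:
    """Fibrosis fraction relative to the control-group mean (%).

    May be negative for control samples; the mean over the control group
    itself is zero by construction.
    """
    control_group = list(control_group)
    if not control_group:
        raise ValueError("control group must be non-empty")
    ref = float(np.mean([_fibrosis_sum(f) for f in control_group]))
    return _fibrosis_sum(sample) - ref


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest second-order central moment."""
    c = coords - coords.mean(axis=0)
    mom = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(mom)
    return evecs[:, np.argmax(evals)]


def _align(v: np.ndarray, axis: int) -> np.ndarray:
    # axes are directionless; flip into the non-negative hemisphere of `axis`
    if v[axis] < 0:
        return -v
    if v[axis] == 0:  # degenerate: fall back to first nonzero component
        for c in v:
            if c != 0:
                return v if c > 0 else -v
    return v


def myocyte_orientation(segments: SegmentVolume, n_largest: int = 10) -> float:
    """Deviation of the mean myocyte long axis from y, in degrees.

    The long axis of each of the ``n_largest`` myocytes by voxel count is
    the principal eigenvector of its second-order central moments; axes
    are sign-aligned to +y and averaged as unit vectors. With fewer
    myocytes than requested, all are used (with a warning). Degenerate
    moment tensors (e.g. spheres) use numpy's deterministic eigenvector
    ordering.
    """
    ids = segments.myocyte_ids()
    if len(ids) == 0:
        raise ValueError("orientation requires at least one myocyte")
    counts = np.bincount(segments.ids.ravel())
    counts[0] = 0
    order = np.argsort(counts)[::-1]
    top = [i for i in order[:n_largest] if counts[i] > 0]
    if len(top) < n_largest:
        warnings.warn(
            f"only {len(top)} myocytes available for orientation (requested {n_largest})",
            stacklevel=2,
        )
    axes = []
    for i in top:
        coords = np.argwhere(segments.ids == i).astype(float) + 0.5
        axes.append(_align(_principal_axis(coords), axis=1))
    mean = np.mean(axes, axis=0)
    mean /= np.linalg.norm(mean)
    return float(np.degrees(np.arccos(np.clip(abs(mean[1]), -1.0, 1.0))))


def cleft_normal(labels: TissueLabels) -> tuple[float, bool]:
    """Deviation of the largest cleft plane's normal from x, in degrees.

    The largest 26-connected component of the cleft mask is fit by a
    plane (least squares on voxel centers); the plane normal is the
    smallest-eigenvalue eigenvector of the central moments. Returns
    ``(delta_n, no_cleft)``; an empty cleft mask yields ``(0.0, True)``.
    """
    if not labels.cleft.any():
        return 0.0, True
    lab, n = ndi.label(labels.cleft, structure=_CUBE)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    largest = int(np.argmax(sizes))
    coords = np.argwhere(lab == largest).astype(float) + 0.5
    c = coords - coords.mean(axis=0)
    mom = c.T @ c / len(c)
    evals, evecs = np.linalg.eigh(mom)
    normal = evecs[:, np.argmin(evals)]
    return float(np.degrees(np.arccos(np.clip(abs(normal[0]), -1.0, 1.0)))), False


def qc_exclude(features: TissueFeatures) -> TissueFeatures:
    """Flag stacks with weak microstructural alignment.

    Exclusion fires on ``delta_l > 10`` degrees or ``delta_n > 30``
    degrees (strict inequalities); the reason names the offending angle.
    """
    if features.delta_l is None or features.delta_n is None:
        raise ValueError("delta_l and delta_n must be computed before QC")
    reasons = []
    if features.delta_l > 10.0:
        reasons.append(f"delta_l {features.delta_l:.1f} deg > 10 deg")
    if features.delta_n > 30.0:
        reasons.append(f"delta_n {features.delta_n:.1f} deg > 30 deg")
    features.excluded = bool(reasons)
    features.exclusion_reason = "; ".join(reasons)
    return features
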
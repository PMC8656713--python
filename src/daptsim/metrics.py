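"""DVH metrics and dose accumulation onto the planning geometry.

Dose-volume metrics follow the voxel-rank convention: ``D_q`` is the value
at rank ``ceil(q/100 * n)`` of the structure's voxel doses sorted in
descending order (the largest dose received by at least q% of the volume).
No interpolation between sorted voxel doses is performed; the DVH-curve
readout serves as an independent cross-check, not as the definition.

Accumulation resamples each fraction dose back to the planning frame by
the exact inverse of its composed rigid transform (daily setup plus
post-adaptation offset) with trilinear interpolation, then sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .cohort import Phantom
from .grid import VoxelGrid

__all__ = [
    "DVHCurve",
    "accumulate",
    "warp_to_planning",
    "dose_at_volume",
    "d_1cc",
    "mean_dose",
    "integral_dose",
    "dvh",
]


@dataclass
class DVHCurve:
    """Cumulative dose-volume curve on uniform dose bins."""

    dose_edges: np.ndarray              # Gy, left bin edges starting at 0
    cumulative_volume_fraction: np.ndarray  # in [0, 1], non-increasing

    def __post_init__(self) -> None:
        v = self.cumulative_volume_fraction
        if v[0] != 1.0 or np.any(np.diff(v) > 1e-12):
            raise ValueError("DVH curve must start at 1.0 and be non-increasing")

    def dose_at_volume(self, q: float) -> float:
        """Largest dose edge with at least q% cumulative volume."""
        ok = np.flatnonzero(self.cumulative_volume_fraction >= q / 100.0)
        return float(self.dose_edges[ok[-1]]) if ok.size else 0.0


def warp_to_planning(dose: VoxelGrid, transform_mm) -> VoxelGrid:
    """Invert a rigid translation: dose delivered on a geometry displaced by
    ``transform_mm`` (planning -> delivery) is pulled back to the planning
    frame by trilinear resampling at the translated coordinates."""
    t = np.asarray(transform_mm, float)
    if np.all(t == 0):
        return dose.copy()
    dvox = -t / np.asarray(dose.spacing)
    vals = ndimage.shift(dose.values, dvox, order=1, mode="constant", cval=0.0)
    np.clip(vals, 0.0, None, out=vals)
    return VoxelGrid(dose.spacing, dose.origin, vals)


def accumulate(outcomes, planning_phantom: Phantom) -> VoxelGrid:
    """Sum fraction doses warped back to the planning grid.

    ``outcomes`` is an iterable of objects exposing ``delivered_dose``
    (a :class:`VoxelGrid`) and ``total_transform`` (planning -> delivery
    translation in mm); plain ``(dose, transform)`` pairs are accepted too.
    """
    total = planning_phantom.grid.zeros()
    count = 0
    for item in outcomes:
        if hasattr(item, "delivered_dose"):
            dose, t = item.delivered_dose, item.total_transform
        else:
            dose, t = item
        if t is None:
            raise ValueError("fraction outcome is missing its transform")
        if tuple(dose.shape) != tuple(total.shape):
            raise ValueError("fraction dose grid does not match planning grid")
        total.values += warp_to_planning(dose, t).values
        count += 1
    if count == 0:
        raise ValueError("no fraction outcomes to accumulate")
    return total


def _structure_doses(dose: VoxelGrid, mask: np.ndarray) -> np.ndarray:
    if not mask.any():
        raise ValueError("empty structure mask")
    return dose.values[mask]


def dose_at_volume(dose: VoxelGrid, mask: np.ndarray, q: float) -> float:
    """Minimum dose to the hottest q% of the structure (voxel-rank D_q)."""
    if not 0 < q <= 100:
        raise ValueError("q must be in (0, 100]")
    vals = np.sort(_structure_doses(dose, mask))[::-1]
    k = int(np.ceil(q / 100.0 * len(vals)))
    return float(vals[k - 1])


def d_1cc(dose: VoxelGrid, mask: np.ndarray, voxel_volume: float) -> float:
    """Minimum dose to the most irradiated 1 cc (1000 mm^3)."""
    vals = np.sort(_structure_doses(dose, mask))[::-1]
    k = int(np.ceil(1000.0 / voxel_volume))
    if k > len(vals):
        warnings.warn(
            "structure smaller than 1 cc; D1cc falls back to the minimum dose",
            stacklevel=2,
        )
        k = len(vals)
    return float(vals[k - 1])


def mean_dose(dose: VoxelGrid, mask: np.ndarray) -> float:
    """Arithmetic mean dose (Gy) over the mask."""
    return float(_structure_doses(dose, mask).mean())


def integral_dose(dose: VoxelGrid, healthy_mask: np.ndarray, voxel_volume: float | None = None) -> float:
    """Integral dose D.V over the healthy tissue, in Gy * liter."""
    vv = dose.voxel_volume if voxel_volume is None else voxel_volume
    return float(_structure_doses(dose, healthy_mask).sum() * vv / 1e6)


def dvh(dose: VoxelGrid, mask: np.ndarray, bin_width: float = 0.1) -> DVHCurve:
    """Cumulative DVH with uniform bins of ``bin_width`` Gy."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = _structure_doses(dose, mask)
    n_bins = int(np.ceil((vals.max() + bin_width) / bin_width)) + 1
    edges = bin_width * np.arange(n_bins + 1)
    hist, _ = np.histogram(vals, bins=edges)
    # volume fraction receiving at least the left edge of each bin
    cum = 1.0 - np.concatenate([[0.0], np.cumsum(hist) / len(vals)])[:-1]
    return DVHCurve(dose_edges=edges[:-1], cumulative_volume_fraction=cum)
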
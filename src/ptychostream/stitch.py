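"""Assemble per-position phase patches from an irregular scan into one image.

Each 128x128 (or smaller) inference patch is centred on its beam position,
which for spiral scans does not lie on a regular grid.  Every patch is
bilinearly resampled onto a common regular grid and the overlapping values
statistically averaged — uniformly, or weighted by the probe amplitude so
pixels seen through the bright ring of the illumination count more.
Pixels never covered by any patch carry zero weight and are NaN in the
output; metrics must exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PatchSet", "StitchedImage", "stitch"]


@dataclass
class PatchSet:
    """Phase patches plus the beam position of each, all on one pixel pitch."""

    patches: np.ndarray
    positions_nm: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=np.float64)
        self.positions_nm = np.atleast_2d(np.asarray(self.positions_nm, dtype=np.float64))
        if self.patches.ndim != 3 or self.patches.shape[0] < 1:
            raise ValueError("patches must be a nonempty (n, s, s) array")
        if self.positions_nm.shape != (self.patches.shape[0], 2):
            raise ValueError("need exactly one (x, y) position per patch")

    @property
    def n(self) -> int:
        return int(self.patches.shape[0])

    @property
    def side(self) -> int:
        return int(self.patches.shape[1])


@dataclass
class StitchedImage:
    """Averaged phase on a regular grid plus the accumulated weight map."""

    phase: np.ndarray
    weight: np.ndarray
    origin_nm: tuple[float, float]
    pixel_size_nm: float

    @property
    def valid(self) -> np.ndarray:
        return self.weight > 0


def stitch(patchset: PatchSet, weighting: str = "uniform",
           probe_amplitude: np.ndarray | None = None,
           origin_nm: tuple[float, float] | None = None,
           shape: tuple[int, int] | None = None) -> StitchedImage:
    """Average bilinearly-resampled patches onto a global regular grid.

    The grid spacing equals the patch pixel size; by default the grid is the
    bounding box of all patch footprints.  ``weighting='probe_amplitude'``
    weights each contribution by ``|probe|`` resampled along with the patch.
    Accumulation is in double precision and commutative, so the result is
    invariant to patch order.
    """
    if weighting not in ("uniform", "probe_amplitude"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if weighting == "probe_amplitude":
        if probe_amplitude is None:
            raise ValueError("probe_amplitude weighting requires the probe amplitude")
        if probe_amplitude.shape != patchset.patches.shape[1:]:
            raise ValueError("probe amplitude must match the patch shape")
    px = patchset.pixel_size_nm
    s = patchset.side
    half = (s - 1) / 2.0

    if origin_nm is None or shape is None:
        lo = patchset.positions_nm.min(axis=0) - half * px
        hi = patchset.positions_nm.max(axis=0) + half * px
        origin_nm = (float(lo[0]), float(lo[1]))
        shape = (int(np.ceil((hi[1] - lo[1]) / px)) + 1,
                 int(np.ceil((hi[0] - lo[0]) / px)) + 1)

    acc = np.zeros(shape, dtype=np.float64)
    wacc = np.zeros(shape, dtype=np.float64)
    gy = np.arange(shape[0])
    gx = np.arange(shape[1])

    for i in range(patchset.n):
        x_nm, y_nm = patchset.positions_nm[i]
        # patch pixel coordinates of each global grid node in the footprint
        pc_col = (origin_nm[0] + gx * px - x_nm) / px + half
        pc_row = (origin_nm[1] + gy * px - y_nm) / px + half
        cols = np.nonzero((pc_col >= 0) & (pc_col <= s - 1))[0]
        rows = np.nonzero((pc_row >= 0) & (pc_row <= s - 1))[0]
        if cols.size == 0 or rows.size == 0:
            continue
        rr, cc = np.meshgrid(pc_row[rows], pc_col[cols], indexing="ij")
        coords = np.vstack([rr.ravel(), cc.ravel()])
        vals = ndimage.map_coordinates(patchset.patches[i], coords, order=1,
                                       mode="nearest").reshape(rr.shape)
        if weighting == "probe_amplitude":
            w = ndimage.map_coordinates(probe_amplitude, coords, order=1,
                                        mode="nearest").reshape(rr.shape)
        else:
            w = np.ones_like(vals)
        acc[np.ix_(rows, cols)] += w * vals
        wacc[np.ix_(rows, cols)] += w

    with np.errstate(invalid="ignore", divide="ignore"):
        phase = acc / wacc
    phase[wacc == 0] = np.nan
    return StitchedImage(phase, wacc, origin_nm, px)
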
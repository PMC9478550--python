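"""Barrier-avoiding geodesic distances on the pixel grid.

Cracks and folds in a damaged section break the spatial correlation between
tissue on the two sides of the damage line.  Plain Euclidean distance ignores
the damage; the path (geodesic) distance — the length of the shortest pixel
path that bypasses barrier pixels — does not.  This module computes such
distances by wavefront expansion (a priority-queue grid Dijkstra) and, on top
of it, the per-pixel distance to the K-th nearest member of a point set, the
quantity that drives the KNN density estimate of the expected-affine blend.

All coordinates are 0-based ``(row, col)`` with the origin at the top-left of
the image, matching NumPy indexing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import tifffile

from ._wavefront import k_nearest, wavefront
from .errors import InvalidInputError

__all__ = [
    "GridMetric",
    "DamageMask",
    "GeodesicDistanceMap",
    "snap_to_free",
    "wavefront_distance",
    "kth_nearest_distance",
    "k_order_distances",
]


@dataclass(frozen=True)
class GridMetric:
    """Connectivity and step weights of the pixel-grid graph.

    4-connectivity uses unit axial steps; 8-connectivity adds diagonal steps
    of weight sqrt(2), which approximates Euclidean distance more closely in
    the undamaged limit.
    """

    connectivity: int = 8

    def __post_init__(self):
        if self.connectivity not in (4, 8):
            raise InvalidInputError(
                f"connectivity must be 4 or 8, got {self.connectivity}"
            )

    def offsets(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Neighbor offsets ``(drow, dcol, weight)`` as int64/int64/float64."""
        dr = [-1, 1, 0, 0]
        dc = [0, 0, -1, 1]
        w = [1.0, 1.0, 1.0, 1.0]
        if self.connectivity == 8:
            dr += [-1, -1, 1, 1]
            dc += [-1, 1, -1, 1]
            w += [math.sqrt(2.0)] * 4
        return (
            np.asarray(dr, dtype=np.int64),
            np.asarray(dc, dtype=np.int64),
            np.asarray(w, dtype=np.float64),
        )


@dataclass
class DamageMask:
    """Binary barrier raster in the moving-image frame (True = damage pixel)."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise InvalidInputError("damage mask must be a 2-D raster")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def n_free(self) -> int:
        return int(self.grid.size - self.grid.sum())

    def require_free(self) -> None:
        if self.n_free == 0:
            raise InvalidInputError("damage mask has no non-barrier pixel")

    @classmethod
    def empty(cls, shape: tuple[int, int]) -> "DamageMask":
        return cls(np.zeros(shape, dtype=bool))

    @classmethod
    def from_file(cls, path) -> "DamageMask":
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:
            arr = arr[..., 0]
        return cls(arr != 0)

    def to_file(self, path) -> None:
        import imageio.v3 as iio

        iio.imwrite(path, (self.grid.astype(np.uint8) * 255))

    def downscaled(self, factor: int) -> "DamageMask":
        """Block-reduce by ``factor``; a block is a barrier if any pixel is."""
        if factor == 1:
            return self
        H, W = self.grid.shape
        Hc, Wc = -(-H // factor), -(-W // factor)
        padded = np.zeros((Hc * factor, Wc * factor), dtype=bool)
        padded[:H, :W] = self.grid
        return DamageMask(
            padded.reshape(Hc, factor, Wc, factor).any(axis=(1, 3))
        )


@dataclass
class GeodesicDistanceMap:
    """Per-pixel path distances (pixel units); +inf on barrier/unreachable pixels."""

    values: np.ndarray
    seeds: np.ndarray
    metric: GridMetric = field(default_factory=GridMetric)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.values.astype(np.float32))


def _as_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise InvalidInputError("empty point/seed set")
    if pts.shape[1] != 2:
        raise InvalidInputError("points must be (row, col) pairs")
    return pts


def snap_to_free(mask: DamageMask, points) -> np.ndarray:
    """Round points to pixels and move any barrier pixel to the nearest free one.

    Nearest is Euclidean; ties break in row-major scan order.  Returns an
    ``(n, 2)`` int64 array.
    """
    mask.require_free()
    pts = _as_points(points)
    H, W = mask.shape
    pix = np.rint(pts).astype(np.int64)
    if (pix[:, 0] < 0).any() or (pix[:, 0] >= H).any() or (
        pix[:, 1] < 0
    ).any() or (pix[:, 1] >= W).any():
        raise InvalidInputError("point outside the mask grid")
    on_barrier = mask.grid[pix[:, 0], pix[:, 1]]
    if on_barrier.any():
        free = np.argwhere(~mask.grid)  # row-major order -> argmin tie-break
        bad = np.nonzero(on_barrier)[0]
        for chunk in np.array_split(bad, max(1, bad.size // 64)):
            d2 = (free[None, :, 0] - pix[chunk, None, 0]) ** 2 + (
                free[None, :, 1] - pix[chunk, None, 1]
            ) ** 2
            pix[chunk] = free[np.argmin(d2, axis=1)]
    return pix


def wavefront_distance(
    mask: DamageMask,
    seeds: Sequence,
    metric: GridMetric | None = None,
) -> GeodesicDistanceMap:
    """Exact multi-source shortest-path distance map by wavefront expansion.

    Barrier pixels are excluded from the grid graph; their distance (and the
    distance of pixels with no barrier-free path to any seed) is +inf.  Seeds
    lying on barrier pixels are snapped to the nearest free pixel first.
    """
    metric = metric or GridMetric()
    mask.require_free()
    pix = snap_to_free(mask, seeds)
    H, W = mask.shape
    off_dr, off_dc, off_w = metric.offsets()
    flat = (pix[:, 0] * W + pix[:, 1]).astype(np.int64)
    dist = wavefront(mask.grid, flat, off_dr, off_dc, off_w)
    return GeodesicDistanceMap(dist.reshape(H, W), seeds=pix, metric=metric)


def k_order_distances(
    mask: DamageMask,
    points: Sequence,
    K: int,
    metric: GridMetric | None = None,
) -> np.ndarray:
    """All order statistics 1..K' of per-point geodesic distances, K' = min(K, n).

    Returns a ``(K', H, W)`` array: plane ``j`` is the distance to the
    (j+1)-th nearest point of the set.  Coincident points count as distinct
    sample points.
    """
    metric = metric or GridMetric()
    mask.require_free()
    if K < 1:
        raise InvalidInputError("K must be >= 1")
    pix = snap_to_free(mask, points)
    Keff = min(K, len(pix))
    H, W = mask.shape
    off_dr, off_dc, off_w = metric.offsets()
    flat = (pix[:, 0] * W + pix[:, 1]).astype(np.int64)
    res = k_nearest(mask.grid, flat, Keff, off_dr, off_dc, off_w)
    return res.T.reshape(Keff, H, W).copy()


def kth_nearest_distance(
    mask: DamageMask,
    points: Sequence,
    K: int,
    metric: GridMetric | None = None,
) -> GeodesicDistanceMap:
    """Per-pixel geodesic distance to the K-th nearest member of ``points``.

    The effective K is ``min(K, len(points))``; the value is +inf wherever
    fewer than that many points are geodesically reachable.
    """
    metric = metric or GridMetric()
    orders = k_order_distances(mask, points, K, metric)
    pix = snap_to_free(mask, points)
    return GeodesicDistanceMap(orders[-1], seeds=pix, metric=metric)
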
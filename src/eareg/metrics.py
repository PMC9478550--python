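"""Evaluation measures for matching and registration quality.

* correct-match rate — a pair is correct when the mapped moving keypoint
  lands strictly within 3 px of its reference keypoint;
* Area% — fraction of the section covered by 35-px disks around match
  points after rescaling the shorter image side to 1,000 px (a uniformity
  measure: higher means the matches constrain more of the section);
* patchwise NCC — zero-lag normalized cross-correlation over non-overlapping
  64 x 64 patches of registered vs reference image;
* endpoint error — per-pixel Euclidean deviation of an estimated deformation
  field from a ground-truth field (synthetic scenes only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import InvalidInputError

__all__ = [
    "MatchEvaluation",
    "NCCReport",
    "EndpointErrorReport",
    "correct_match_stats",
    "area_coverage",
    "patch_ncc",
    "endpoint_error",
]


@dataclass
class MatchEvaluation:
    """Counts and coverage of a match set against ground truth."""

    match_num: int
    inlier_num: int
    inlier_pct: float
    area_pct: float | None = None

    def as_dict(self) -> dict:
        return {
            "match_num": self.match_num,
            "inlier_num": self.inlier_num,
            "inlier_pct": self.inlier_pct,
            "area_pct": self.area_pct,
        }


@dataclass
class NCCReport:
    """Per-patch NCC raster with summary statistics over valid patches."""

    values: np.ndarray  # (rows, cols) patch grid, NCC in [-1, 1]
    valid: np.ndarray  # False where either patch had zero variance
    mean: float
    std: float

    def as_dict(self) -> dict:
        return {
            "ncc_mean": self.mean,
            "ncc_std": self.std,
            "n_patches": int(self.valid.size),
            "n_valid": int(self.valid.sum()),
        }


@dataclass
class EndpointErrorReport:
    median: float
    mean: float
    p95: float
    raster: np.ndarray  # per-pixel error, NaN on excluded pixels

    def as_dict(self) -> dict:
        return {
            "epe_median": self.median,
            "epe_mean": self.mean,
            "epe_p95": self.p95,
        }


def _truth_map(truth, points: np.ndarray) -> np.ndarray:
    """Map (row, col) points through a truth field (2, H, W) or 2x3 affine."""
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    truth = np.asarray(truth, dtype=np.float64)
    if truth.ndim == 3 and truth.shape[0] == 2:
        return np.stack(
            [
                ndimage.map_coordinates(truth[0], pts.T, order=1, mode="nearest"),
                ndimage.map_coordinates(truth[1], pts.T, order=1, mode="nearest"),
            ],
            axis=1,
        )
    if truth.shape == (2, 3):
        return pts @ truth[:, :2].T + truth[:, 2]
    raise InvalidInputError("truth must be a (2, H, W) field or a 2x3 affine")


def correct_match_stats(matches, truth, radius_px: float = 3.0) -> MatchEvaluation:
    """Count matches whose mapped error is strictly below ``radius_px``."""
    mapped = _truth_map(truth, matches.moving_pos)
    err = np.linalg.norm(mapped - matches.reference_pos, axis=1)
    correct = err < radius_px  # strict: an error of exactly 3 px is not correct
    n, c = len(matches), int(correct.sum())
    return MatchEvaluation(
        match_num=n,
        inlier_num=c,
        inlier_pct=100.0 * c / n if n else 0.0,
    )


def area_coverage(
    points,
    image_shape: tuple[int, int],
    radius_px: float = 35.0,
    normalize_short_side_to: int = 1000,
) -> float:
    """Percent of the section within ``radius_px`` of any point.

    The image grid and the points are first rescaled so the shorter side is
    ``normalize_short_side_to`` pixels (aspect preserved).  Coverage counts
    each pixel whose center lies within the radius of at least one point —
    overlapping disks are counted once.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    H, W = image_shape
    scale = normalize_short_side_to / min(H, W)
    Hs, Ws = int(round(H * scale)), int(round(W * scale))
    if len(points) == 0:
        return 0.0
    tree = cKDTree(points * scale)
    covered = 0
    rows = np.arange(Hs, dtype=np.float64)
    cols = np.arange(Ws, dtype=np.float64)
    chunk = max(1, 2_000_000 // max(Ws, 1))
    for lo in range(0, Hs, chunk):
        rr, cc = np.meshgrid(rows[lo : lo + chunk], cols, indexing="ij")
        centers = np.column_stack([rr.ravel(), cc.ravel()])
        d, _ = tree.query(centers, k=1, distance_upper_bound=radius_px + 1e-9)
        covered += int((d <= radius_px).sum())
    return 100.0 * covered / (Hs * Ws)


def patch_ncc(
    registered: np.ndarray,
    reference: np.ndarray,
    patch: int = 64,
    valid_mask: np.ndarray | None = None,
) -> NCCReport:
    """Zero-lag NCC over non-overlapping patches; trailing partials dropped.

    Patches where either image has zero variance are recorded as 0 and
    excluded from the mean/std (flagged in ``valid``).  If ``valid_mask`` is
    given (True = pixel carries registered content), patches containing any
    invalid pixel are excluded the same way: NCC is meaningless where the
    warp had no source data.
    """
    a = np.asarray(registered, dtype=np.float64)
    b = np.asarray(reference, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidInputError(f"shape mismatch {a.shape} vs {b.shape}")
    H, W = a.shape
    pr, pc = H // patch, W // patch
    if pr == 0 or pc == 0:
        raise InvalidInputError("image smaller than one patch")
    a = a[: pr * patch, : pc * patch].reshape(pr, patch, pc, patch)
    b = b[: pr * patch, : pc * patch].reshape(pr, patch, pc, patch)
    am = a.mean(axis=(1, 3), keepdims=True)
    bm = b.mean(axis=(1, 3), keepdims=True)
    az, bz = a - am, b - bm
    cov = (az * bz).sum(axis=(1, 3))
    sa = np.sqrt((az**2).sum(axis=(1, 3)))
    sb = np.sqrt((bz**2).sum(axis=(1, 3)))
    valid = (sa > 0) & (sb > 0)
    if valid_mask is not None:
        vm = np.asarray(valid_mask, dtype=bool)
        if vm.shape != (H, W):
            raise InvalidInputError("valid_mask shape mismatch")
        vm = vm[: pr * patch, : pc * patch].reshape(pr, patch, pc, patch)
        valid &= vm.all(axis=(1, 3))
    ncc = np.zeros((pr, pc))
    ncc[valid] = cov[valid] / (sa[valid] * sb[valid])
    vals = ncc[valid]
    return NCCReport(
        values=ncc,
        valid=valid,
        mean=float(vals.mean()) if vals.size else 0.0,
        std=float(vals.std()) if vals.size else 0.0,
    )


def ncc_heatmap_png(report: NCCReport, path, vmin: float = 0.0, vmax: float = 1.0) -> None:
    """Write the per-patch NCC raster as a color-mapped PNG (viridis scale).

    Invalid patches are shown blank.  Requires matplotlib (the ``plot``
    extra).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.where(report.valid, report.values, np.nan)
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(vals, cmap="viridis", vmin=vmin, vmax=vmax)
    fig.colorbar(im, ax=ax, label="patch NCC")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def endpoint_error(
    field, truth_field: np.ndarray, exclusion_mask: np.ndarray | None = None
) -> EndpointErrorReport:
    """Per-pixel Euclidean distance between estimated and true mapped coordinates.

    ``field`` may be an ExpectedAffineField or a (2, H, W) coordinate map;
    pixels where ``exclusion_mask`` is True (e.g. the dilated damage zone)
    are excluded from the summaries and NaN in the raster.
    """
    u = field.coordinate_map() if hasattr(field, "coordinate_map") else np.asarray(field)
    truth_field = np.asarray(truth_field, dtype=np.float64)
    if u.shape != truth_field.shape:
        raise InvalidInputError("field and truth grids differ")
    err = np.hypot(u[0] - truth_field[0], u[1] - truth_field[1])
    if exclusion_mask is not None:
        err = np.where(exclusion_mask, np.nan, err)
    vals = err[np.isfinite(err)]
    return EndpointErrorReport(
        median=float(np.median(vals)),
        mean=float(vals.mean()),
        p95=float(np.percentile(vals, 95)),
        raster=err,
    )
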
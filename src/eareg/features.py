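"""Keypoint extraction, descriptors, and mutual nearest-neighbor matching.

Keypoints are extracted per grid patch (default 10 x 10 patches, up to 50
keypoints each above a confidence threshold of 0.015) so that matches cover
the whole section rather than clumping on high-contrast regions; an even
spatial distribution is what lets the downstream clustering estimate a local
affine on *every* side of the damage.

The extractor is a pluggable backend: any callable mapping a grayscale image
to ``(positions, scores, descriptors)``.  The default backend is a
self-contained classical detector (Shi-Tomasi corner response, score
normalized to [0, 1]) with a 16 x 16 normalized intensity-patch descriptor
(length 256), so no pretrained weights are needed.  A learned extractor can be
dropped in by registering another backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage.feature import corner_shi_tomasi, peak_local_max

from .errors import ConfigurationError, InvalidInputError

__all__ = [
    "Keypoint",
    "KeypointSet",
    "MatchSet",
    "ClassicalBackend",
    "register_backend",
    "resolve_backend",
    "equalize_histogram",
    "extract_keypoints_gridded",
    "mutual_nn_match",
]


def equalize_histogram(image: np.ndarray) -> np.ndarray:
    """Global histogram equalization to an 8-bit image.

    Classic integer CDF remap: level v maps to
    ``round((cdf(v) - cdf_min) / (n_pixels - cdf_min) * 255)``.  Deterministic
    and monotone; a constant image maps to a constant image.  Accepts any
    integer bit depth (floats in [0, 1] are quantized to 16 bits first).
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise InvalidInputError("equalize_histogram expects a single-channel image")
    if np.issubdtype(image.dtype, np.floating):
        image = np.clip(image, 0.0, 1.0)
        image = (image * 65535.0 + 0.5).astype(np.uint16)
    elif not np.issubdtype(image.dtype, np.integer):
        raise InvalidInputError(f"unsupported image dtype {image.dtype}")
    flat = image.ravel().astype(np.int64)
    flat = flat - flat.min()
    counts = np.bincount(flat)
    cdf = np.cumsum(counts)
    cdf_min = cdf[np.nonzero(counts)[0][0]]
    n = flat.size
    if n == cdf_min:  # single gray level: rescale it to 8 bits, keep it constant
        vmax = float(np.iinfo(image.dtype).max)
        level = np.uint8(np.round(float(image.ravel()[0]) / vmax * 255.0))
        return np.full(image.shape, level, dtype=np.uint8)
    lut = np.round((cdf - cdf_min) / (n - cdf_min) * 255.0).astype(np.uint8)
    return lut[flat].reshape(image.shape)


@dataclass(frozen=True)
class Keypoint:
    """A detected interest point with its confidence and descriptor."""

    position: tuple[float, float]  # (row, col), sub-pixel allowed
    score: float
    descriptor: np.ndarray


class KeypointSet:
    """Column-oriented container of keypoints (positions, scores, descriptors)."""

    def __init__(self, positions, scores, descriptors):
        self.positions = np.asarray(positions, dtype=np.float64).reshape(-1, 2)
        self.scores = np.asarray(scores, dtype=np.float64).reshape(-1)
        self.descriptors = np.asarray(descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2 and len(self) > 0:
            raise InvalidInputError("descriptors must be a 2-D array")
        if len(self.scores) != len(self.positions) or (
            len(self) > 0 and self.descriptors.shape[0] != len(self)
        ):
            raise InvalidInputError("keypoint arrays must have equal length")

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> Keypoint:
        return Keypoint(
            tuple(self.positions[i]), float(self.scores[i]), self.descriptors[i]
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    @property
    def descriptor_size(self) -> int:
        return self.descriptors.shape[1] if len(self) else 0

    @classmethod
    def empty(cls, descriptor_size: int = 256) -> "KeypointSet":
        return cls(
            np.empty((0, 2)), np.empty(0), np.empty((0, descriptor_size))
        )


class ClassicalBackend:
    """Shi-Tomasi corners + normalized 16 x 16 intensity-patch descriptors.

    Corner scores are divided by the image-wide maximum response so they lie
    in [0, 1] and the default 0.015 confidence threshold is meaningful.
    Detection is at integer pixel positions; descriptors are mean-subtracted,
    L2-normalized raw patches (length 256) — not rotation invariant, which is
    adequate for section-to-section registration where rotations are small.
    """

    descriptor_size = 256
    patch = 16

    def __init__(self, sigma: float = 1.5, min_distance: int = 3):
        self.sigma = sigma
        self.min_distance = min_distance

    def __call__(self, image: np.ndarray):
        img = np.asarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise InvalidInputError("backend expects a single-channel image")
        if img.max() > 1.0:
            img = img / max(np.iinfo(image.dtype).max if np.issubdtype(
                image.dtype, np.integer) else img.max(), 1.0)
        response = corner_shi_tomasi(img, sigma=self.sigma)
        rmax = response.max()
        if rmax <= 0:
            return (np.empty((0, 2)), np.empty(0), np.empty((0, self.descriptor_size)))
        response = response / rmax
        peaks = peak_local_max(
            response, min_distance=self.min_distance, threshold_abs=1e-6
        )
        if peaks.size == 0:
            return (np.empty((0, 2)), np.empty(0), np.empty((0, self.descriptor_size)))
        scores = response[peaks[:, 0], peaks[:, 1]]
        descriptors = self._describe(img, peaks)
        return peaks.astype(np.float64), scores, descriptors

    def _describe(self, img: np.ndarray, peaks: np.ndarray) -> np.ndarray:
        half = self.patch // 2
        padded = np.pad(img, half, mode="reflect")
        out = np.empty((len(peaks), self.patch * self.patch))
        for i, (r, c) in enumerate(peaks):
            win = padded[r : r + self.patch, c : c + self.patch].ravel()
            win = win - win.mean()
            norm = np.linalg.norm(win)
            out[i] = win / norm if norm > 0 else win
        return out


_BACKENDS: dict[str, Callable[[], Callable]] = {"classical": ClassicalBackend}


def register_backend(name: str, factory: Callable[[], Callable]) -> None:
    """Register an extractor backend factory under ``name``."""
    _BACKENDS[name] = factory


def resolve_backend(backend) -> Callable:
    if callable(backend):
        return backend
    try:
        return _BACKENDS[backend]()
    except KeyError:
        raise ConfigurationError(
            f"unknown extractor backend {backend!r}; known: {sorted(_BACKENDS)}"
        ) from None


def _patch_index(coord: np.ndarray, size: int, cells: int) -> np.ndarray:
    # remainder pixels belong to the last row/column of patches
    step = max(size // cells, 1)
    return np.minimum((coord // step).astype(np.int64), cells - 1)


def extract_keypoints_gridded(
    image: np.ndarray,
    grid: tuple[int, int] = (10, 10),
    max_per_patch: int = 50,
    confidence_threshold: float = 0.015,
    backend="classical",
) -> KeypointSet:
    """Extract keypoints evenly over a patch grid.

    The image is divided into ``grid`` near-equal patches; each patch keeps at
    most ``max_per_patch`` keypoints with score >= ``confidence_threshold``,
    in descending score order.  The output ordering (patches row-major, then
    by rank) is independent of patch processing order.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("empty image")
    extractor = resolve_backend(backend)
    positions, scores, descriptors = extractor(image)
    positions = np.asarray(positions, dtype=np.float64).reshape(-1, 2)
    scores = np.asarray(scores, dtype=np.float64).reshape(-1)
    descriptors = np.asarray(descriptors, dtype=np.float64)
    keep = scores >= confidence_threshold
    positions, scores, descriptors = positions[keep], scores[keep], descriptors[keep]
    if len(positions) == 0:
        dsize = descriptors.shape[1] if descriptors.ndim == 2 and descriptors.shape[1] else 256
        return KeypointSet.empty(dsize)

    H, W = image.shape
    rows, cols = grid
    pr = _patch_index(positions[:, 0], H, rows)
    pc = _patch_index(positions[:, 1], W, cols)
    patch_id = pr * cols + pc
    # stable sort: patch, then -score, then row-major position for ties
    order = np.lexsort((positions[:, 1], positions[:, 0], -scores, patch_id))
    patch_sorted = patch_id[order]
    rank = np.arange(len(order)) - np.searchsorted(
        patch_sorted, patch_sorted, side="left"
    )
    keep = order[rank < max_per_patch]
    return KeypointSet(positions[keep], scores[keep], descriptors[keep])


@dataclass
class MatchSet:
    """Mutual nearest-neighbor keypoint correspondences (moving <-> reference)."""

    moving_pos: np.ndarray  # (n, 2) (row, col) in the moving image
    reference_pos: np.ndarray  # (n, 2) in the reference image
    distance: np.ndarray  # (n,) descriptor Euclidean distance
    moving_shape: tuple[int, int] = (0, 0)
    reference_shape: tuple[int, int] = (0, 0)
    moving_index: np.ndarray = field(default=None)
    reference_index: np.ndarray = field(default=None)

    def __post_init__(self):
        self.moving_pos = np.asarray(self.moving_pos, dtype=np.float64).reshape(-1, 2)
        self.reference_pos = np.asarray(self.reference_pos, dtype=np.float64).reshape(-1, 2)
        self.distance = np.asarray(self.distance, dtype=np.float64).reshape(-1)
        if self.moving_index is None:
            self.moving_index = np.arange(len(self.moving_pos))
        if self.reference_index is None:
            self.reference_index = np.arange(len(self.reference_pos))

    def __len__(self) -> int:
        return self.moving_pos.shape[0]

    def to_text(self, path) -> None:
        header = (
            "# eareg match file\n"
            f"# moving_shape {self.moving_shape[0]} {self.moving_shape[1]}\n"
            f"# reference_shape {self.reference_shape[0]} {self.reference_shape[1]}\n"
            "# moving_row moving_col ref_row ref_col distance\n"
        )
        body = np.column_stack(
            [self.moving_pos, self.reference_pos, self.distance]
        )
        with open(path, "w") as fh:
            fh.write(header)
            for row in body:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_text(cls, path) -> "MatchSet":
        mshape = rshape = (0, 0)
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    parts = line[1:].split()
                    if parts[:1] == ["moving_shape"]:
                        mshape = (int(parts[1]), int(parts[2]))
                    elif parts[:1] == ["reference_shape"]:
                        rshape = (int(parts[1]), int(parts[2]))
                    continue
                if line:
                    rows.append([float(v) for v in line.split()])
        arr = np.asarray(rows, dtype=np.float64).reshape(-1, 5)
        return cls(arr[:, :2], arr[:, 2:4], arr[:, 4], mshape, rshape)


def mutual_nn_match(
    moving_kps: KeypointSet, reference_kps: KeypointSet
) -> MatchSet:
    """Mutual nearest-neighbor matching in descriptor space.

    A pair (a, b) is kept iff b is a's nearest reference descriptor and a is
    b's nearest moving descriptor (Euclidean distance; argmin ties break to
    the lower index).  Swapping the inputs yields the same pairs with roles
    exchanged.
    """
    if len(moving_kps) == 0 or len(reference_kps) == 0:
        raise InvalidInputError("both keypoint sets must be non-empty")
    if moving_kps.descriptor_size != reference_kps.descriptor_size:
        raise InvalidInputError(
            "descriptor length mismatch: "
            f"{moving_kps.descriptor_size} vs {reference_kps.descriptor_size}"
        )
    a = moving_kps.descriptors
    b = reference_kps.descriptors
    d2 = (
        np.sum(a**2, axis=1)[:, None]
        + np.sum(b**2, axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )
    np.maximum(d2, 0.0, out=d2)
    fwd = np.argmin(d2, axis=1)
    bwd = np.argmin(d2, axis=0)
    idx_m = np.nonzero(bwd[fwd] == np.arange(len(a)))[0]
    idx_r = fwd[idx_m]
    return MatchSet(
        moving_pos=moving_kps.positions[idx_m],
        reference_pos=reference_kps.positions[idx_r],
        distance=np.sqrt(d2[idx_m, idx_r]),
        moving_shape=(0, 0),
        reference_shape=(0, 0),
        moving_index=idx_m,
        reference_index=idx_r,
    )
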
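"""Clustering of matches in the moving frame and robust per-cluster affines.

A single global transform cannot describe a damaged section: tissue on the
two sides of a crack or fold moves differently.  Matches are therefore
clustered by K-means on the moving-frame keypoint coordinates, with the
barrier-avoiding path distance as the metric, so keypoints on opposite sides
of the damage line land in different clusters even when they are close in
Euclidean terms.  Each cluster is then fit with a 2-D affine by RANSAC;
clusters with too few inliers are discarded.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.measure import ransac as _sk_ransac
from skimage.transform import AffineTransform as _SkAffine

from .errors import InvalidInputError, RegistrationFailureError
from .features import MatchSet
from .geodesics import DamageMask, GridMetric, snap_to_free, wavefront_distance

__all__ = [
    "AffineTransform",
    "Cluster",
    "ClusterSet",
    "path_kmeans",
    "fit_cluster_affines",
    "fit_affine_lstsq",
]


@dataclass
class AffineTransform:
    """2-D affine map ``x -> A x + t`` in (row, col) coordinates, moving -> reference."""

    matrix: np.ndarray  # 2x3, [A | t]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64).reshape(2, 3)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:, :2]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 2]

    @property
    def determinant(self) -> float:
        return float(np.linalg.det(self.linear))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2)
        return pts @ self.linear.T + self.translation

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.linear)
        return AffineTransform(
            np.column_stack([Ainv, -Ainv @ self.translation])
        )


def fit_affine_lstsq(src: np.ndarray, dst: np.ndarray) -> AffineTransform:
    """Least-squares affine ``src -> dst`` from >= 3 non-collinear point pairs."""
    src = np.asarray(src, dtype=np.float64).reshape(-1, 2)
    dst = np.asarray(dst, dtype=np.float64).reshape(-1, 2)
    if len(src) < 3:
        raise InvalidInputError("need at least 3 point pairs for an affine fit")
    design = np.column_stack([src, np.ones(len(src))])
    coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
    return AffineTransform(coef.T)  # coef is 3x2: [A^T; t]


@dataclass
class Cluster:
    """A group of matches with (after RANSAC) inlier flags and a fitted affine."""

    member_indices: np.ndarray  # indices into the MatchSet
    moving_pts: np.ndarray  # (m, 2) moving-frame coordinates
    reference_pts: np.ndarray  # (m, 2) reference-frame coordinates
    centroid: np.ndarray  # (row, col), moving frame, non-barrier pixel
    inlier_flags: np.ndarray | None = None
    affine: AffineTransform | None = None

    def __len__(self) -> int:
        return len(self.member_indices)

    @property
    def n_inliers(self) -> int:
        return 0 if self.inlier_flags is None else int(self.inlier_flags.sum())

    @property
    def inlier_moving_pts(self) -> np.ndarray:
        if self.inlier_flags is None:
            return self.moving_pts
        return self.moving_pts[self.inlier_flags]


@dataclass
class ClusterSet:
    """Retained clusters c_1..c_r, each with a fitted affine."""

    clusters: list[Cluster]
    k_requested: int
    matches: MatchSet | None = None
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def n_total_inliers(self) -> int:
        return sum(c.n_inliers for c in self.clusters)

    @property
    def affines(self) -> np.ndarray:
        """Stacked (r, 2, 3) affine matrices."""
        return np.stack([c.affine.matrix for c in self.clusters])

    def to_json(self, path) -> None:
        doc = {
            "k_requested": self.k_requested,
            "seed": self.seed,
            "clusters": [
                {
                    "affine": [float(v) for v in c.affine.matrix.ravel()],
                    "centroid": [float(v) for v in c.centroid],
                    "member_indices": [int(i) for i in c.member_indices],
                    "inlier_flags": [bool(b) for b in c.inlier_flags],
                }
                for c in self.clusters
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


def _distance_at(mask: DamageMask, centroid, metric: GridMetric, pix: np.ndarray):
    dmap = wavefront_distance(mask, [centroid], metric).values
    return dmap[pix[:, 0], pix[:, 1]]


def path_kmeans(
    matches: MatchSet,
    mask: DamageMask,
    k: int = 20,
    metric: GridMetric | None = None,
    max_iter: int = 30,
    seed: int = 0,
) -> list[Cluster]:
    """K-means on moving-frame keypoint coordinates under the geodesic metric.

    Lloyd iteration: assignment uses one wavefront distance map per centroid,
    evaluated at the (pixel-snapped) match coordinates; the centroid update is
    the arithmetic mean of member coordinates snapped to the nearest
    non-barrier pixel, and is kept only if it does not increase the cluster's
    assignment cost, so the objective (sum of member-to-centroid geodesic
    distances) is non-increasing.  Empty clusters are reseeded to the match
    geodesically farthest from its centroid.  Initialization is
    k-means++-style on geodesic distances, driven by ``seed``.
    """
    metric = metric or GridMetric()
    n = len(matches)
    if n == 0:
        raise InvalidInputError("no matches to cluster")
    pix = snap_to_free(mask, matches.moving_pos)
    n_unique = len(np.unique(pix, axis=0))
    if n_unique < k:
        warnings.warn(
            f"only {n_unique} distinct match pixels; reducing k from {k}",
            stacklevel=2,
        )
        k = n_unique
    rng = np.random.default_rng(seed)

    # --- k-means++ style seeding under the geodesic metric
    centroids = [pix[rng.integers(n)]]
    best = _distance_at(mask, centroids[0], metric, pix)
    while len(centroids) < k:
        unreachable = ~np.isfinite(best)
        if unreachable.any():
            cand = int(rng.choice(np.nonzero(unreachable)[0]))
        else:
            w = best**2
            total = w.sum()
            if total <= 0:
                remaining = np.unique(pix, axis=0)
                taken = {tuple(c) for c in centroids}
                fresh = [p for p in remaining if tuple(p) not in taken]
                if not fresh:
                    break
                cand_pix = fresh[int(rng.integers(len(fresh)))]
                centroids.append(np.asarray(cand_pix))
                best = np.minimum(best, _distance_at(mask, cand_pix, metric, pix))
                continue
            cand = int(rng.choice(n, p=w / total))
        centroids.append(pix[cand])
        best = np.minimum(best, _distance_at(mask, centroids[-1], metric, pix))
    k = len(centroids)
    centroids = np.asarray(centroids)

    assign = np.full(n, -1, dtype=np.int64)
    dist_to_centroid = np.full((k, n), np.inf)
    cost = np.full(k, np.inf)  # per-cluster assignment cost under current centroid
    for _ in range(max_iter):
        for i in range(k):
            dist_to_centroid[i] = _distance_at(mask, centroids[i], metric, pix)
        new_assign = np.argmin(dist_to_centroid, axis=0)
        # reseed empty clusters to the geodesically farthest match
        member_dist = dist_to_centroid[new_assign, np.arange(n)]
        for i in range(k):
            if not (new_assign == i).any():
                finite = np.where(np.isfinite(member_dist), member_dist, -1.0)
                far = int(np.argmax(finite))
                centroids[i] = pix[far]
                dist_to_centroid[i] = _distance_at(mask, centroids[i], metric, pix)
                new_assign = np.argmin(dist_to_centroid, axis=0)
                member_dist = dist_to_centroid[new_assign, np.arange(n)]
        if (new_assign == assign).all():
            break
        assign = new_assign
        # guarded centroid update: mean snapped to a free pixel, kept only if
        # it does not increase the cluster's cost
        for i in range(k):
            members = assign == i
            d_cur = dist_to_centroid[i][members]
            cost[i] = d_cur[np.isfinite(d_cur)].sum()
            mean = matches.moving_pos[members].mean(axis=0)
            cand = snap_to_free(mask, [mean])[0]
            if (cand == centroids[i]).all():
                continue
            d_new = _distance_at(mask, cand, metric, pix[members])
            new_cost = d_new[np.isfinite(d_new)].sum()
            n_new_fin = np.isfinite(d_new).sum()
            n_cur_fin = np.isfinite(d_cur).sum()
            if n_new_fin > n_cur_fin or (
                n_new_fin == n_cur_fin and new_cost <= cost[i]
            ):
                centroids[i] = cand
                cost[i] = new_cost

    clusters = []
    for i in range(k):
        members = np.nonzero(assign == i)[0]
        if members.size == 0:
            continue
        clusters.append(
            Cluster(
                member_indices=members,
                moving_pts=matches.moving_pos[members],
                reference_pts=matches.reference_pos[members],
                centroid=centroids[i].astype(np.float64),
            )
        )
    return clusters


def _ransac_affine(src, dst, threshold, max_trials, rng):
    def model_valid(model, *data):
        m = model.params
        return bool(np.all(np.isfinite(m)) and abs(np.linalg.det(m[:2, :2])) > 1e-8)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate minimal samples are expected
        model, inliers = _sk_ransac(
            (src, dst),
            _SkAffine,
            min_samples=3,
            residual_threshold=threshold,
            max_trials=max_trials,
            is_model_valid=model_valid,
            rng=rng,
        )
    return model, inliers


def fit_cluster_affines(
    clusters: Sequence[Cluster],
    ransac_threshold_px: float = 3.0,
    min_inliers: int = 8,
    max_trials: int = 1000,
    seed: int = 0,
) -> ClusterSet:
    """RANSAC one affine per cluster; discard clusters with too few inliers.

    The residual is the Euclidean reprojection error in the reference frame;
    the final affine is refit by least squares on the consensus set.  Raises
    :class:`RegistrationFailureError` if no cluster survives.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(max(len(clusters), 1))
    retained: list[Cluster] = []
    for cl, cs in zip(clusters, child_seeds):
        if len(cl) < max(3, min_inliers):
            continue
        src, dst = cl.moving_pts, cl.reference_pts
        centered = src - src.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
            continue  # collinear: no well-posed affine
        model, inliers = _ransac_affine(
            src, dst, ransac_threshold_px, max_trials, np.random.default_rng(cs)
        )
        if model is None or inliers is None or inliers.sum() < min_inliers:
            continue
        inliers = np.asarray(inliers, dtype=bool)
        affine = fit_affine_lstsq(src[inliers], dst[inliers])
        if abs(affine.determinant) < 1e-8:
            continue
        cl.inlier_flags = inliers
        cl.affine = affine
        retained.append(cl)
    if not retained:
        raise RegistrationFailureError(
            "local-affine", "no cluster retained a valid affine "
            f"(min_inliers={min_inliers})"
        )
    return ClusterSet(clusters=retained, k_requested=len(clusters), seed=seed)
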
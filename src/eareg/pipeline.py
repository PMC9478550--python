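"""End-to-end expected-affine registration of one damaged/reference pair.

Stage order: histogram equalization -> gridded keypoint extraction on both
sections -> mutual nearest-neighbor matching -> path-distance K-means in the
moving frame -> per-cluster RANSAC affines -> geodesic KNN densities ->
posteriors -> dense expected-affine field -> warp of the moving image onto
the reference grid.  All randomness derives from a single seed and every
stage count is echoed into the run log.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

from .config import RegistrationConfig
from .errors import RegistrationFailureError
from .expected_field import (
    DensityField,
    ExpectedAffineField,
    PosteriorField,
    expected_affine_field,
    knn_density,
    posterior,
    warp_moving,
)
from .features import (
    KeypointSet,
    MatchSet,
    equalize_histogram,
    extract_keypoints_gridded,
    mutual_nn_match,
)
from .geodesics import DamageMask, GridMetric
from .local_affine import (
    AffineTransform,
    ClusterSet,
    fit_affine_lstsq,
    fit_cluster_affines,
    path_kmeans,
)

__all__ = ["RegistrationResult", "register_pair", "fit_global_affine"]


@dataclass
class RegistrationResult:
    """All intermediate and final artifacts of one registration run."""

    registered: np.ndarray
    valid: np.ndarray
    field: ExpectedAffineField
    posteriors: PosteriorField
    densities: DensityField
    clusters: ClusterSet
    matches: MatchSet
    moving_keypoints: KeypointSet
    reference_keypoints: KeypointSet
    mask: DamageMask
    config: RegistrationConfig
    log: dict = _dc_field(default_factory=dict)


def _derive_seeds(seed: int) -> tuple[int, int]:
    ss = np.random.SeedSequence(seed)
    a, b = ss.spawn(2)
    return (
        int(a.generate_state(1)[0] % (2**31)),
        int(b.generate_state(1)[0] % (2**31)),
    )


def register_pair(
    moving: np.ndarray,
    reference: np.ndarray,
    mask: DamageMask | None = None,
    config: RegistrationConfig | None = None,
    seed: int | None = None,
) -> RegistrationResult:
    """Register a damaged moving section to an intact reference section.

    ``mask`` marks crack/fold pixels in the moving frame (None means no
    damage).  ``seed`` overrides ``config.rng_seed``.  Deterministic: the
    same inputs, config and seed give identical outputs.
    """
    config = config or RegistrationConfig()
    seed = config.rng_seed if seed is None else int(seed)
    kmeans_seed, ransac_seed = _derive_seeds(seed)
    metric = GridMetric(config.connectivity)
    moving = np.asarray(moving)
    if mask is None:
        mask = DamageMask.empty(moving.shape)

    eq_moving = equalize_histogram(moving)
    eq_reference = equalize_histogram(np.asarray(reference))
    kp_moving = extract_keypoints_gridded(
        eq_moving,
        grid=config.grid,
        max_per_patch=config.max_per_patch,
        confidence_threshold=config.confidence_threshold,
        backend=config.backend,
    )
    kp_reference = extract_keypoints_gridded(
        eq_reference,
        grid=config.grid,
        max_per_patch=config.max_per_patch,
        confidence_threshold=config.confidence_threshold,
        backend=config.backend,
    )
    if len(kp_moving) == 0 or len(kp_reference) == 0:
        raise RegistrationFailureError("features", "no keypoints extracted")
    matches = mutual_nn_match(kp_moving, kp_reference)
    matches.moving_shape = tuple(moving.shape)
    matches.reference_shape = tuple(np.asarray(reference).shape)
    if len(matches) < 3:
        raise RegistrationFailureError(
            "matching", f"only {len(matches)} mutual matches"
        )

    raw_clusters = path_kmeans(
        matches,
        mask,
        k=config.k_clusters,
        metric=metric,
        max_iter=config.kmeans_max_iter,
        seed=kmeans_seed,
    )
    clusters = fit_cluster_affines(
        raw_clusters,
        ransac_threshold_px=config.ransac_threshold_px,
        min_inliers=config.min_inliers,
        max_trials=config.ransac_max_trials,
        seed=ransac_seed,
    )
    clusters.matches = matches

    densities = knn_density(
        clusters,
        mask,
        K=config.knn_K,
        metric=metric,
        epsilon_px=config.epsilon_px,
        downscale=config.downscale,
    )
    posteriors = posterior(densities)
    field = expected_affine_field(posteriors, clusters)
    registered, valid = warp_moving(moving, field)

    log = {
        "seed": seed,
        "kmeans_seed": kmeans_seed,
        "ransac_seed": ransac_seed,
        "config": config.as_dict(),
        "n_keypoints_moving": len(kp_moving),
        "n_keypoints_reference": len(kp_reference),
        "n_matches": len(matches),
        "n_clusters_retained": len(clusters),
        "n_total_inliers": clusters.n_total_inliers,
    }
    return RegistrationResult(
        registered=registered,
        valid=valid,
        field=field,
        posteriors=posteriors,
        densities=densities,
        clusters=clusters,
        matches=matches,
        moving_keypoints=kp_moving,
        reference_keypoints=kp_reference,
        mask=mask,
        config=config,
        log=log,
    )


def fit_global_affine(
    matches: MatchSet,
    ransac_threshold_px: float = 3.0,
    max_trials: int = 1000,
    seed: int = 0,
) -> AffineTransform:
    """Single global RANSAC affine over all matches (the baseline the
    expected-affine field generalizes)."""
    from .local_affine import _ransac_affine

    model, inliers = _ransac_affine(
        matches.moving_pos,
        matches.reference_pos,
        ransac_threshold_px,
        max_trials,
        np.random.default_rng(seed),
    )
    if model is None or inliers is None or inliers.sum() < 3:
        raise RegistrationFailureError("global-affine", "RANSAC found no consensus")
    return fit_affine_lstsq(
        matches.moving_pos[inliers], matches.reference_pos[inliers]
    )
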
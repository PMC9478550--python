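"""Pipeline configuration with field-standard defaults.

Defaults follow the published operating point of the method: 10 x 10
extraction patches with up to 50 keypoints each above a 0.015 confidence
threshold, k = 20 K-means clusters, K = 3 density neighbors.  The remaining
knobs (RANSAC threshold, inlier cutoff, grid connectivity, the epsilon clamp
of the density, the geodesic downscale) are declared here so every run can
echo the exact values it used.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .errors import ConfigurationError

__all__ = ["RegistrationConfig"]


@dataclass
class RegistrationConfig:
    grid: tuple[int, int] = (10, 10)
    max_per_patch: int = 50
    confidence_threshold: float = 0.015
    k_clusters: int = 20
    knn_K: int = 3
    min_inliers: int = 8
    ransac_threshold_px: float = 3.0
    ransac_max_trials: int = 1000
    kmeans_max_iter: int = 30
    connectivity: int = 8
    epsilon_px: float = 0.5
    downscale: int = 1
    rng_seed: int = 0
    backend: str = "classical"

    def __post_init__(self):
        self.grid = tuple(self.grid)
        if len(self.grid) != 2 or min(self.grid) < 1:
            raise ConfigurationError(f"bad patch grid {self.grid}")
        for name in ("max_per_patch", "k_clusters", "knn_K", "min_inliers",
                     "ransac_max_trials", "kmeans_max_iter", "downscale"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("confidence_threshold", "ransac_threshold_px", "epsilon_px"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        return d

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "RegistrationConfig":
        with open(path) as fh:
            doc = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**doc)
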
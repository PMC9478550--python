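"""Synthetic EM-like scenes with ground-truth discontinuous deformation.

A scene is built from a deterministic pseudo-EM texture (band-limited noise
plus dark membrane-like arcs and light mitochondria-like blobs), a damage
line, and one affine per side of the line.  The stored truth field is the
registration map T: moving -> reference; the physical damage displacement at
moving pixel x is x - T(x) (tissue at intact location T(x) ended up at
damaged location x).  Sign conventions follow damage physics:

* fold  — tissue on both sides moved TOWARD the line (overlap; some intact
  tissue has no damaged-frame image and is recorded in a lost-tissue mask);
* crack — tissue on both sides moved AWAY from the line (a gap opens; the
  gap band carries no tissue and is filled with dark debris texture).

The generator covers what the registration pipeline needs to be exercised —
rich texture in every patch cell, a genuine discontinuity confined to the
mask, exactly-affine truth away from the blend zone — and deliberately not
photorealism (no staining artifacts, charging, or knife marks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InvalidSceneError
from .geodesics import DamageMask
from .local_affine import AffineTransform

__all__ = [
    "SyntheticScene",
    "generate_texture",
    "make_damaged_pair",
    "scene_from_spec",
    "rotation_affine",
    "benchmark_crack_scene",
]


def generate_texture(shape: tuple[int, int] = (256, 256), seed: int = 0) -> np.ndarray:
    """Deterministic pseudo-EM texture in [0, 1] with gradients everywhere.

    Band-limited Gaussian noise provides dense texture in every grid patch;
    scattered dark elliptical arcs emulate membranes and light filled disks
    emulate mitochondria-sized organelles.
    """
    H, W = shape
    if H < 64 or W < 64:
        raise ConfigurationError("texture shape must be at least 64 x 64")
    rng = np.random.default_rng(seed)
    base = ndimage.gaussian_filter(rng.standard_normal((H, W)), 1.5)
    base = 0.5 + 0.22 * base / base.std()

    n_arcs = max(12, H * W // 3000)
    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    for _ in range(n_arcs):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        a, b = rng.uniform(8, 30), rng.uniform(5, 18)
        th = rng.uniform(0, np.pi)
        ry = (yy - cy) * np.cos(th) + (xx - cx) * np.sin(th)
        rx = -(yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        rad = (ry / a) ** 2 + (rx / b) ** 2
        ring = np.abs(rad - 1.0) < 0.15
        base[ring] *= rng.uniform(0.35, 0.6)
    n_blobs = max(8, H * W // 5000)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        r = rng.uniform(2, 6)
        blob = (yy - cy) ** 2 + (xx - cx) ** 2 < r * r
        base[blob] = np.minimum(base[blob] * rng.uniform(1.3, 1.6) + 0.1, 1.0)
    base = ndimage.gaussian_filter(base, 0.6)
    return np.clip(base, 0.0, 1.0)


@dataclass
class SyntheticScene:
    """An image pair with ground-truth deformation, damage mask, and metadata."""

    reference: np.ndarray  # intact section, float in [0, 1]
    moving: np.ndarray  # damaged section, float in [0, 1]
    mask: DamageMask  # damage band, moving frame
    truth_field: np.ndarray  # (2, H, W) moving -> reference coordinate map
    params: dict
    lost_tissue: np.ndarray | None = None  # reference-frame pixels with no image

    @property
    def shape(self) -> tuple[int, int]:
        return self.reference.shape

    def truth_at(self, points: np.ndarray) -> np.ndarray:
        """Bilinear sample of the truth map at (row, col) points."""
        pts = np.asarray(points, dtype=np.float64).reshape(-1, 2).T
        return np.stack(
            [
                ndimage.map_coordinates(self.truth_field[0], pts, order=1, mode="nearest"),
                ndimage.map_coordinates(self.truth_field[1], pts, order=1, mode="nearest"),
            ],
            axis=1,
        )

    def save(self, out_dir) -> None:
        import imageio.v3 as iio
        import tifffile

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        iio.imwrite(out / "reference.png",
                    np.clip(self.reference * 255, 0, 255).astype(np.uint8))
        iio.imwrite(out / "moving.png",
                    np.clip(self.moving * 255, 0, 255).astype(np.uint8))
        self.mask.to_file(out / "mask.png")
        tifffile.imwrite(out / "truth_field.tif",
                         self.truth_field.astype(np.float32))
        (out / "scene.json").write_text(json.dumps(self.params, indent=1))

    @classmethod
    def load(cls, in_dir) -> "SyntheticScene":
        import imageio.v3 as iio
        import tifffile

        d = Path(in_dir)
        return cls(
            reference=iio.imread(d / "reference.png").astype(np.float64) / 255.0,
            moving=iio.imread(d / "moving.png").astype(np.float64) / 255.0,
            mask=DamageMask.from_file(d / "mask.png"),
            truth_field=tifffile.imread(d / "truth_field.tif").astype(np.float64),
            params=json.loads((d / "scene.json").read_text()),
        )


def _line_frame(line):
    p0 = np.asarray(line[0], dtype=np.float64)
    p1 = np.asarray(line[1], dtype=np.float64)
    t = p1 - p0
    length = np.linalg.norm(t)
    if length == 0:
        raise ConfigurationError("damage line endpoints coincide")
    t = t / length
    nrm = np.array([-t[1], t[0]])  # 90-degree rotation of the tangent
    return p0, p1, t, nrm, length


def _signed_coords(shape, line):
    p0, p1, t, nrm, length = _line_frame(line)
    yy, xx = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    dr, dc = yy - p0[0], xx - p0[1]
    s = dr * nrm[0] + dc * nrm[1]  # signed distance to the supporting line
    a = dr * t[0] + dc * t[1]  # along-line coordinate
    return s, a, length, nrm


def _smoothstep(t):
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def make_damaged_pair(
    texture: np.ndarray,
    line,
    side_affines: tuple[AffineTransform, AffineTransform],
    kind: str = "crack",
    blend_width: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    endpoint_radius: float = 40.0,
) -> SyntheticScene:
    """Build a damaged moving image from an intact texture and side affines.

    ``side_affines = (A_left, A_right)`` are moving -> reference maps applied
    to the s < 0 and s >= 0 sides of the line (s = signed distance).  The
    truth field is exactly the side affine away from the line and, inside the
    ``blend_width`` zone, a smoothstep interpolation of the two.  If the line
    segment ends inside the image, the field relaxes to the even mixture over
    ``endpoint_radius`` beyond the endpoint, modeling partial damage.  The
    mask is the line dilated to width max(2, normal jump implied by the
    affines).  Raises :class:`InvalidSceneError` if tissue just outside the
    mask band would originate from across the line.
    """
    if kind not in ("fold", "crack"):
        raise ConfigurationError(f"unknown damage kind {kind!r}")
    texture = np.asarray(texture, dtype=np.float64)
    H, W = texture.shape
    rng = np.random.default_rng(seed)
    A_left, A_right = side_affines
    s, a, length, nrm = _signed_coords((H, W), line)

    # weight of the right-side affine
    if blend_width > 0:
        w = _smoothstep((s + blend_width) / (2.0 * blend_width))
    else:
        w = (s >= 0).astype(np.float64)
    # partial damage: relax toward the even mixture beyond the segment ends
    overshoot = np.maximum(np.maximum(-a, a - length), 0.0)
    if overshoot.max() > 0 and endpoint_radius > 0:
        relax = 1.0 - _smoothstep(overshoot / endpoint_radius)
        w = 0.5 + (w - 0.5) * relax

    yy, xx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    def _apply(Aff):
        m = Aff.matrix
        return (
            m[0, 0] * yy + m[0, 1] * xx + m[0, 2],
            m[1, 0] * yy + m[1, 1] * xx + m[1, 2],
        )

    lr, lc = _apply(A_left)
    rr_, rc = _apply(A_right)
    Tr = (1.0 - w) * lr + w * rr_
    Tc = (1.0 - w) * lc + w * rc
    truth = np.stack([Tr, Tc])

    # normal jump of the damage displacement across the line, per station
    p0, p1, tvec, nrm_v, _ = _line_frame(line)
    stations = [p0 + f * length * tvec for f in (0.2, 0.35, 0.5, 0.65, 0.8)]
    jumps = []
    for st in stations:
        probes = np.array([st + 3.0 * nrm_v, st - 3.0 * nrm_v])
        disp = probes - np.stack([A.apply(p)[0] for A, p in
                                  zip((A_right, A_left), probes)])
        jumps.append(float((disp[0] - disp[1]) @ nrm_v))  # >0: moved apart
    jump = jumps[len(jumps) // 2]
    max_jump = max(abs(j) for j in jumps)
    width = max(2.0, max_jump)

    band = (np.abs(s) <= width / 2.0) & (a >= -width / 2.0) & (a <= length + width / 2.0)

    # consistency: tissue just outside the band on the two sides must not have
    # crossed each other in the intact section
    margin = width / 2.0 + 1.5
    for st in stations:
        p_r = st + margin * nrm_v
        p_l = st - margin * nrm_v
        if not all(0 <= p[0] < H and 0 <= p[1] < W for p in (p_r, p_l)):
            continue
        s_r = float((A_right.apply(p_r)[0] - p0) @ nrm_v)
        s_l = float((A_left.apply(p_l)[0] - p0) @ nrm_v)
        if s_r < s_l - 1e-6:
            raise InvalidSceneError(
                "side affines map tissue across the damage line beyond the "
                "mask width"
            )

    moving = ndimage.map_coordinates(texture, truth, order=1, mode="nearest")
    damaged = max_jump > 0.5  # equal side affines leave the section intact
    if damaged and kind == "crack":
        # the gap carries no tissue: dark debris fill
        moving[band] = 0.04 + 0.05 * rng.random(int(band.sum()))
    elif damaged:
        # folded-over tissue absorbs more: darken the band
        moving[band] *= 0.45

    lost = None
    if damaged and kind == "fold":
        covered = np.zeros((H, W), dtype=bool)
        pr = np.clip(np.rint(Tr[~band]).astype(int), 0, H - 1)
        pc = np.clip(np.rint(Tc[~band]).astype(int), 0, W - 1)
        covered[pr, pc] = True
        covered = ndimage.binary_dilation(covered, iterations=2)
        maxdisp = float(np.hypot(Tr - yy, Tc - xx).max())
        m = int(np.ceil(maxdisp)) + 3
        interior = np.zeros((H, W), dtype=bool)
        interior[m:-m, m:-m] = True
        lost = ~covered & interior

    reference = texture.copy()
    if noise_sigma > 0:
        reference = reference + rng.normal(0.0, noise_sigma, (H, W))
        moving = moving + rng.normal(0.0, noise_sigma, (H, W))
    reference = np.clip(reference, 0.0, 1.0)
    moving = np.clip(moving, 0.0, 1.0)

    params = {
        "kind": kind,
        "shape": [H, W],
        "line": [list(map(float, line[0])), list(map(float, line[1]))],
        "A_left": [float(v) for v in A_left.matrix.ravel()],
        "A_right": [float(v) for v in A_right.matrix.ravel()],
        "blend_width": float(blend_width),
        "noise_sigma": float(noise_sigma),
        "seed": int(seed),
        "mask_width": float(width),
        "normal_jump": jump,
        "max_normal_jump": max_jump,
    }
    return SyntheticScene(
        reference=reference,
        moving=moving,
        mask=DamageMask(band),
        truth_field=truth,
        params=params,
        lost_tissue=lost,
    )


def _normal_translation_affines(line, kind: str, magnitude: float):
    """Side affines for pure +/- normal translations with the kind's sign.

    The *damage* moved tissue away from (crack) or toward (fold) the line, so
    the moving -> reference truth map translates each side back by the same
    amount: crack sides map toward the line, fold sides map away from it.
    """
    _, _, _, nrm, _ = _line_frame(line)
    sign = -1.0 if kind == "crack" else +1.0  # registration direction
    shift = sign * magnitude * nrm
    A_right = AffineTransform(np.column_stack([np.eye(2), shift]))
    A_left = AffineTransform(np.column_stack([np.eye(2), -shift]))
    return A_left, A_right


def rotation_affine(theta_deg: float, center, translation=(0.0, 0.0)) -> AffineTransform:
    """Rotation by ``theta_deg`` about ``center`` plus a translation, (row, col)."""
    th = np.deg2rad(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    c = np.asarray(center, dtype=np.float64)
    t = c - R @ c + np.asarray(translation, dtype=np.float64)
    return AffineTransform(np.column_stack([R, t]))


def benchmark_crack_scene(
    seed: int,
    shape: tuple[int, int] = (256, 256),
    magnitude: float = 5.0,
    rotation_deg: float = 2.0,
) -> SyntheticScene:
    """A seeded crack scene with genuinely distinct side transforms.

    The damage opens a gap of ``2 * magnitude`` px (10 px at the default) and
    additionally rotates the two sides by opposite ``rotation_deg`` about the
    section center, as a physically broken section does — the relative
    displacement across the line is at least the gap and no single affine can
    fit both sides.  The line is near-vertical with a seed-dependent column
    and tilt; the texture is seeded independently of the damage.
    """
    H, W = shape
    rng = np.random.default_rng(seed)
    col = rng.uniform(0.42, 0.58) * W
    line = [[-5.0, col + rng.uniform(-10.0, 10.0)], [H + 5.0, col]]
    p0 = np.asarray(line[0])
    p1 = np.asarray(line[1])
    t = (p1 - p0) / np.linalg.norm(p1 - p0)
    nrm = np.array([-t[1], t[0]])
    # registration map (moving -> reference) pulls each side back toward the
    # line and undoes its rotation
    A_right = rotation_affine(+rotation_deg, (H / 2, W / 2), -magnitude * nrm)
    A_left = rotation_affine(-rotation_deg, (H / 2, W / 2), +magnitude * nrm)
    texture = generate_texture(shape, seed=seed)
    return make_damaged_pair(
        texture, line, (A_left, A_right), kind="crack", seed=seed + 1
    )


def scene_from_spec(spec: dict) -> SyntheticScene:
    """Build a scene from a flat JSON-able descriptor (the CLI entry point).

    Keys: ``kind`` (fold|crack), ``shape``, ``seed``, ``line`` (two points;
    default a full-height diagonal-ish line), ``magnitude`` (normal
    displacement per side, px) or explicit ``A_left``/``A_right`` (6 numbers,
    row-major), ``blend_width``, ``noise_sigma``.
    """
    spec = dict(spec)
    kind = spec.get("kind")
    if kind not in ("fold", "crack"):
        raise ConfigurationError(f"unknown scene kind {kind!r}")
    shape = tuple(spec.get("shape", (256, 256)))
    seed = int(spec.get("seed", 0))
    H, W = shape
    line = spec.get("line") or [[-5.0, W * 0.55], [H + 5.0, W * 0.45]]
    if "A_left" in spec or "A_right" in spec:
        if not ("A_left" in spec and "A_right" in spec):
            raise ConfigurationError("A_left and A_right must be given together")
        side = (
            AffineTransform(np.asarray(spec["A_left"]).reshape(2, 3)),
            AffineTransform(np.asarray(spec["A_right"]).reshape(2, 3)),
        )
    else:
        side = _normal_translation_affines(line, kind, float(spec.get("magnitude", 5.0)))
    texture = generate_texture(shape, seed=seed)
    return make_damaged_pair(
        texture,
        line,
        side,
        kind=kind,
        blend_width=float(spec.get("blend_width", 0.0)),
        noise_sigma=float(spec.get("noise_sigma", 0.0)),
        seed=seed + 1,
    )
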
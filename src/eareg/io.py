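"""Image, mask, field, and report I/O for the command-line pipeline."""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .errors import InvalidInputError

__all__ = ["read_image", "write_image", "read_mask_file", "write_json"]


def read_image(path) -> np.ndarray:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a 2-D array."""
    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such image file: {p}")
    arr = iio.imread(p)
    if arr.ndim == 3:
        if arr.shape[2] not in (1, 3, 4):
            raise InvalidInputError(f"unsupported channel layout {arr.shape}")
        arr = arr[..., 0] if arr.shape[2] == 1 else np.round(
            arr[..., :3].mean(axis=2)
        ).astype(arr.dtype)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D image, got shape {arr.shape}")
    return arr


def write_image(path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), image)


def read_mask_file(path):
    from .geodesics import DamageMask

    p = Path(path)
    if not p.exists():
        raise InvalidInputError(f"no such mask file: {p}")
    return DamageMask.from_file(p)


def write_json(path, doc: dict) -> None:
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")
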
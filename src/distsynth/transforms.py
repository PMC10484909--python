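"""Random geometric transforms applied identically to a mask and its image.

Used in two places: augmenting input masks when building a synthetic
database, and (optionally) augmenting each center's (mask, image) pairs
during adversarial training — which both enlarges the effective dataset and
suppresses per-sample memorization.  Masks use nearest-neighbor
interpolation and background fill; images use linear interpolation and zero
fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import affine_transform

__all__ = ["TransformSpec", "apply_transform", "apply_transform_image"]


@dataclass
class TransformSpec:
    scale_range: tuple = (0.9, 1.1)
    shift_frac: float = 0.1          # max |shift| as a fraction of the side
    flip_h: float = 0.5              # probability
    flip_v: float = 0.0
    rotation_deg: float = 10.0       # max |rotation|
    enabled: bool = True

    def draw(self, rng: np.random.Generator, size: int) -> dict:
        if not self.enabled:
            return {"scale": 1.0, "shift": (0.0, 0.0), "flip_h": False,
                    "flip_v": False, "rot": 0.0}
        return {
            "scale": float(rng.uniform(*self.scale_range)),
            "shift": tuple(rng.uniform(-self.shift_frac, self.shift_frac, 2) * size),
            "flip_h": bool(rng.random() < self.flip_h),
            "flip_v": bool(rng.random() < self.flip_v),
            "rot": float(rng.uniform(-self.rotation_deg, self.rotation_deg)),
        }


def _matrix_offset(shape, params):
    theta = np.deg2rad(params["rot"])
    s = params["scale"]
    c0 = (np.asarray(shape) - 1) / 2.0
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]]) / s
    offset = c0 - rot @ (c0 + np.asarray(params["shift"]))
    return rot, offset


def _is_identity(params) -> bool:
    return (params["rot"] == 0.0 and params["scale"] == 1.0
            and tuple(params["shift"]) == (0.0, 0.0))


def apply_transform(mask: np.ndarray, params: dict) -> np.ndarray:
    """Apply one geometric transform to a label mask (nearest interpolation,
    background fill)."""
    out = mask
    if params["flip_h"]:
        out = out[:, ::-1]
    if params["flip_v"]:
        out = out[::-1, :]
    if _is_identity(params):
        return np.ascontiguousarray(out)
    rot, offset = _matrix_offset(out.shape, params)
    return affine_transform(out, rot, offset=offset, order=0, mode="constant",
                            cval=0, output=out.dtype)


def apply_transform_image(image: np.ndarray, params: dict) -> np.ndarray:
    """Apply the same transform to a (c, H, W) image stack (linear
    interpolation, zero fill)."""
    out = image
    if params["flip_h"]:
        out = out[:, :, ::-1]
    if params["flip_v"]:
        out = out[:, ::-1, :]
    if _is_identity(params):
        return np.ascontiguousarray(out)
    rot, offset = _matrix_offset(out.shape[1:], params)
    return np.stack([affine_transform(ch, rot, offset=offset, order=1,
                                      mode="constant", cval=0.0)
                     for ch in out])
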
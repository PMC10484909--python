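"""Synthetic database generation from a trained generator.

A trained mask-to-image generator becomes a data provider: input masks are
randomly transformed (scale, shift, flip, rotation — nearest-neighbor for
labels), the generator synthesizes images for the transformed masks with
inference-time dropout providing sample diversity, and the manifest records
every transform parameter and seed so a database is reproducible bit-exactly.
This module never touches real images: its inputs are masks and the
generator only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import datagen
from .trainer import generate_images
from .transforms import TransformSpec, apply_transform, apply_transform_image

__all__ = ["TransformSpec", "apply_transform", "apply_transform_image",
           "generate_database", "mix_masks"]


def generate_database(generator, masks: list, transforms: TransformSpec,
                      multiplier: int, seed: int, n_classes: int,
                      out_dir=None) -> tuple[list, np.ndarray, dict]:
    """multiplier x len(masks) synthetic (mask, image) pairs.

    Returns (transformed masks, synthetic images in [0,1], manifest).  When
    ``out_dir`` is given the pairs and manifest are also written in the same
    layout as a phantom center dataset.
    """
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    if generator.spec.in_channels != n_classes + 1:
        raise ValueError("generator was trained for a different class count")
    rng = np.random.default_rng(seed)
    out_masks, entries = [], []
    for rep in range(multiplier):
        for i, m in enumerate(masks):
            params = transforms.draw(rng, m.shape[0])
            out_masks.append(apply_transform(m, params))
            entries.append({"id": f"syn_{rep}_{i:04d}", "source_index": i,
                            "transform": params})
    gen_seed = int(rng.integers(0, 2 ** 31))
    images = generate_images(generator, np.stack(out_masks), n_classes,
                             np.random.default_rng(gen_seed))
    manifest = {"multiplier": multiplier, "seed": seed, "generation_seed": gen_seed,
                "transforms": asdict(transforms), "entries": entries}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for e, m, img in zip(entries, out_masks, images):
            np.savez(out / f"{e['id']}.npz", mask=m, image=img)
            e["files"] = {"archive": f"{e['id']}.npz"}
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return out_masks, images, manifest


def mix_masks(mask_a: np.ndarray, mask_b: np.ndarray,
              foreground_classes) -> np.ndarray:
    """Overlay the listed foreground classes of mask_b onto mask_a (mask_b
    takes precedence where both are foreground)."""
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shapes differ")
    fg = [c for c in foreground_classes]
    missing = [c for c in fg if not np.any(mask_b == c)]
    if missing:
        raise ValueError(f"classes {missing} absent from mask_b")
    out = mask_a.copy()
    sel = np.isin(mask_b, fg)
    out[sel] = mask_b[sel]
    return out
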
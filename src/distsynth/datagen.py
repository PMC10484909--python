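"""Multi-center phantom dataset generator.

Emulates a federation of imaging centers holding paired (label mask,
multi-modality image) data with known ground truth: elliptical structures on
a background, per-(class, modality) base intensities, and per-center
heterogeneity as an affine intensity transform (shift/scale) plus Gaussian
noise.  Because the forward model is analytic, every statistic of the data
(class occupancy, per-class channel means, noise level) can be checked in
closed form, which is what makes the rest of the package testable without
any external dataset.

Masks use 0 = background and classes 1..n_classes; pixel indexing is 0-based
row-major with the origin at the top-left.  Images are generated in [0, 1];
training code maps them to [-1, 1] via :func:`to_tanh_range`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.draw import ellipse as _ellipse

__all__ = [
    "PhantomSpec", "CenterSpec", "TaskSequence", "CenterData",
    "make_mask", "render_modalities", "make_center_data",
    "build_center_dataset", "load_center_dataset", "regenerate_center_dataset",
    "sample_seed", "to_tanh_range", "from_tanh_range", "mask_to_onehot",
]

_MASK64 = (1 << 64) - 1


def _splitmix64(z: int) -> int:
    z = (z + 0x9E3779B97F4A7C15) & _MASK64
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
    return z ^ (z >> 31)


def sample_seed(center_seed: int, index: int) -> int:
    """Per-sample seed from (center seed, sample index) via splitmix64 mixing,
    so centers are independent deterministic streams.  Kept below 2**31."""
    return _splitmix64(_splitmix64(center_seed & _MASK64) ^ (index + 1)) % (2 ** 31)


# ---------------------------------------------------------------------------
# Specs

@dataclass
class PhantomSpec:
    image_size: int = 32
    n_classes: int = 2
    # intensity_table[class, modality], class 0 = background; values in [0, 1]
    intensity_table: tuple = ((0.1,), (0.45,), (0.75,))
    noise_sd: float = 0.03
    smoothing_sigma: float = 0.0
    # per-class (min_axis, max_axis) as a fraction of image_size
    shape_params: tuple = ((0.15, 0.35), (0.08, 0.2))

    def __post_init__(self):
        table = np.asarray(self.intensity_table, dtype=float)
        if self.image_size < 8:
            raise ValueError("image_size must be >= 8")
        if self.n_classes < 0:
            raise ValueError("n_classes must be >= 0")
        if table.ndim != 2 or table.shape[0] != self.n_classes + 1:
            raise ValueError("intensity_table needs one row per class incl. background")
        if np.any(table < 0) or np.any(table > 1):
            raise ValueError("intensity_table values must lie in [0, 1]")
        if self.noise_sd < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_sd and smoothing_sigma must be >= 0")
        if self.n_classes and len(self.shape_params) != self.n_classes:
            raise ValueError("shape_params needs one (min, max) pair per class")

    @property
    def n_modalities(self) -> int:
        return len(self.intensity_table[0])

    def table(self) -> np.ndarray:
        return np.asarray(self.intensity_table, dtype=float)


@dataclass
class CenterSpec:
    center_id: str
    n_samples: int
    modalities: tuple = (0,)
    weight: float | None = None          # defaults proportional to n_samples
    intensity_shift: float = 0.0
    intensity_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.modalities:
            raise ValueError("modality set must be non-empty")
        if self.weight is not None and self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class TaskSequence:
    """Ordered (time index, centers active at that time) pairs."""
    tasks: tuple

    def __post_init__(self):
        times = [t for t, _ in self.tasks]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time indices must be strictly increasing")
        ids = [c.center_id for _, cs in self.tasks for c in cs]
        if len(ids) != len(set(ids)):
            raise ValueError("each center may appear in exactly one time slot")


def validate_federation(centers: list[CenterSpec], phantom: PhantomSpec) -> None:
    """Every modality must be available at >= 1 center across the federation."""
    union = set()
    for c in centers:
        if max(c.modalities) >= phantom.n_modalities:
            raise ValueError(f"center {c.center_id}: modality index out of table range")
        union |= set(c.modalities)
    if union != set(range(phantom.n_modalities)):
        missing = set(range(phantom.n_modalities)) - union
        raise ValueError(f"modalities {sorted(missing)} are absent from every center")


# ---------------------------------------------------------------------------
# Generation

def make_mask(spec: PhantomSpec, seed: int) -> np.ndarray:
    """One elliptical structure per foreground class; later classes paint over
    earlier ones, and any class fully occluded is re-painted so that every
    class in 1..n_classes occupies at least one pixel."""
    rng = np.random.default_rng(seed)
    n = spec.image_size
    mask = np.zeros((n, n), dtype=np.int32)
    for cls in range(1, spec.n_classes + 1):
        _paint_ellipse(mask, cls, spec, rng)
    for cls in range(1, spec.n_classes + 1):     # repair full occlusions
        tries = 0
        while not np.any(mask == cls) and tries < 20:
            _paint_ellipse(mask, cls, spec, rng)
            tries += 1
    return mask


def _paint_ellipse(mask: np.ndarray, cls: int, spec: PhantomSpec,
                   rng: np.random.Generator) -> None:
    n = spec.image_size
    lo, hi = spec.shape_params[cls - 1]
    a = max(1.0, rng.uniform(lo, hi) * n)
    b = max(1.0, rng.uniform(lo, hi) * n)
    cy = rng.uniform(0.25 * n, 0.75 * n)
    cx = rng.uniform(0.25 * n, 0.75 * n)
    theta = rng.uniform(0.0, np.pi)
    rr, cc = _ellipse(cy, cx, a, b, shape=mask.shape, rotation=theta)
    mask[rr, cc] = cls


def render_modalities(mask: np.ndarray, spec: PhantomSpec, center: CenterSpec,
                      seed: int) -> np.ndarray:
    """Render the channels for ``center.modalities`` as an array of shape
    (len(C_j), H, W): table lookup x scale + shift + noise, then optional
    blur, clipped to [0, 1].  Channels for absent modalities do not exist."""
    if mask.max(initial=0) > spec.n_classes:
        raise ValueError("mask labels exceed n_classes")
    if max(center.modalities) >= spec.n_modalities:
        raise ValueError("modality index out of table range")
    rng = np.random.default_rng(seed)
    table = spec.table()
    out = np.empty((len(center.modalities), *mask.shape))
    for i, k in enumerate(center.modalities):
        base = table[mask, k] * center.intensity_scale + center.intensity_shift
        if spec.noise_sd > 0:
            base = base + rng.normal(0.0, spec.noise_sd, size=mask.shape)
        if spec.smoothing_sigma > 0:
            base = gaussian_filter(base, spec.smoothing_sigma)
        out[i] = np.clip(base, 0.0, 1.0)
    return out


@dataclass
class CenterData:
    """In-memory dataset for one center: aligned lists of masks and stacks."""
    spec: CenterSpec
    phantom: PhantomSpec
    masks: list                 # (H, W) int arrays
    images: list                # (len(C_j), H, W) float arrays in [0, 1]
    sample_seeds: list

    def __len__(self):
        return len(self.masks)


def make_center_data(center: CenterSpec, phantom: PhantomSpec) -> CenterData:
    masks, images, seeds = [], [], []
    for i in range(center.n_samples):
        s = sample_seed(center.seed, i)
        m = make_mask(phantom, s)
        y = render_modalities(m, phantom, center, s + 1)
        masks.append(m)
        images.append(y)
        seeds.append(s)
    return CenterData(center, phantom, masks, images, seeds)


# ---------------------------------------------------------------------------
# On-disk layout: indexed-PNG masks, 8-bit PNG per modality, NPZ lossless
# archive, and a manifest.json tying them together.

_PALETTE = [0, 0, 0, 230, 60, 60, 60, 160, 230, 240, 200, 60, 130, 220, 90,
            180, 100, 200, 220, 220, 220]


def _write_indexed_png(path: Path, mask: np.ndarray) -> None:
    img = Image.fromarray(mask.astype(np.uint8), mode="P")
    img.putpalette(_PALETTE + [0] * (768 - len(_PALETTE)))
    img.save(path)


def build_center_dataset(center: CenterSpec, phantom: PhantomSpec, out_dir) -> dict:
    """Write n_samples (mask, stack) pairs plus a manifest; returns the
    manifest dict.  Regenerating from the manifest is bit-exact."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = make_center_data(center, phantom)
    entries = []
    for i, (m, y, s) in enumerate(zip(data.masks, data.images, data.sample_seeds)):
        sid = f"{center.center_id}_{i:04d}"
        files = {"mask": f"{sid}_mask.png", "archive": f"{sid}.npz"}
        _write_indexed_png(out / files["mask"], m)
        for ci, k in enumerate(center.modalities):
            fname = f"{sid}_mod{k}.png"
            Image.fromarray(np.round(255.0 * y[ci]).astype(np.uint8)).save(out / fname)
            files[f"mod{k}"] = fname
        np.savez(out / files["archive"], mask=m, image=y,
                 modalities=np.asarray(center.modalities))
        entries.append({"id": sid, "seed": int(s), "files": files})
    manifest = {
        "center_id": center.center_id,
        "n_samples": center.n_samples,
        "modalities": list(center.modalities),
        "center": asdict(center),
        "phantom": asdict(phantom),
        "entries": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def load_center_dataset(manifest_path) -> CenterData:
    """Load the lossless archives listed in a manifest."""
    path = Path(manifest_path)
    with open(path) as fh:
        manifest = json.load(fh)
    center = _center_from_dict(manifest["center"])
    phantom = _phantom_from_dict(manifest["phantom"])
    masks, images, seeds = [], [], []
    for e in manifest["entries"]:
        with np.load(path.parent / e["files"]["archive"]) as z:
            masks.append(z["mask"])
            images.append(z["image"])
        seeds.append(e["seed"])
    return CenterData(center, phantom, masks, images, seeds)


def regenerate_center_dataset(manifest_path) -> CenterData:
    """Recompute the dataset from the manifest's specs and seeds alone."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    return make_center_data(_center_from_dict(manifest["center"]),
                            _phantom_from_dict(manifest["phantom"]))


def _center_from_dict(d: dict) -> CenterSpec:
    d = dict(d)
    d["modalities"] = tuple(d["modalities"])
    return CenterSpec(**d)


def _phantom_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    d["intensity_table"] = tuple(tuple(r) for r in d["intensity_table"])
    d["shape_params"] = tuple(tuple(r) for r in d["shape_params"])
    return PhantomSpec(**d)


# ---------------------------------------------------------------------------
# Encoding helpers shared by training code

def to_tanh_range(img: np.ndarray) -> np.ndarray:
    return img * 2.0 - 1.0


def from_tanh_range(img: np.ndarray) -> np.ndarray:
    return np.clip((img + 1.0) / 2.0, 0.0, 1.0)


def mask_to_onehot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """(H, W) int -> (n_classes + 1, H, W) float one-hot."""
    return (np.arange(n_classes + 1)[:, None, None] == mask[None]).astype(float)
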
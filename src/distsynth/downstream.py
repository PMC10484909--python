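"""Downstream segmentation: overlap/boundary/instance metrics and a small
U-Net trainer used to compare real and synthetic training databases.

Metric conventions (the formulas do not pin these down, so they are fixed
here and used consistently):

* boundaries are foreground pixels with at least one background 4-neighbor,
  with the outside of the image treated as background;
* distances are Euclidean between pixel centers;
* the 95th percentile is computed with linear interpolation over the sorted
  directed distances;
* Dice of two empty masks is 1, so a correct prediction of an absent
  structure is not penalized;
* reported standard deviations use divisor n (not n - 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from . import nn

__all__ = [
    "dice", "hd", "hd95", "surface_distance", "aji", "object_dice",
    "boundary", "SegConfig", "UNet", "train_segmenter", "evaluate",
    "SegEvalResult",
]


# ---------------------------------------------------------------------------
# Overlap and boundary metrics

def dice(gt: np.ndarray, seg: np.ndarray) -> float:
    """2|G ∩ S| / (|G| + |S|); both-empty -> 1 by convention."""
    gt = np.asarray(gt, dtype=bool)
    seg = np.asarray(seg, dtype=bool)
    if gt.shape != seg.shape:
        raise ValueError("mask shapes differ")
    denom = gt.sum() + seg.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(gt, seg).sum() / denom)


def boundary(mask: np.ndarray) -> np.ndarray:
    """(k, 2) coordinates of foreground pixels with a background 4-neighbor."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return np.argwhere(m & ~interior)


def _directed_distances(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return cdist(src, dst).min(axis=1)


def _boundary_pair(gt, seg):
    bg, bs = boundary(gt), boundary(seg)
    if len(bg) == 0 or len(bs) == 0:
        raise ValueError("boundary distance undefined for an empty mask")
    return bg, bs


def hd(gt: np.ndarray, seg: np.ndarray) -> float:
    """Hausdorff distance between mask boundaries, in pixels."""
    bg, bs = _boundary_pair(gt, seg)
    return float(max(_directed_distances(bg, bs).max(),
                     _directed_distances(bs, bg).max()))


def hd95(gt: np.ndarray, seg: np.ndarray) -> float:
    """Max of the two directed 95th-percentile boundary distances."""
    bg, bs = _boundary_pair(gt, seg)
    return float(max(np.percentile(_directed_distances(bg, bs), 95),
                     np.percentile(_directed_distances(bs, bg), 95)))


def surface_distance(gt: np.ndarray, seg: np.ndarray) -> float:
    """Symmetric mean of the directed boundary distances."""
    bg, bs = _boundary_pair(gt, seg)
    return float(0.5 * (_directed_distances(bg, bs).mean()
                        + _directed_distances(bs, bg).mean()))


# ---------------------------------------------------------------------------
# Instance metrics

def _objects(labelled: np.ndarray) -> dict[int, np.ndarray]:
    labelled = np.asarray(labelled)
    return {int(l): labelled == l for l in np.unique(labelled) if l != 0}


def aji(gt_instances: np.ndarray, seg_instances: np.ndarray) -> float:
    """Aggregated Jaccard Index over instance label maps (background 0).

    Ground-truth objects are processed in ascending label order; each greedily
    consumes the unused segmented object with maximal Jaccard (ties to the
    lower segmented label).  Unconsumed segmented objects are penalized in
    the denominator.  Empty maps give 0 by convention.
    """
    gt_objs = _objects(gt_instances)
    seg_objs = _objects(seg_instances)
    used: set[int] = set()
    inter_sum = 0
    union_sum = 0
    for gl in sorted(gt_objs):
        g = gt_objs[gl]
        best_j, best_label = 0.0, None
        for sl in sorted(seg_objs):
            if sl in used:
                continue
            inter = np.logical_and(g, seg_objs[sl]).sum()
            if inter == 0:
                continue
            j = inter / np.logical_or(g, seg_objs[sl]).sum()
            if j > best_j:
                best_j, best_label = j, sl
        if best_label is None:
            union_sum += int(g.sum())
        else:
            s = seg_objs[best_label]
            inter_sum += int(np.logical_and(g, s).sum())
            union_sum += int(np.logical_or(g, s).sum())
            used.add(best_label)
    for sl, s in seg_objs.items():          # unmatched set O
        if sl not in used:
            union_sum += int(s.sum())
    if union_sum == 0:
        return 0.0
    return float(inter_sum / union_sum)


def object_dice(gt_instances: np.ndarray, seg_instances: np.ndarray) -> float:
    """Object-level Dice: size-weighted Dice of each object against its
    maximum-overlap partner, symmetrized over the two maps."""
    gt_objs = _objects(gt_instances)
    seg_objs = _objects(seg_instances)
    if not gt_objs and not seg_objs:
        return 1.0
    if not gt_objs or not seg_objs:
        return 0.0

    def _half(a_objs, b_objs):
        total = sum(o.sum() for o in a_objs.values())
        acc = 0.0
        for o in a_objs.values():
            best = max(b_objs.values(),
                       key=lambda b: np.logical_and(o, b).sum())
            acc += (o.sum() / total) * dice(o, best)
        return acc

    return float(0.5 * (_half(gt_objs, seg_objs) + _half(seg_objs, gt_objs)))


# ---------------------------------------------------------------------------
# U-Net segmenter

class _MaxPool2x2(nn.Module):
    def forward(self, x, train=False):
        n, c, h, w = x.shape
        v = x.reshape(n, c, h // 2, 2, w // 2, 2)
        flat = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, c, h2, w2 = dout.shape
        dflat = np.zeros((n, c, h2, w2, 4))
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        v = dflat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return v.reshape(self._shape)


class _ConvBlock(nn.Module):
    def __init__(self, cin, cout, rng):
        self.net = nn.Sequential(
            nn.Conv2d(cin, cout, 3, 1, 1, rng=rng), nn.BatchNorm2d(cout), nn.ReLU(),
            nn.Conv2d(cout, cout, 3, 1, 1, rng=rng), nn.BatchNorm2d(cout), nn.ReLU())

    def params(self):
        return self.net.params()

    def state(self):
        return self.net.state()

    def load_state(self, a):
        self.net.load_state(a)

    def forward(self, x, train=False):
        return self.net.forward(x, train)

    def backward(self, d):
        return self.net.backward(d)


class UNet:
    """Small encoder-decoder with skip connections; logits out (no softmax)."""

    def __init__(self, in_channels: int, n_out: int, width: int = 8,
                 depth: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.depth = depth
        self.enc = []
        self.pools = []
        ch = in_channels
        w = width
        for _ in range(depth):
            self.enc.append(_ConvBlock(ch, w, rng))
            self.pools.append(_MaxPool2x2())
            ch, w = w, w * 2
        self.mid = _ConvBlock(ch, w, rng)
        self.ups = []
        self.dec = []
        for _ in range(depth):
            self.ups.append(nn.ConvTranspose2d(w, w // 2, 3, 2, 1, 1, rng=rng))
            self.dec.append(_ConvBlock(w, w // 2, rng))
            w //= 2
        self.head = nn.Conv2d(w, n_out, 1, 1, 0, rng=rng)

    def _modules(self):
        return self.enc + self.pools + [self.mid] + self.ups + self.dec + [self.head]

    def params(self):
        return [p for m in self._modules() for p in m.params()]

    def state(self):
        return [a for m in self._modules() for a in m.state()]

    def load_state(self, arrays):
        i = 0
        for m in self._modules():
            k = len(m.state())
            m.load_state(arrays[i:i + k])
            i += k

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x, train=False):
        skips = []
        for enc, pool in zip(self.enc, self.pools):
            x = enc.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.mid.forward(x, train)
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            dec._split = skip.shape[1]
            x = dec.forward(x, train)
        return self.head.forward(x, train)

    def backward(self, dout):
        d = self.head.backward(dout)
        dskips = []
        for up, dec in zip(reversed(self.ups), reversed(self.dec)):
            d = dec.backward(d)
            split = dec._split
            dskips.append(d[:, :split])
            d = up.backward(d[:, split:])
        d = self.mid.backward(d)
        # dskips was collected shallow-to-deep; encoders unwind deep-to-shallow
        for enc, pool, dskip in zip(reversed(self.enc), reversed(self.pools),
                                    reversed(dskips)):
            d = pool.backward(d)
            d = enc.backward(d + dskip)
        return d


@dataclass
class SegConfig:
    epochs: int = 40
    batch_size: int = 8
    lr: float = 0.01            # Adam
    width: int = 8
    depth: int = 2
    loss: str = "ce_dice"       # ce_dice | ce | bce
    val_fraction: float = 0.2
    seed: int = 0


def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _seg_loss_and_grad(logits, target_onehot, kind):
    """Returns (loss, dloss/dlogits).  ce_dice adds a soft-Dice term over
    foreground classes to the pixel-mean cross-entropy."""
    if kind == "bce":
        p = 1.0 / (1.0 + np.exp(-logits))
        t = target_onehot
        eps = 1e-8
        loss = float(-np.mean(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))
        return loss, (p - t) / t.size
    p = _softmax(logits)
    t = target_onehot
    npix = t.shape[0] * t.shape[2] * t.shape[3]
    ce = float(-(t * np.log(p + 1e-12)).sum() / npix)
    dlogits = (p - t) / npix
    if kind == "ce":
        return ce, dlogits
    eps = 1.0
    fg = slice(1, None)
    inter = (p[:, fg] * t[:, fg]).sum(axis=(0, 2, 3))
    sums = p[:, fg].sum(axis=(0, 2, 3)) + t[:, fg].sum(axis=(0, 2, 3))
    dice_c = (2 * inter + eps) / (sums + eps)
    k = dice_c.size
    dl_dp = np.zeros_like(p)
    dl_dp[:, fg] = -(2 * t[:, fg] * (sums + eps)[None, :, None, None]
                     - (2 * inter + eps)[None, :, None, None]) \
        / ((sums + eps) ** 2)[None, :, None, None] / k
    ddice = p * (dl_dp - (dl_dp * p).sum(axis=1, keepdims=True))
    return ce + float(1.0 - dice_c.mean()), dlogits + ddice


def _mean_fg_dice(pred_labels, masks):
    vals = []
    for pr, gt in zip(pred_labels, masks):
        classes = np.unique(gt)
        classes = classes[classes != 0]
        if classes.size == 0:
            continue
        vals.append(np.mean([dice(gt == c, pr == c) for c in classes]))
    return float(np.mean(vals)) if vals else 0.0


def train_segmenter(masks: list, images: list, n_classes: int,
                    config: SegConfig) -> tuple[UNet, dict]:
    """Train a U-Net on paired (mask, image) samples.

    A 20% holdout (at least one sample) is split off as the validation set
    and the parameters with the best validation Dice are returned."""
    n = len(masks)
    if n < 5:
        raise ValueError("need at least 5 samples to hold out a validation set")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    x = np.stack(images)
    t = np.stack([(np.arange(n_classes + 1)[:, None, None] == m).astype(float)
                  for m in masks])
    model = UNet(x.shape[1], 1 if config.loss == "bce" else n_classes + 1,
                 config.width, config.depth, seed=config.seed + 1)
    opt = nn.Adam(model.params(), lr=config.lr, beta1=0.9)
    history = {"loss": [], "val_dice": [], "n_train": len(train_idx),
               "n_val": len(val_idx)}
    best = (-1.0, None)
    for _ in range(config.epochs):
        perm = rng.permutation(train_idx)
        ep_loss = 0.0
        n_batches = 0
        for i in range(0, len(perm), config.batch_size):
            bidx = perm[i:i + config.batch_size]
            logits = model.forward(x[bidx], train=True)
            loss, dlogits = _seg_loss_and_grad(logits, t[bidx], config.loss)
            model.zero_grad()
            model.backward(dlogits)
            opt.step()
            model.zero_grad()
            ep_loss += loss
            n_batches += 1
        preds = predict(model, x[val_idx])
        vdice = _mean_fg_dice(preds, [masks[i] for i in val_idx])
        history["loss"].append(ep_loss / max(1, n_batches))
        history["val_dice"].append(vdice)
        if vdice > best[0]:
            best = (vdice, [a.copy() for a in model.state()])
    if best[1] is not None:
        model.load_state(best[1])
    return model, history


def predict(model: UNet, images: np.ndarray, batch: int = 16) -> np.ndarray:
    outs = []
    for i in range(0, len(images), batch):
        logits = model.forward(np.asarray(images[i:i + batch]), train=False)
        outs.append(logits.argmax(axis=1))
    return np.concatenate(outs)


# ---------------------------------------------------------------------------
# Evaluation

@dataclass
class SegEvalResult:
    per_sample: dict            # structure -> {"dice": [...], "hd95": [...], "sd": [...]}
    aggregate: dict             # structure -> {"dice_mean", "dice_sd", ...}
    mean_dice: float


def evaluate(model: UNet, masks: list, images: list, n_classes: int) -> SegEvalResult:
    """Per-sample, per-structure Dice/HD95/SD with mean +/- sd (divisor n).

    Boundary metrics are undefined when either mask is empty for a structure;
    those samples are recorded as NaN and skipped in the aggregates."""
    preds = predict(model, np.stack(images))
    per = {c: {"dice": [], "hd95": [], "sd": []} for c in range(1, n_classes + 1)}
    for pr, gt in zip(preds, masks):
        for c in range(1, n_classes + 1):
            g, s = gt == c, pr == c
            per[c]["dice"].append(dice(g, s))
            if g.any() and s.any():
                per[c]["hd95"].append(hd95(g, s))
                per[c]["sd"].append(surface_distance(g, s))
            else:
                per[c]["hd95"].append(np.nan)
                per[c]["sd"].append(np.nan)
    agg = {}
    for c, d in per.items():
        agg[c] = {}
        for name, vals in d.items():
            v = np.asarray(vals, dtype=float)
            agg[c][f"{name}_mean"] = float(np.nanmean(v)) if np.any(np.isfinite(v)) else np.nan
            agg[c][f"{name}_sd"] = float(np.nanstd(v)) if np.any(np.isfinite(v)) else np.nan
    mean_dice = float(np.mean([agg[c]["dice_mean"] for c in per]))
    return SegEvalResult(per, agg, mean_dice)
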
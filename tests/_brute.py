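"""Exhaustive brute-force segmentation-metric oracles, independent of the
implementations under test (per-pixel Python loops, no vectorization)."""

import numpy as np


def brute_boundary(mask):
    pts = []
    h, w = mask.shape
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nbrs = [(r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)]
            if any(not (0 <= rr < h and 0 <= cc < w) or not mask[rr, cc]
                   for rr, cc in nbrs):
                pts.append((r, c))
    return pts


def brute_directed(a, b):
    return [min(np.hypot(r - r2, c - c2) for r2, c2 in b) for r, c in a]


def brute_hd95(gt, seg):
    bg, bs = brute_boundary(gt), brute_boundary(seg)
    return max(np.percentile(brute_directed(bg, bs), 95),
               np.percentile(brute_directed(bs, bg), 95))


def brute_sd(gt, seg):
    bg, bs = brute_boundary(gt), brute_boundary(seg)
    return 0.5 * (np.mean(brute_directed(bg, bs))
                  + np.mean(brute_directed(bs, bg)))


def brute_dice(gt, seg):
    denom = gt.sum() + seg.sum()
    return 1.0 if denom == 0 else 2 * (gt & seg).sum() / denom


def brute_aji(gt, seg):
    gl = [l for l in np.unique(gt) if l]
    sl = [l for l in np.unique(seg) if l]
    used, inter_s, union_s = set(), 0, 0
    for g in gl:
        gm = gt == g
        best, pick = 0.0, None
        for s in sl:
            if s in used:
                continue
            i = (gm & (seg == s)).sum()
            if i == 0:
                continue
            j = i / (gm | (seg == s)).sum()
            if j > best:
                best, pick = j, s
        if pick is None:
            union_s += gm.sum()
        else:
            sm = seg == pick
            inter_s += (gm & sm).sum()
            union_s += (gm | sm).sum()
            used.add(pick)
    union_s += sum((seg == s).sum() for s in sl if s not in used)
    return 0.0 if union_s == 0 else inter_s / union_s
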
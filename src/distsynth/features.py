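"""Pluggable image feature extractors.

The desk default is a fixed-seed random convolutional pyramid: two stride-2
convolutions with ReLU, followed by per-channel spatial mean and standard
deviation pooling.  Random convolutional features preserve enough image
statistics for Frechet-style distances and perceptual losses at phantom
scale, are fully deterministic, and require no pretrained weights.  An
ImageNet-pretrained extractor can be plugged in through the same interface
(`features(images) -> (n, d)` plus `extractor_id`).
"""

from __future__ import annotations

import numpy as np

from . import nn

__all__ = ["RandomConvExtractor", "IdentityExtractor"]


class IdentityExtractor:
    """Flattened pixels as features; handy for exact hand-checkable tests."""

    def __init__(self):
        self.extractor_id = "identity"

    def features(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        return images.reshape(images.shape[0], -1)

    def features_grad(self, images: np.ndarray, dfeat: np.ndarray) -> np.ndarray:
        return dfeat.reshape(images.shape)


class RandomConvExtractor:
    """Deterministic random-weight convolutional feature extractor.

    Supports backpropagation through :meth:`features_grad`, so it can also
    serve as the perceptual-loss network.
    """

    def __init__(self, in_channels: int, width: int = 16, seed: int = 1234):
        rng = np.random.default_rng(seed)
        self.net = nn.Sequential(
            nn.Conv2d(in_channels, width, 3, 2, 1, rng=rng),
            nn.ReLU(),
            nn.Conv2d(width, 2 * width, 3, 2, 1, rng=rng),
            nn.ReLU(),
        )
        self.in_channels = in_channels
        self.width = width
        self.extractor_id = f"randconv-c{in_channels}-w{width}-s{seed}"

    @property
    def n_features(self) -> int:
        return 4 * self.width

    def _activations(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 3:
            images = images[:, None]
        if images.shape[1] != self.in_channels:
            raise ValueError(
                f"extractor built for {self.in_channels} channels, got {images.shape[1]}")
        return self.net.forward(images, train=False)

    def features(self, images: np.ndarray) -> np.ndarray:
        """(n, c, h, w) or (n, h, w) -> (n, 2 * 2 * width): per-channel
        spatial mean and standard deviation."""
        a = self._activations(images)
        mean = a.mean(axis=(2, 3))
        sd = a.std(axis=(2, 3))
        return np.concatenate([mean, sd], axis=1)

    def features_grad(self, images: np.ndarray, dfeat: np.ndarray) -> np.ndarray:
        """Backpropagate a gradient w.r.t. features to the input images."""
        squeeze = np.asarray(images).ndim == 3
        a = self._activations(images)  # refresh caches
        n, c, h, w = a.shape
        npix = h * w
        dmean = dfeat[:, :c]
        dsd = dfeat[:, c:]
        mean = a.mean(axis=(2, 3), keepdims=True)
        sd = a.std(axis=(2, 3), keepdims=True)
        da = dmean[:, :, None, None] / npix
        centered = a - mean
        safe_sd = np.where(sd > 1e-12, sd, 1.0)
        da = da + dsd[:, :, None, None] * centered / (npix * safe_sd)
        dx = self.net.backward(da)
        return dx[:, 0] if squeeze else dx
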
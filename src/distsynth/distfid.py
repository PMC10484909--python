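"""Frechet distance between feature distributions, and its federated form.

FID between two image sets summarizes each by the mean vector and covariance
matrix of extracted features and evaluates

    ||mu1 - mu2||^2 + Tr(sigma1 + sigma2 - 2 sqrt(sigma1 sigma2)).

In a federation no pooled real dataset exists, so each center transmits its
feature statistics (mu_1^j, sigma_1^j, |S_j|) once; the weighted average of
per-center FIDs against the synthetic set,

    DistFID = sum_j w_j FID_j,   w_j = |S_j| / sum_k |S_k|,

is used to select the best generator checkpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["FeatureStats", "CenterStatsBundle", "compute_stats", "fid",
           "dist_fid", "select_best", "save_stats", "load_stats"]

_STATS_FORMAT_VERSION = 1


@dataclass
class FeatureStats:
    mu: np.ndarray
    sigma: np.ndarray
    n: int
    extractor_id: str

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float).ravel()
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if self.sigma.shape != (self.mu.size, self.mu.size):
            raise ValueError("sigma must be square with mu's dimension")
        if not np.allclose(self.sigma, self.sigma.T, atol=1e-8):
            raise ValueError("sigma must be symmetric")
        if self.n < 2:
            raise ValueError("feature statistics need n >= 2 images")


@dataclass
class CenterStatsBundle:
    """Per-center (id, stats, dataset size) triples with size-derived weights."""
    entries: list   # of (center_id, FeatureStats, n_samples)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty stats bundle")
        ids = {s.extractor_id for _, s, _ in self.entries}
        if len(ids) != 1:
            raise ValueError(f"stats mix extractors: {sorted(ids)}")

    @property
    def weights(self) -> np.ndarray:
        sizes = np.array([n for _, _, n in self.entries], dtype=float)
        return sizes / sizes.sum()


def compute_stats(images: np.ndarray, extractor) -> FeatureStats:
    """Feature mean and covariance (divisor n - 1) of an image set."""
    feats = extractor.features(np.asarray(images))
    if feats.shape[0] < 2:
        raise ValueError("need >= 2 images for a covariance")
    mu = feats.mean(axis=0)
    sigma = np.cov(feats, rowvar=False, ddof=1)
    return FeatureStats(mu, np.atleast_2d(sigma), feats.shape[0], extractor.extractor_id)


def _psd_sqrt(mat: np.ndarray, clip_tol: float = 1e-6) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    if vals.min(initial=0.0) < -clip_tol * max(1.0, abs(vals).max()):
        raise ValueError("matrix is not PSD beyond roundoff tolerance")
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def fid(a: FeatureStats, b: FeatureStats) -> float:
    """Frechet distance between two Gaussian feature fits.

    The cross term Tr sqrt(sigma1 sigma2) is computed through the symmetric
    PSD root: Tr sqrt(s1^(1/2) sigma2 s1^(1/2)), with small negative
    eigenvalues from roundoff clipped to zero.
    """
    if a.mu.size != b.mu.size:
        raise ValueError("feature dimensions differ")
    if a.extractor_id != b.extractor_id:
        raise ValueError("stats come from different extractors")
    diff = a.mu - b.mu
    s1h = _psd_sqrt(a.sigma)
    inner = s1h @ b.sigma @ s1h
    vals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    cross = np.sqrt(np.clip(vals, 0.0, None)).sum()
    val = float(diff @ diff + np.trace(a.sigma) + np.trace(b.sigma) - 2.0 * cross)
    return max(val, 0.0)


def dist_fid(bundle: CenterStatsBundle, synth: FeatureStats) -> float:
    """Size-weighted average of per-center FIDs against the synthetic set."""
    return float(sum(w * fid(stats, synth)
                     for w, (_, stats, _) in zip(bundle.weights, bundle.entries)))


def select_best(history) -> int:
    """Index of the lowest score; ties break to the earliest epoch."""
    history = list(history)
    if not history:
        raise ValueError("empty history")
    return int(np.argmin(history))


# ---------------------------------------------------------------------------
# Persistence (transmitted once, before training)

def save_stats(path, stats: FeatureStats) -> None:
    np.savez(Path(path), version=np.array(_STATS_FORMAT_VERSION), mu=stats.mu,
             sigma=stats.sigma, n=np.array(stats.n),
             extractor_id=np.frombuffer(stats.extractor_id.encode(), dtype=np.uint8))


def load_stats(path) -> FeatureStats:
    with np.load(Path(path)) as z:
        if int(z["version"]) != _STATS_FORMAT_VERSION:
            raise ValueError("unsupported stats file version")
        return FeatureStats(z["mu"], z["sigma"], int(z["n"]),
                            bytes(z["extractor_id"]).decode())
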
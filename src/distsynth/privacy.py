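"""Membership-inference risk harness for a trained generator.

Two attack settings are evaluated.  In the pool setting the attacker holds a
transformation-augmented synthetic database and, for each real image, finds
the closest synthetic image under the min-max-normalized sum of two
similarity metrics — normalized RMSE and perceptual distance (1 - cosine of
feature vectors) — then uses the matched pair's two raw metrics as features.
In the API setting the attacker feeds a real image's mask to the generator
and compares the returned synthetic image directly.  Linear and RBF-kernel
SVMs are trained on labeled member/non-member features and evaluated by
F1/recall/precision/AUC; chance-level AUC means the attack fails.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skm
from sklearn.svm import SVC

from .trainer import generate_images

__all__ = ["SimilarityFeatures", "AttackReport", "nrmse", "perceptual_distance",
           "similarity_features", "paired_similarity", "attack_eval"]


@dataclass
class SimilarityFeatures:
    nrmse: float
    pdist: float
    combined: float | None = None
    matched_id: int | None = None


@dataclass
class AttackReport:
    linear: dict
    rbf: dict
    n_train: int
    n_test: int
    params: dict


def nrmse(real: np.ndarray, synth: np.ndarray) -> float:
    """RMSE divided by the real image's intensity range."""
    real = np.asarray(real, dtype=float)
    synth = np.asarray(synth, dtype=float)
    rng = real.max() - real.min()
    rmse = float(np.sqrt(np.mean((real - synth) ** 2)))
    return rmse / rng if rng > 0 else rmse


def perceptual_distance(real: np.ndarray, synth: np.ndarray, extractor) -> float:
    """1 - cosine similarity of extractor features; lies in [0, 2]."""
    fa = extractor.features(real[None]).ravel()
    fb = extractor.features(synth[None]).ravel()
    na, nb = np.linalg.norm(fa), np.linalg.norm(fb)
    if na == 0 or nb == 0:
        return 1.0
    return float(1.0 - fa @ fb / (na * nb))


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    return (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)


def similarity_features(real_image: np.ndarray, synthetic_set: np.ndarray,
                        extractor) -> SimilarityFeatures:
    """Pool-setting features: metrics against every synthetic image, min-max
    normalized and summed to pick the closest match; the matched pair's raw
    metrics are returned."""
    if len(synthetic_set) == 0:
        raise ValueError("empty synthetic set")
    e = np.array([nrmse(real_image, s) for s in synthetic_set])
    p = np.array([perceptual_distance(real_image, s, extractor)
                  for s in synthetic_set])
    combined = _minmax(e) + _minmax(p)
    i = int(np.argmin(combined))
    return SimilarityFeatures(float(e[i]), float(p[i]), float(combined[i]), i)


def paired_similarity(real_image: np.ndarray, mask: np.ndarray, generator,
                      extractor, n_classes: int,
                      rng: np.random.Generator | None = None) -> SimilarityFeatures:
    """API-setting features: the mask goes to the black-box generator and the
    returned synthetic image is compared with the real image directly."""
    synth = generate_images(generator, mask[None], n_classes, rng)[0]
    return SimilarityFeatures(nrmse(real_image, synth),
                              perceptual_distance(real_image, synth, extractor))


def attack_eval(train_features: np.ndarray, train_labels: np.ndarray,
                test_features: np.ndarray, test_labels: np.ndarray,
                seed: int = 0) -> AttackReport:
    """Fit linear and RBF SVMs (C = 1; RBF bandwidth by the median
    heuristic) on membership labels and report test F1/recall/precision/AUC."""
    xtr = np.asarray(train_features, dtype=float)
    xte = np.asarray(test_features, dtype=float)
    ytr = np.asarray(train_labels).astype(int)
    yte = np.asarray(test_labels).astype(int)
    if len(np.unique(ytr)) < 2 or len(np.unique(yte)) < 2:
        raise ValueError("membership labels must contain both classes")
    d2 = ((xtr[:, None, :] - xtr[None, :, :]) ** 2).sum(-1)
    med = np.median(d2[np.triu_indices_from(d2, k=1)])
    gamma = 1.0 / (2.0 * med) if med > 0 else "scale"
    out = {}
    for name, clf in (("linear", SVC(kernel="linear", C=1.0, random_state=seed)),
                      ("rbf", SVC(kernel="rbf", C=1.0, gamma=gamma,
                                  random_state=seed))):
        clf.fit(xtr, ytr)
        pred = clf.predict(xte)
        score = clf.decision_function(xte)
        out[name] = {
            "f1": float(skm.f1_score(yte, pred, zero_division=0)),
            "recall": float(skm.recall_score(yte, pred, zero_division=0)),
            "precision": float(skm.precision_score(yte, pred, zero_division=0)),
            "auc": float(skm.roc_auc_score(yte, score)),
        }
    return AttackReport(out["linear"], out["rbf"], len(ytr), len(yte),
                        {"C": 1.0, "gamma": None if gamma == "scale" else float(gamma),
                         "seed": seed})
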
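"""Adversarial, reconstruction and continual-learning losses, plus the
gradient aggregation rule used by the central generator.

All functions are pure and operate on numpy arrays so each formula can be
unit-tested against hand-computed values.  Score maps are post-sigmoid patch
probabilities in [0, 1]; log arguments are clamped at ``clamp_eps`` so the
losses stay finite at saturation (the only point where the implementation
deviates from the idealized formulas).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LossWeights", "GradientPacket", "discriminator_loss",
    "discriminator_loss_grads", "generator_center_loss",
    "generator_adversarial_grad", "aggregate_gradients",
    "multimodal_generator_loss", "reminding_loss", "reminding_grad",
    "pack_gradient_packet", "unpack_gradient_packet", "l1_loss", "perceptual_loss",
]


@dataclass
class LossWeights:
    lambda1: float = 100.0       # L1 weight
    lambda2: float = 10.0        # perceptual weight
    lambda_reminding: float = 1.0
    batch_size: int = 4
    clamp_eps: float = 1e-8

    def __post_init__(self):
        if min(self.lambda1, self.lambda2, self.lambda_reminding) < 0:
            raise ValueError("loss weights must be >= 0")
        if not (0.0 < self.clamp_eps <= 1e-3):
            raise ValueError("clamp_eps must lie in (0, 1e-3]")


@dataclass
class GradientPacket:
    """What a center returns to the generator: per-sample gradients of its
    local generator loss w.r.t. the synthetic images, plus scalar losses."""
    center_id: str
    grad: np.ndarray             # same shape as the synthetic batch
    losses: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.grad)):
            raise ValueError("gradient packet contains non-finite values")


def _clamp(s: np.ndarray, eps: float) -> np.ndarray:
    return np.clip(s, eps, 1.0 - eps)


# ---------------------------------------------------------------------------
# Discriminator

def discriminator_loss(scores_real: np.ndarray, scores_fake: np.ndarray,
                       clamp_eps: float = 1e-8) -> float:
    """Mean over batch and patches of -log D(y|x) - log(1 - D(yhat|x))."""
    if scores_real.shape != scores_fake.shape:
        raise ValueError("real/fake score map shapes differ")
    sr = _clamp(scores_real, clamp_eps)
    sf = _clamp(scores_fake, clamp_eps)
    return float(np.mean(-np.log(sr)) + np.mean(-np.log(1.0 - sf)))


def discriminator_loss_grads(scores_real, scores_fake, clamp_eps: float = 1e-8):
    """Gradients of :func:`discriminator_loss` w.r.t. the two score maps."""
    sr = _clamp(scores_real, clamp_eps)
    sf = _clamp(scores_fake, clamp_eps)
    d_real = -1.0 / (sr * scores_real.size)
    d_fake = 1.0 / ((1.0 - sf) * scores_fake.size)
    return d_real, d_fake


# ---------------------------------------------------------------------------
# Generator (per-center part)

def l1_loss(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute pixel difference."""
    return float(np.mean(np.abs(y - yhat)))


def perceptual_loss(y: np.ndarray, yhat: np.ndarray, extractor) -> float:
    """Mean squared distance between extractor features."""
    fy, fyh = extractor.features(y), extractor.features(yhat)
    return float(np.mean((fy - fyh) ** 2))


def generator_center_loss(scores_fake: np.ndarray, y: np.ndarray,
                          yhat: np.ndarray, w: LossWeights,
                          extractor=None) -> tuple[float, dict]:
    """Per-center generator loss: mean log(1 - D(yhat)) plus weighted L1 and
    perceptual terms.  Returns (total, per-term breakdown)."""
    if y.shape != yhat.shape:
        raise ValueError("real/synthetic shapes differ")
    if w.lambda2 > 0 and extractor is None:
        raise ValueError("perceptual weight > 0 requires a feature extractor")
    sf = _clamp(scores_fake, w.clamp_eps)
    adv = float(np.mean(np.log(1.0 - sf)))
    terms = {"adversarial": adv, "l1": l1_loss(y, yhat)}
    terms["perceptual"] = perceptual_loss(y, yhat, extractor) if w.lambda2 > 0 else 0.0
    total = adv + w.lambda1 * terms["l1"] + w.lambda2 * terms["perceptual"]
    return float(total), terms


def generator_adversarial_grad(scores_fake: np.ndarray,
                               clamp_eps: float = 1e-8) -> np.ndarray:
    """d/d(score) of mean log(1 - D(yhat))."""
    sf = _clamp(scores_fake, clamp_eps)
    return -1.0 / ((1.0 - sf) * scores_fake.size)


def l1_grad(y: np.ndarray, yhat: np.ndarray) -> np.ndarray:
    return np.sign(yhat - y) / y.size


# ---------------------------------------------------------------------------
# Aggregation at the central generator

def aggregate_gradients(packets: list[GradientPacket], weights, N: int | None = None,
                        strict_prefactor: bool = True) -> np.ndarray:
    """Weighted aggregation of per-center gradients:

        (1 / (N * sum(pi))) * sum_j pi_j * grad_j

    ``strict_prefactor`` keeps the printed 1/N factor; with it off the
    aggregation is the plain pi-weighted average 1/sum(pi).  Centers absent
    from ``packets`` contribute nothing.
    """
    if not packets:
        raise ValueError("no gradient packets to aggregate")
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(packets):
        raise ValueError("one weight per packet required")
    if np.any(weights < 0) or weights.sum() <= 0:
        raise ValueError("weights must be >= 0 with positive sum")
    shape = packets[0].grad.shape
    if any(p.grad.shape != shape for p in packets):
        raise ValueError("packet gradient shapes differ")
    n = len(packets) if N is None else N
    scale = 1.0 / ((n if strict_prefactor else 1.0) * weights.sum())
    out = np.zeros(shape)
    for w_j, p in zip(weights, packets):
        out += w_j * p.grad
    return scale * out


# ---------------------------------------------------------------------------
# Multi-modality / missing-modality

def multimodal_generator_loss(per_modality: dict, available: set | frozenset,
                              w: LossWeights, extractor=None) -> tuple[float, dict]:
    """Generator loss for one center with modality subset C_j.

    ``per_modality`` maps modality index k -> (scores_fake_k, y_k, yhat_k);
    terms must be supplied exactly for k in C_j and are summed (not averaged)
    over modalities, so the complete-modality case reduces to the
    single-stack form channel-sum convention.
    """
    supplied = set(per_modality)
    if supplied - set(available):
        raise ValueError(f"modalities {sorted(supplied - set(available))} not in C_j")
    if set(available) - supplied:
        raise ValueError(f"missing terms for modalities {sorted(set(available) - supplied)}")
    total = 0.0
    breakdown = {}
    for k in sorted(per_modality):
        t, terms = generator_center_loss(*per_modality[k], w, extractor)
        total += t
        breakdown[k] = terms
    return float(total), breakdown


# ---------------------------------------------------------------------------
# Continual learning

def reminding_loss(g_t_out: np.ndarray, g_prev_out: np.ndarray) -> float:
    """Per-pixel mean squared difference between the current and the frozen
    previous generator on masks from earlier tasks."""
    if g_t_out.shape != g_prev_out.shape:
        raise ValueError("generator output shapes differ")
    return float(np.mean((g_t_out - g_prev_out) ** 2))


def reminding_grad(g_t_out: np.ndarray, g_prev_out: np.ndarray) -> np.ndarray:
    return 2.0 * (g_t_out - g_prev_out) / g_t_out.size


# ---------------------------------------------------------------------------
# Wire format: flat binary array + JSON header

def pack_gradient_packet(p: GradientPacket) -> bytes:
    header = {
        "center_id": p.center_id,
        "shape": list(p.grad.shape),
        "dtype": str(p.grad.dtype),
        "losses": {k: float(v) for k, v in p.losses.items()},
    }
    hb = json.dumps(header).encode()
    return len(hb).to_bytes(4, "little") + hb + np.ascontiguousarray(p.grad).tobytes()


def unpack_gradient_packet(raw: bytes) -> GradientPacket:
    n = int.from_bytes(raw[:4], "little")
    header = json.loads(raw[4:4 + n].decode())
    grad = np.frombuffer(raw[4 + n:], dtype=header["dtype"]).reshape(header["shape"])
    return GradientPacket(header["center_id"], grad.copy(), header["losses"])
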
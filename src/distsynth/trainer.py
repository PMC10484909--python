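"""Distributed adversarial training across simulated centers.

One central generator lives at the server; each center holds its private
real data and one patch discriminator per available modality (or a single
multi-channel discriminator in base mode).  Per round, every center draws a
mask batch from its own data, the server synthesizes images for those masks,
the center updates its discriminator(s) once and returns per-sample
gradients of its local generator loss; the server aggregates the weighted
gradients and takes one Adam step.  Every inter-node payload passes through
an audited channel restricted to {mask, synthetic_image, loss_scalars,
gradient_packet, feature_stats} — real images never leave their center.

Model selection: before training each center transmits its real feature
statistics once; every ``eval_every`` epochs the server synthesizes
``n_eval_samples`` fresh images and records the Dist-FID score, and the
checkpoint with the lowest score is kept.

Continual mode trains on a sequence of center cohorts.  At task t the
generator warm-starts from the previous best model, the cohorts of earlier
tasks (data and discriminators) are gone, and a frozen copy of the previous
generator anchors the update through the reminding loss
L_Digesting + lambda * L_Reminding evaluated on retained masks.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import datagen, losses, nets
from .datagen import (CenterData, PhantomSpec, TaskSequence, mask_to_onehot,
                      to_tanh_range, _splitmix64)
from .distfid import CenterStatsBundle, FeatureStats, compute_stats, dist_fid, select_best
from .features import RandomConvExtractor
from .losses import LossWeights

__all__ = [
    "TrainConfig", "PrivacyError", "Channel", "CenterNode", "MaskSampler",
    "TrainResult", "train", "train_round", "continual_train",
    "train_monolithic", "generate_images", "evaluate_dist_fid",
    "ALLOWED_KINDS",
]

ALLOWED_KINDS = frozenset(
    {"mask", "synthetic_image", "loss_scalars", "gradient_packet", "feature_stats"})


class PrivacyError(RuntimeError):
    """A disallowed payload or a forbidden data access crossed the boundary."""


# ---------------------------------------------------------------------------
# Audited message channel

def payload_hash(payload) -> str:
    if isinstance(payload, np.ndarray):
        raw = np.ascontiguousarray(payload).tobytes()
    elif isinstance(payload, bytes):
        raw = payload
    elif isinstance(payload, dict):
        raw = json.dumps(payload, sort_keys=True, default=float).encode()
    else:
        raw = repr(payload).encode()
    return hashlib.sha256(raw).hexdigest()


class Channel:
    """In-process transport; every message is logged as
    {direction, kind, nbytes, hash} and disallowed kinds abort the run."""

    def __init__(self):
        self.log: list[dict] = []

    def send(self, direction: str, kind: str, payload):
        if kind not in ALLOWED_KINDS:
            raise PrivacyError(f"payload kind {kind!r} is not allowed on the wire")
        if isinstance(payload, np.ndarray):
            nbytes = payload.nbytes
        elif isinstance(payload, bytes):
            nbytes = len(payload)
        else:
            nbytes = len(json.dumps(payload, sort_keys=True, default=float))
        self.log.append({"direction": direction, "kind": kind, "nbytes": int(nbytes),
                         "hash": payload_hash(payload)})
        return payload

    def dump_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.log:
                fh.write(json.dumps(rec) + "\n")


# ---------------------------------------------------------------------------
# Config

@dataclass
class TrainConfig:
    mode: str = "base"                  # base | multimodal | missing | continual
    epochs: int = 200
    rounds_per_epoch: int | None = None  # default: mean center size / batch_size
    batch_size: int = 4
    lr: float = 2e-4
    beta1: float = 0.5
    d_lr: float | None = None            # defaults to lr
    weights: LossWeights = field(default_factory=LossWeights)
    gen_base_width: int = 16
    gen_res_blocks: int = 2
    dropout_rate: float = 0.5
    dropout_at_inference: bool = True
    disc_width: int = 16
    eval_every: int = 1
    n_eval_samples: int = 256
    seed: int = 0
    strict_eq5: bool = True
    single_discriminator: bool = False   # multimodal ablation: one c-channel D
    extractor_seed: int = 1234
    augment: object | None = None        # TransformSpec for train-time pairs

    def __post_init__(self):
        if self.epochs < 1 or self.eval_every < 1:
            raise ValueError("epochs and eval_every must be >= 1")
        if self.mode not in {"base", "multimodal", "missing", "continual"}:
            raise ValueError(f"unknown mode {self.mode!r}")

    def generator_spec(self, n_classes: int, n_modalities: int) -> nets.GeneratorSpec:
        return nets.GeneratorSpec(
            in_channels=n_classes + 1, out_channels=n_modalities,
            base_width=self.gen_base_width, n_residual_blocks=self.gen_res_blocks,
            dropout_rate=self.dropout_rate,
            dropout_active_at_inference=self.dropout_at_inference)


def _derive(seed: int, tag: str, index: int = 0) -> int:
    h = int.from_bytes(hashlib.sha256(tag.encode()).digest()[:8], "little")
    return _splitmix64(_splitmix64(seed ^ h) ^ (index + 1)) % (2 ** 31)


# ---------------------------------------------------------------------------
# Center node

class CenterNode:
    """Holds one center's private data and discriminator(s).

    ``per_modality`` switches between one discriminator per available
    modality (the preferred multi-modality design) and a single
    discriminator over the full local channel stack.
    """

    def __init__(self, data: CenterData, config: TrainConfig, per_modality: bool,
                 pi: float = 1.0):
        self._data = data
        self.spec = data.spec
        self.config = config
        self.pi = pi
        self.per_modality = per_modality
        self.n_classes = data.phantom.n_classes
        mask_ch = self.n_classes + 1
        w = config.weights
        d_lr = config.d_lr if config.d_lr is not None else config.lr
        self.discs: dict = {}
        self.opts: dict = {}
        if per_modality:
            keys = list(self.spec.modalities)
            ch = 1
        else:
            keys = [-1]
            ch = len(self.spec.modalities)
        for i, k in enumerate(keys):
            spec = nets.DiscriminatorSpec.toy(in_channels=mask_ch + ch,
                                              width=config.disc_width)
            d = nets.build_discriminator(
                spec, seed=_derive(config.seed, f"d_init:{self.spec.center_id}", i))
            self.discs[k] = d
            self.opts[k] = nn_adam(d.params(), d_lr, config.beta1)
        self._rng = np.random.default_rng(
            _derive(config.seed, f"sample:{self.spec.center_id}"))
        self._perc = (RandomConvExtractor(1 if per_modality else ch,
                                          seed=config.extractor_seed)
                      if w.lambda2 > 0 else None)
        self.retired = False

    # -- private data access ------------------------------------------------
    @property
    def data(self) -> CenterData:
        if self.retired:
            raise PrivacyError(
                f"real data of retired center {self.spec.center_id} is unavailable")
        return self._data

    def retire(self) -> None:
        """Drop real data and discriminators (end of a continual task)."""
        self.retired = True
        self._data = None
        self.discs = {}
        self.opts = {}

    def real_image_hashes(self) -> set[str]:
        out = set()
        for y in self.data.images:
            for arr in (y, to_tanh_range(y)):
                out.add(payload_hash(np.ascontiguousarray(arr)))
        return out

    # -- protocol steps -----------------------------------------------------
    def sample_mask_batch(self, m: int):
        """Draw a batch of (mask, image) pairs; with ``config.augment`` set,
        the same random geometric transform is applied to each pair."""
        from .transforms import apply_transform, apply_transform_image
        idx = self._rng.integers(0, len(self.data), size=m)
        masks, images = [], []
        for i in idx:
            mk, im = self.data.masks[i], self.data.images[i]
            if self.config.augment is not None:
                params = self.config.augment.draw(self._rng, mk.shape[0])
                mk = apply_transform(mk, params)
                im = apply_transform_image(im, params)
            masks.append(mk)
            images.append(im)
        self._pending = (np.stack(masks), np.stack(images))
        return idx, self._pending[0]

    def reference_stats(self, extractor) -> FeatureStats:
        return compute_stats(np.stack(self.data.images), extractor)

    def training_step(self, idx: np.ndarray, yhat: np.ndarray) -> bytes:
        """Update each local discriminator once on (real vs synthetic), then
        compute the per-sample gradient of the local generator loss w.r.t.
        the synthetic images.  Returns a serialized gradient packet."""
        _ = self.data                       # asserts the center is not retired
        w = self.config.weights
        masks, images = self._pending
        onehot = np.stack([mask_to_onehot(m, self.n_classes) for m in masks])
        y = to_tanh_range(images)
        grad = np.zeros_like(yhat)
        scalars = {"adversarial": 0.0, "l1": 0.0, "perceptual": 0.0,
                   "generator": 0.0, "discriminator": 0.0}
        items = ([(k, y[:, i:i + 1], yhat[:, i:i + 1], slice(i, i + 1))
                  for i, k in enumerate(self.spec.modalities)]
                 if self.per_modality else [(-1, y, yhat, slice(None))])
        for key, y_k, yhat_k, sl in items:
            d, opt = self.discs[key], self.opts[key]
            eps = w.clamp_eps
            # one discriminator update
            s_r = d.forward(onehot, y_k, train=True)
            g_r = -1.0 / (np.clip(s_r, eps, 1 - eps) * s_r.size)
            d.backward(g_r)
            s_f = d.forward(onehot, yhat_k, train=True)
            g_f = 1.0 / ((1.0 - np.clip(s_f, eps, 1 - eps)) * s_f.size)
            d.backward(g_f)
            opt.step()
            d.zero_grad()
            scalars["discriminator"] += losses.discriminator_loss(s_r, s_f, eps)
            # local generator loss and its gradient w.r.t. yhat_k
            s_f2 = d.forward(onehot, yhat_k, train=True)
            g_total, terms = losses.generator_center_loss(s_f2, y_k, yhat_k, w,
                                                          self._perc)
            g_img = d.backward_image(losses.generator_adversarial_grad(s_f2, eps),
                                     yhat_k.shape[1])
            d.zero_grad()
            g_img = g_img + w.lambda1 * losses.l1_grad(y_k, yhat_k)
            if w.lambda2 > 0:
                fy = self._perc.features(y_k)
                fyh = self._perc.features(yhat_k)
                dfeat = 2.0 * (fyh - fy) / fy.size
                g_img = g_img + w.lambda2 * self._perc.features_grad(yhat_k, dfeat)
            grad[:, sl] += g_img
            scalars["generator"] += g_total
            for name in ("adversarial", "l1", "perceptual"):
                scalars[name] += terms[name]
        packet = losses.GradientPacket(self.spec.center_id, grad, scalars)
        return losses.pack_gradient_packet(packet)


def nn_adam(params, lr, beta1):
    from . import nn
    return nn.Adam(params, lr=lr, beta1=beta1)


# ---------------------------------------------------------------------------
# Federation-level mask sampling (annotations are shareable)

class MaskSampler:
    """Draws masks over the union of centers: center j with probability
    pi_j (propto |S_j| by default), then uniformly within the center."""

    def __init__(self, centers_data: list[CenterData], rng: np.random.Generator,
                 weights=None):
        self.pools = [cd.masks for cd in centers_data]
        sizes = np.array([len(p) for p in self.pools], dtype=float)
        w = sizes if weights is None else np.asarray(weights, dtype=float)
        self.p = w / w.sum()
        self.rng = rng

    def sample(self, n: int):
        centers = self.rng.choice(len(self.pools), size=n, p=self.p)
        masks = np.stack([self.pools[c][self.rng.integers(0, len(self.pools[c]))]
                          for c in centers])
        return masks, centers


# ---------------------------------------------------------------------------
# Helpers shared by training and evaluation

def generate_images(generator: nets.Generator, masks: np.ndarray, n_classes: int,
                    rng: np.random.Generator | None = None,
                    batch: int = 16) -> np.ndarray:
    """Synthesize images for a stack of masks; returns [0, 1]-scaled arrays.

    Uses running batch-norm statistics; dropout stays active when the
    generator spec asks for inference-time noise.  A dedicated RNG keeps the
    training noise stream untouched."""
    saved = generator.rngbox.rng
    if rng is not None:
        generator.rngbox.rng = rng
    try:
        outs = []
        for i in range(0, len(masks), batch):
            chunk = np.stack([mask_to_onehot(m, n_classes) for m in masks[i:i + batch]])
            outs.append(generator.forward(chunk, train=False))
        return datagen.from_tanh_range(np.concatenate(outs))
    finally:
        generator.rngbox.rng = saved


def dist_fid_from_images(ref: list, synth: np.ndarray, extractors: dict) -> float:
    """Dist-FID of a synthetic image stack against per-center reference stats.

    ``ref`` entries are (center_id, stats, n_samples, modalities) where stats
    is a FeatureStats over the center's full channel stack, or — in
    missing-modality federations, where stacks have unequal channel sets — a
    {modality: FeatureStats} dict computed channel-wise with a shared
    single-channel extractor; a center's FID term is then the mean over its
    available modalities, so every comparison happens in a common feature
    space."""
    from .distfid import fid as _fid
    sizes = np.array([n for _, _, n, _ in ref], dtype=float)
    weights = sizes / sizes.sum()
    total = 0.0
    for w_j, (cid, stats, _, mods) in zip(weights, ref):
        if isinstance(stats, dict):
            ex = extractors["per_modality"]
            term = float(np.mean([
                _fid(stats[k], compute_stats(synth[:, [k]], ex)) for k in mods]))
        else:
            ex = extractors[tuple(mods)]
            term = _fid(stats, compute_stats(synth[:, list(mods)], ex))
        total += w_j * term
    return float(total)


def evaluate_dist_fid(generator, ref: list, sampler: MaskSampler,
                      extractors: dict, n_classes: int, n_samples: int,
                      rng: np.random.Generator) -> float:
    """Dist-FID of fresh synthetic images against per-center reference stats."""
    masks, _ = sampler.sample(n_samples)
    synth = generate_images(generator, masks, n_classes, rng)
    return dist_fid_from_images(ref, synth, extractors)


@dataclass
class RemindingContext:
    prev_generator: nets.Generator       # frozen G_{t-1}, dropout disabled
    sampler: MaskSampler                 # masks retained from earlier tasks
    lam: float
    rng: np.random.Generator
    _fingerprint: tuple = None

    def __post_init__(self):
        self._fingerprint = tuple(a.sum() for a in self.prev_generator.state())

    def check_frozen(self) -> bool:
        return self._fingerprint == tuple(a.sum() for a in self.prev_generator.state())


@dataclass
class TrainResult:
    generator: nets.Generator            # final-state generator
    best_state: list                     # parameters at the Dist-FID argmin
    best_epoch: int
    history: dict
    channel: Channel
    bundle: CenterStatsBundle | None     # None in missing-modality mode
    ref: list                            # per-center (id, stats, n, modalities)
    extractors: dict
    sampler: MaskSampler
    config: TrainConfig
    n_classes: int

    def best_generator(self) -> nets.Generator:
        g = self.generator.clone()
        g.load_state([a.copy() for a in self.best_state])
        return g


# ---------------------------------------------------------------------------
# Core loops

def train_round(generator: nets.Generator, centers: list[CenterNode],
                config: TrainConfig, opt, channel: Channel, pis: np.ndarray,
                reminding: RemindingContext | None = None) -> dict:
    """One synchronous round: every center contributes a batch; the generator
    aggregates the pi-weighted gradients and takes one Adam step."""
    n = len(centers)
    n_classes = centers[0].n_classes
    m = config.batch_size
    prefactor = 1.0 / ((n if config.strict_eq5 else 1.0) * pis.sum())
    agg = {"d_loss": 0.0, "g_loss": 0.0, "reminding": 0.0}
    generator.zero_grad()
    for pi_j, center in zip(pis, centers):
        cid = center.spec.center_id
        idx, masks = center.sample_mask_batch(m)
        channel.send(f"{cid}->server", "mask", masks)
        onehot = np.stack([mask_to_onehot(mk, n_classes) for mk in masks])
        yhat_full = generator.forward(onehot, train=True)
        mods = list(center.spec.modalities)
        yhat_local = yhat_full[:, mods] if len(mods) != yhat_full.shape[1] or \
            mods != list(range(yhat_full.shape[1])) else yhat_full
        channel.send(f"server->{cid}", "synthetic_image", yhat_local)
        raw = center.training_step(idx, yhat_local)
        channel.send(f"{cid}->server", "gradient_packet", raw)
        packet = losses.unpack_gradient_packet(raw)
        channel.send(f"{cid}->server", "loss_scalars", packet.losses)
        dfull = np.zeros_like(yhat_full)
        dfull[:, mods] = packet.grad
        generator.backward(pi_j * prefactor * dfull)
        agg["d_loss"] += packet.losses["discriminator"]
        agg["g_loss"] += pi_j * prefactor * m * packet.losses["generator"]
    if reminding is not None and reminding.lam > 0:
        masks, _ = reminding.sampler.sample(m)
        onehot = np.stack([mask_to_onehot(mk, n_classes) for mk in masks])
        out_t = generator.forward(onehot, train=True)
        out_prev = reminding.prev_generator.forward(onehot, train=False)
        agg["reminding"] = losses.reminding_loss(out_t, out_prev)
        generator.backward(reminding.lam * losses.reminding_grad(out_t, out_prev))
    opt.step()
    generator.zero_grad()
    agg["d_loss"] /= n
    return agg


def _pi_weights(centers_data: list[CenterData]) -> np.ndarray:
    pis = np.array([cd.spec.weight if cd.spec.weight is not None else len(cd)
                    for cd in centers_data], dtype=float)
    return pis / pis.sum()        # pi_j propto |S_j| unless overridden


def train(config: TrainConfig, centers_data: list[CenterData],
          phantom: PhantomSpec, channel: Channel | None = None,
          init_generator: nets.Generator | None = None,
          reminding: RemindingContext | None = None,
          eval_callback=None) -> TrainResult:
    """Full training run with per-epoch Dist-FID tracking and best-model
    selection.  Reproducible given ``config.seed``."""
    datagen.validate_federation([cd.spec for cd in centers_data], phantom)
    if config.mode in {"base"} and any(
            set(cd.spec.modalities) != set(range(phantom.n_modalities))
            for cd in centers_data):
        raise ValueError("base mode requires complete modalities at every center")
    channel = channel if channel is not None else Channel()
    n_classes, c = phantom.n_classes, phantom.n_modalities
    per_modality = (config.mode in {"multimodal", "missing"}
                    and not config.single_discriminator)
    if config.mode == "missing" and config.single_discriminator:
        raise ValueError("missing-modality mode needs per-modality discriminators")

    gen_spec = config.generator_spec(n_classes, c)
    if init_generator is not None:
        generator = init_generator.clone()
    else:
        generator = nets.build_generator(gen_spec, seed=_derive(config.seed, "g_init"))
    generator.set_noise_rng(np.random.default_rng(_derive(config.seed, "dropout")))
    opt = nn_adam(generator.params(), config.lr, config.beta1)

    pis = _pi_weights(centers_data)
    centers = [CenterNode(cd, config, per_modality, pi)
               for cd, pi in zip(centers_data, pis)]

    # reference statistics, transmitted once before training
    per_modality_stats = config.mode == "missing"
    extractors: dict = {}
    ref = []
    for center in centers:
        mods = tuple(center.spec.modalities)
        if per_modality_stats:
            ex = extractors.setdefault(
                "per_modality", RandomConvExtractor(1, seed=config.extractor_seed))
            stats = {k: compute_stats(np.stack(center.data.images)[:, [i]], ex)
                     for i, k in enumerate(mods)}
            mu_msg = {str(k): s.mu.tolist() for k, s in stats.items()}
        else:
            if mods not in extractors:
                extractors[mods] = RandomConvExtractor(len(mods),
                                                       seed=config.extractor_seed)
            stats = center.reference_stats(extractors[mods])
            mu_msg = {"mu": stats.mu.tolist()}
        channel.send(f"{center.spec.center_id}->server", "feature_stats",
                     {**mu_msg, "n": len(center.data)})
        ref.append((center.spec.center_id, stats, len(center.data), mods))
    bundle = (CenterStatsBundle([(cid, s, n) for cid, s, n, _ in ref])
              if not per_modality_stats else None)

    sampler = MaskSampler(centers_data,
                          np.random.default_rng(_derive(config.seed, "masks")))
    eval_rng = np.random.default_rng(_derive(config.seed, "eval"))
    mean_size = int(np.mean([len(cd) for cd in centers_data]))
    rounds = config.rounds_per_epoch or max(1, mean_size // config.batch_size)

    history = {"epoch": [], "d_loss": [], "g_loss": [], "reminding": [],
               "dist_fid": [], "dist_fid_epoch": []}
    best = (np.inf, None, -1)
    for epoch in range(config.epochs):
        ep = {"d_loss": 0.0, "g_loss": 0.0, "reminding": 0.0}
        for _ in range(rounds):
            agg = train_round(generator, centers, config, opt, channel, pis,
                              reminding)
            for k in ep:
                ep[k] += agg[k] / rounds
        if not np.isfinite(ep["g_loss"]) or not np.isfinite(ep["d_loss"]):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}: {ep}")
        history["epoch"].append(epoch)
        for k in ("d_loss", "g_loss", "reminding"):
            history[k].append(ep[k])
        if (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1:
            masks, _ = sampler.sample(config.n_eval_samples)
            synth = generate_images(generator, masks, n_classes, eval_rng)
            score = dist_fid_from_images(ref, synth, extractors)
            if eval_callback is not None:
                eval_callback(epoch, generator, synth)
            history["dist_fid"].append(score)
            history["dist_fid_epoch"].append(epoch)
            if score < best[0]:
                best = (score, [a.copy() for a in generator.state()], epoch)
    if reminding is not None and not reminding.check_frozen():
        raise RuntimeError("frozen previous-task generator was modified")
    best_idx = select_best(history["dist_fid"])
    assert history["dist_fid_epoch"][best_idx] == best[2]
    return TrainResult(generator, best[1], best[2], history, channel, bundle,
                       ref, extractors, sampler, config, n_classes)


def continual_train(sequence: TaskSequence, config: TrainConfig,
                    phantom: PhantomSpec) -> list[TrainResult]:
    """Train through a temporal sequence of center cohorts.

    After each task the cohort is retired (real data and discriminators
    dropped); only its masks and feature statistics are retained.  With
    lambda_reminding = 0 the run degenerates to plain fine-tuning."""
    results: list[TrainResult] = []
    prev_gen: nets.Generator | None = None
    retained: list[CenterData] = []
    lam = config.weights.lambda_reminding
    for t, (_, specs) in enumerate(sequence.tasks):
        cohort = [datagen.make_center_data(cs, phantom) for cs in specs]
        ctx = None
        if prev_gen is not None and lam > 0:
            frozen = nets.Generator(
                replace(prev_gen.spec, dropout_active_at_inference=False),
                np.random.default_rng(0))
            frozen.load_state([a.copy() for a in prev_gen.state()])
            ctx = RemindingContext(
                frozen,
                MaskSampler(retained,
                            np.random.default_rng(_derive(config.seed, "remind", t))),
                lam, np.random.default_rng(_derive(config.seed, "remind_rng", t)))
        task_cfg = replace(config, seed=_derive(config.seed, "task", t))
        res = train(task_cfg, cohort, phantom, init_generator=prev_gen,
                    reminding=ctx)
        results.append(res)
        prev_gen = res.best_generator()
        # only annotations are retained across tasks
        retained = retained + [CenterData(cd.spec, cd.phantom, cd.masks, [], [])
                               for cd in cohort]
    return results


# ---------------------------------------------------------------------------
# Monolithic reference (single-site conditional GAN, no federation plumbing)

def train_monolithic(config: TrainConfig, data: CenterData, phantom: PhantomSpec,
                     n_steps: int) -> tuple[nets.Generator, list[dict]]:
    """Ordinary single-site conditional-GAN training loop, written without
    the channel/packet machinery; used as the step-equivalence oracle for a
    one-center federation with matched seeds."""
    n_classes, c = phantom.n_classes, phantom.n_modalities
    w = config.weights
    generator = nets.build_generator(config.generator_spec(n_classes, c),
                                     seed=_derive(config.seed, "g_init"))
    generator.set_noise_rng(np.random.default_rng(_derive(config.seed, "dropout")))
    g_opt = nn_adam(generator.params(), config.lr, config.beta1)
    mask_ch = n_classes + 1
    d_spec = nets.DiscriminatorSpec.toy(in_channels=mask_ch + c,
                                        width=config.disc_width)
    disc = nets.build_discriminator(
        d_spec, seed=_derive(config.seed, f"d_init:{data.spec.center_id}", 0))
    d_opt = nn_adam(disc.params(), config.d_lr or config.lr, config.beta1)
    rng = np.random.default_rng(_derive(config.seed, f"sample:{data.spec.center_id}"))
    eps = w.clamp_eps
    perc = RandomConvExtractor(c, seed=config.extractor_seed) if w.lambda2 > 0 else None
    log = []
    from .transforms import apply_transform, apply_transform_image
    for _ in range(n_steps):
        idx = rng.integers(0, len(data), size=config.batch_size)
        masks, images = [], []
        for i in idx:
            mk, im = data.masks[i], data.images[i]
            if config.augment is not None:
                params = config.augment.draw(rng, mk.shape[0])
                mk = apply_transform(mk, params)
                im = apply_transform_image(im, params)
            masks.append(mk)
            images.append(im)
        masks = np.stack(masks)
        onehot = np.stack([mask_to_onehot(mk, n_classes) for mk in masks])
        y = to_tanh_range(np.stack(images))
        yhat = generator.forward(onehot, train=True)
        s_r = disc.forward(onehot, y, train=True)
        disc.backward(-1.0 / (np.clip(s_r, eps, 1 - eps) * s_r.size))
        s_f = disc.forward(onehot, yhat, train=True)
        disc.backward(1.0 / ((1.0 - np.clip(s_f, eps, 1 - eps)) * s_f.size))
        d_opt.step()
        disc.zero_grad()
        s_f2 = disc.forward(onehot, yhat, train=True)
        g_total, _ = losses.generator_center_loss(s_f2, y, yhat, w, perc)
        g_img = disc.backward_image(losses.generator_adversarial_grad(s_f2, eps), c)
        disc.zero_grad()
        g_img = g_img + w.lambda1 * losses.l1_grad(y, yhat)
        if w.lambda2 > 0:
            fy, fyh = perc.features(y), perc.features(yhat)
            g_img = g_img + w.lambda2 * perc.features_grad(
                yhat, 2.0 * (fyh - fy) / fy.size)
        generator.zero_grad()
        generator.backward(g_img)      # N=1, pi=(1): Eq.-5 prefactor is 1
        g_opt.step()
        generator.zero_grad()
        log.append({"d_loss": losses.discriminator_loss(s_r, s_f, eps),
                    "g_loss": g_total})
    return generator, log
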
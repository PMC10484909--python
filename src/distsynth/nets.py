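"""Generator and discriminator architectures.

The central generator is an encoder-decoder ResNet: a 7x7 stem, two stride-2
convolutions down, a stack of residual blocks, two transposed convolutions
up, and a 7x7 head squashed by tanh to [-1, 1].  All non-residual
convolutions are followed by batch normalization and ReLU.  Noise enters
through dropout inside the residual blocks, active during training *and*
inference, rather than through a latent input.

Each discriminator is a PatchGAN: a fully convolutional stack emitting a
sigmoid score per overlapping receptive-field patch.  The full-scale default
follows the common image-to-image translation configuration whose receptive
field is 70x70 pixels; reduced toy-scale specs keep CPU tests fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn


# ---------------------------------------------------------------------------
# Specs

@dataclass
class GeneratorSpec:
    in_channels: int = 2          # one-hot mask channels (background + classes)
    out_channels: int = 1         # c modalities
    base_width: int = 64
    n_residual_blocks: int = 9
    n_down: int = 2
    n_up: int = 2
    dropout_rate: float = 0.5
    dropout_active_at_inference: bool = True

    @staticmethod
    def toy(in_channels: int = 2, out_channels: int = 1, base_width: int = 16,
            n_residual_blocks: int = 2, **kw) -> "GeneratorSpec":
        return GeneratorSpec(in_channels, out_channels, base_width,
                             n_residual_blocks, **kw)


@dataclass
class DiscriminatorSpec:
    """Layer list of (out_channels, kernel, stride); a sigmoid 1-channel head
    is appended implicitly by the final entry having out_channels == 1."""
    in_channels: int = 2          # mask one-hot + image channels, concatenated
    layers: tuple = ((64, 4, 2), (128, 4, 2), (256, 4, 2), (512, 4, 1), (1, 4, 1))

    @staticmethod
    def paper_default(in_channels: int = 2) -> "DiscriminatorSpec":
        return DiscriminatorSpec(in_channels=in_channels)

    @staticmethod
    def toy(in_channels: int = 2, width: int = 16) -> "DiscriminatorSpec":
        return DiscriminatorSpec(
            in_channels=in_channels,
            layers=((width, 4, 2), (2 * width, 4, 2), (1, 4, 1)),
        )


def receptive_field(spec: DiscriminatorSpec) -> int:
    """Receptive field of one output score in input pixels.

    Uses the standard recurrence r <- r + (k - 1) * jump, jump <- jump * s,
    applied layer by layer.
    """
    r, jump = 1, 1
    for _, k, s in spec.layers:
        r += (k - 1) * jump
        jump *= s
    return r


# ---------------------------------------------------------------------------
# Networks

class Generator:
    """Mask (one-hot, NCHW) -> modality stack in [-1, 1]."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        self.spec = spec
        self.rngbox = nn.RngBox(np.random.default_rng(0))
        w = spec.base_width
        rb = self.rngbox
        layers: list[nn.Module] = [
            nn.Conv2d(spec.in_channels, w, 7, 1, 3, rng=rng),
            nn.BatchNorm2d(w), nn.ReLU(),
        ]
        ch = w
        for _ in range(spec.n_down):
            layers += [nn.Conv2d(ch, ch * 2, 3, 2, 1, rng=rng),
                       nn.BatchNorm2d(ch * 2), nn.ReLU()]
            ch *= 2
        for _ in range(spec.n_residual_blocks):
            layers.append(nn.ResidualBlock(ch, spec.dropout_rate, rb,
                                           spec.dropout_active_at_inference, rng))
        for _ in range(spec.n_up):
            layers += [nn.ConvTranspose2d(ch, ch // 2, 3, 2, 1, 1, rng=rng),
                       nn.BatchNorm2d(ch // 2), nn.ReLU()]
            ch //= 2
        layers += [nn.Conv2d(ch, spec.out_channels, 7, 1, 3, rng=rng), nn.Tanh()]
        self.net = nn.Sequential(*layers)

    def set_noise_rng(self, rng: np.random.Generator) -> None:
        self.rngbox.rng = rng

    def params(self):
        return self.net.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        stride = 2 ** self.spec.n_down
        if h % stride or w % stride:
            raise ValueError(
                f"input size {h}x{w} not divisible by {stride} "
                f"({self.spec.n_down} downsamplings)")
        if c != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels, got {c}")
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return self.net.backward(dout)

    def zero_grad(self):
        self.net.zero_grad()

    def state(self):
        return self.net.state()

    def load_state(self, arrays):
        self.net.load_state(arrays)

    def clone(self) -> "Generator":
        g = Generator(self.spec, np.random.default_rng(0))
        g.load_state([a.copy() for a in self.state()])
        return g


class PatchDiscriminator:
    """(mask one-hot, image) concatenated on channels -> patch score map in (0,1)."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        self.spec = spec
        layers: list[nn.Module] = []
        ch = spec.in_channels
        n = len(spec.layers)
        for i, (out_ch, k, s) in enumerate(spec.layers):
            layers.append(nn.Conv2d(ch, out_ch, k, s, (k - 1) // 2, rng=rng))
            last = i == n - 1
            if not last:
                if i > 0:
                    layers.append(nn.BatchNorm2d(out_ch))
                layers.append(nn.LeakyReLU(0.2))
            ch = out_ch
        layers.append(nn.Sigmoid())
        self.net = nn.Sequential(*layers)

    def params(self):
        return self.net.params()

    def forward(self, mask_onehot: np.ndarray, image: np.ndarray,
                train: bool = False) -> np.ndarray:
        if mask_onehot.shape[0] != image.shape[0] or mask_onehot.shape[2:] != image.shape[2:]:
            raise ValueError("mask/image batch or spatial shape mismatch")
        x = np.concatenate([mask_onehot, image], axis=1)
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(
                f"discriminator expects {self.spec.in_channels} channels, got {x.shape[1]}")
        return self.net.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the concatenated (mask, image) input."""
        return self.net.backward(dout)

    def backward_image(self, dout: np.ndarray, n_image_channels: int) -> np.ndarray:
        """Gradient w.r.t. the image part of the input only."""
        dx = self.net.backward(dout)
        return dx[:, -n_image_channels:]

    def zero_grad(self):
        self.net.zero_grad()

    def state(self):
        return self.net.state()

    def load_state(self, arrays):
        self.net.load_state(arrays)


def build_generator(spec: GeneratorSpec, seed: int = 0) -> Generator:
    _validate_gen_spec(spec)
    return Generator(spec, np.random.default_rng(seed))


def build_discriminator(spec: DiscriminatorSpec, seed: int = 0) -> PatchDiscriminator:
    if spec.in_channels < 1 or not spec.layers:
        raise ValueError("invalid discriminator spec")
    if spec.layers[-1][0] != 1:
        raise ValueError("final discriminator layer must emit one score channel")
    return PatchDiscriminator(spec, np.random.default_rng(seed))


def _validate_gen_spec(spec: GeneratorSpec) -> None:
    if spec.in_channels < 1 or spec.out_channels < 1:
        raise ValueError("channel counts must be >= 1")
    if spec.base_width < 1 or spec.n_residual_blocks < 0:
        raise ValueError("invalid generator width/depth")
    if not (0.0 <= spec.dropout_rate < 1.0):
        raise ValueError("dropout_rate must be in [0, 1)")
    if spec.n_down != spec.n_up:
        raise ValueError("n_down must equal n_up to preserve spatial size")


# ---------------------------------------------------------------------------
# Checkpoints

def save_checkpoint(path, net, spec, step: int = 0, kind: str = "generator") -> None:
    """Write parameters + spec + step; reload is bit-exact."""
    path = Path(path)
    arrays = {f"a{i}": a for i, a in enumerate(net.state())}
    header = {"kind": kind, "step": step, "spec": asdict(spec)}
    np.savez(path, __header__=np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns (net, spec, step). Only generator checkpoints are rebuilt."""
    with np.load(Path(path), allow_pickle=False) as z:
        header = json.loads(bytes(z["__header__"]).decode())
        arrays = [z[f"a{i}"] for i in range(len(z.files) - 1)]
    spec_d = header["spec"]
    if header["kind"] == "generator":
        spec = GeneratorSpec(**spec_d)
        net = build_generator(spec, seed=0)
    else:
        spec_d["layers"] = tuple(tuple(l) for l in spec_d["layers"])
        spec = DiscriminatorSpec(**spec_d)
        net = build_discriminator(spec, seed=0)
    net.load_state(arrays)
    return net, spec, header["step"]
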
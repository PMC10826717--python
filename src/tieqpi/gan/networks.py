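"""Generator and discriminator architectures.

The generator is a U-Net: an encoder of stride-2 4x4 convolutions that
halves the spatial size at every stage, a mirrored decoder of stride-2
transposed convolutions, and skip connections concatenating each
encoder feature onto the matching decoder stage.  Leaky ReLU follows
every encoder convolution, batch normalization follows each layer
(except the first and the 1x1 bottleneck), dropout acts in the first
decoder stages, and a tanh maps the single-channel output into [-1, 1].

The discriminator is a PatchGAN: five 4x4 convolutions (three stride-2,
two stride-1) consume the concatenated (intensity, phase) pair and emit
a sigmoid-activated grid of per-patch realness scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn

__all__ = ["GanConfig", "UNetGenerator", "PatchDiscriminator"]


@dataclass(frozen=True)
class GanConfig:
    """Architecture and training hyperparameters.

    Defaults follow the paired image-to-image translation convention:
    256 px tiles, 64 base channels doubling to a 512 cap, 8 encoder /
    8 decoder stages, a 5-conv PatchGAN, Adam at learning rate 1e-4
    with batch size 4, and an L1 reconstruction weight of 100.
    """

    tile: int = 256
    base_channels: int = 64
    encoder_depth: int = 8
    discriminator_convs: int = 5
    learning_rate: float = 1e-4
    batch_size: int = 4
    epochs: int = 200
    l1_weight: float = 100.0
    dropout_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l1_weight < 0:
            raise ValueError("l1_weight must be >= 0")
        depth = self.effective_depth
        if self.tile % (2**depth):
            raise ValueError(
                f"tile {self.tile} is not divisible by 2^{depth}"
            )

    @property
    def effective_depth(self) -> int:
        """Encoder depth actually usable at this tile size."""
        max_depth = int(np.log2(self.tile))
        return min(self.encoder_depth, max_depth)


def _enc_channels(config: GanConfig) -> list[int]:
    b = config.base_channels
    return [min(b * 2**i, b * 8) for i in range(config.effective_depth)]


class UNetGenerator:
    """U-Net encoder/decoder with skip connections; maps (N,1,T,T) -> (N,1,T,T)."""

    def __init__(self, config: GanConfig):
        self.config = config
        depth = config.effective_depth
        if depth < config.encoder_depth:
            warnings.warn(
                f"tile {config.tile} supports only {depth} of the requested "
                f"{config.encoder_depth} encoder stages; depth reduced",
                stacklevel=2,
            )
        rng = np.random.default_rng(config.seed)
        self.drop_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
        )
        ch = _enc_channels(config)
        self.depth = depth

        self.enc: list[nn.Sequential] = []
        cin = 1
        size = config.tile
        for i in range(depth):
            size //= 2
            layers = [nn.Conv2d(cin, ch[i], rng=rng)]
            if 0 < i and size > 1:  # no BN on the first stage or 1x1 bottleneck
                layers.append(nn.BatchNorm2d(ch[i], rng=rng))
            layers.append(nn.LeakyReLU(0.2))
            self.enc.append(nn.Sequential(*layers))
            cin = ch[i]

        self.dec: list[nn.Sequential] = []
        self.dec_out_ch: list[int] = []
        for j in range(depth - 1):
            level = depth - 2 - j  # encoder level whose skip joins here
            cin_dec = ch[depth - 1] if j == 0 else 2 * ch[level + 1]
            cout = ch[level]
            layers = [
                nn.ConvTranspose2d(cin_dec, cout, rng=rng),
                nn.BatchNorm2d(cout, rng=rng),
            ]
            if j < 3 and config.dropout_rate > 0:
                layers.append(nn.Dropout(config.dropout_rate, self.drop_rng))
            layers.append(nn.ReLU())
            self.dec.append(nn.Sequential(*layers))
            self.dec_out_ch.append(cout)
        final_cin = 2 * ch[0] if depth > 1 else ch[0]
        self.final = nn.Sequential(
            nn.ConvTranspose2d(final_cin, 1, rng=rng), nn.Tanh()
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=nn.F)
        skips = []
        for blk in self.enc:
            x = blk.forward(x, train)
            skips.append(x)
        y = skips[-1]
        for j, blk in enumerate(self.dec):
            y = blk.forward(y, train)
            y = np.concatenate([y, skips[self.depth - 2 - j]], axis=1)
        return self.final.forward(y, train)

    __call__ = forward

    def predict(self, x: np.ndarray, noise: bool = False) -> np.ndarray:
        """Inference forward pass.

        Batch normalization uses the statistics of the presented input
        (the paired image-to-image translation convention) without
        touching the running averages; dropout is disabled unless
        ``noise=True``, in which case it realizes the cGAN noise input.
        Deterministic for a given input when ``noise=False``.
        """
        layers = [l for blk in (*self.enc, *self.dec, self.final) for l in blk.layers]
        saved = []
        for l in layers:
            if isinstance(l, nn.Dropout):
                saved.append((l, "enabled", l.enabled))
                l.enabled = noise
            elif isinstance(l, nn.BatchNorm2d):
                saved.append((l, "update_running", l.update_running))
                l.update_running = False
        try:
            return self.forward(x, train=True)
        finally:
            for l, attr, v in saved:
                setattr(l, attr, v)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.final.backward(gy.astype(nn.F))
        skip_grads: dict[int, np.ndarray] = {}
        for j in reversed(range(len(self.dec))):
            ch = self.dec_out_ch[j]
            level = self.depth - 2 - j
            skip_grads[level] = g[:, ch:]
            g = self.dec[j].backward(np.ascontiguousarray(g[:, :ch]))
        for i in reversed(range(self.depth)):
            if i in skip_grads:
                g = g + skip_grads[i]
            g = self.enc[i].backward(g)
        return g

    def params(self):
        for blk in (*self.enc, *self.dec, self.final):
            yield from blk.params()


class PatchDiscriminator:
    """Five-conv PatchGAN scoring (intensity, phase) pairs patch-wise."""

    def __init__(self, config: GanConfig):
        self.config = config
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
        )
        b = config.base_channels
        self.net = nn.Sequential(
            nn.Conv2d(2, b, stride=2, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(b, 2 * b, stride=2, rng=rng),
            nn.BatchNorm2d(2 * b, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(2 * b, 4 * b, stride=2, rng=rng),
            nn.BatchNorm2d(4 * b, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(4 * b, 8 * b, stride=1, rng=rng),
            nn.BatchNorm2d(8 * b, rng=rng),
            nn.LeakyReLU(0.2),
            nn.Conv2d(8 * b, 1, stride=1, rng=rng),
        )

    def _pair(self, intensity: np.ndarray, phase: np.ndarray) -> np.ndarray:
        if intensity.shape != phase.shape:
            raise ValueError(
                f"pair shapes differ: {intensity.shape} vs {phase.shape}"
            )
        return np.concatenate(
            [intensity.astype(nn.F), phase.astype(nn.F)], axis=1
        )

    def forward_logits(
        self, intensity: np.ndarray, phase: np.ndarray, train: bool = True
    ) -> np.ndarray:
        return self.net.forward(self._pair(intensity, phase), train)

    def forward(
        self, intensity: np.ndarray, phase: np.ndarray, train: bool = False
    ) -> np.ndarray:
        """Sigmoid patch map of realness scores in (0, 1)."""
        return nn.sigmoid(self.forward_logits(intensity, phase, train))

    __call__ = forward

    def backward(self, glogits: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the (intensity, phase) pair; returns phase part."""
        g = self.net.backward(glogits.astype(nn.F))
        return g[:, 1:2]

    def params(self):
        yield from self.net.params()
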
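"""cGAN training loop, inference, and checkpointing.

One training step updates the discriminator on a combined real/fake
batch (binary cross-entropy toward 1 for real pairs, 0 for generated
ones) and then the generator on the non-saturating adversarial loss
plus an L1 reconstruction term weighted by ``l1_weight``.  With
``l1_weight = 0`` the objective reduces to the bare adversarial
min-max game.

Training is fully deterministic for a fixed seed (numpy arithmetic,
seeded shuffling, seeded dropout).  The checkpoint with the best
validation SSIM is the one retained in the returned model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.typing import NDArray

from ..data import DatasetSplit, TrainingPair, denormalize_tile, normalize_tile
from ..tie import PhaseMap
from . import nn
from .networks import GanConfig, PatchDiscriminator, UNetGenerator

__all__ = [
    "TrainedModel",
    "cgan_step",
    "train",
    "infer",
    "save_model",
    "load_model",
]


@dataclass
class TrainedModel:
    """Generator + discriminator with their config and training history."""

    generator: UNetGenerator
    discriminator: PatchDiscriminator
    config: GanConfig
    history: list[dict] = dc_field(default_factory=list)
    phase_range: tuple[float, float] = (0.0, 1.0)
    pitch_um: float = 0.086250


def _batch_arrays(pairs: list[TrainingPair]):
    x = np.stack([p.intensity_tile for p in pairs])[:, None].astype(nn.F)
    y = np.stack([p.phase_tile for p in pairs])[:, None].astype(nn.F)
    return x, y


def cgan_step(
    generator: UNetGenerator,
    discriminator: PatchDiscriminator,
    batch: list[TrainingPair],
    config: GanConfig,
    opt_g: nn.Adam | None = None,
    opt_d: nn.Adam | None = None,
) -> dict:
    """One discriminator update and one generator update on a batch.

    Returns ``{"d_loss", "g_adv", "g_l1", "g_total"}``; raises
    ``RuntimeError`` on a non-finite loss.
    """
    if not batch:
        raise ValueError("batch must contain at least one pair")
    opt_g = opt_g or nn.Adam(config.learning_rate)
    opt_d = opt_d or nn.Adam(config.learning_rate)
    x, y = _batch_arrays(batch)

    fake = generator.forward(x, train=True)

    # --- discriminator: real pairs -> 1, generated pairs -> 0
    xx = np.concatenate([x, x])
    yy = np.concatenate([y, fake])
    target = np.zeros((2 * len(batch), 1, 1, 1), dtype=nn.F)
    target[: len(batch)] = 1.0
    logits = discriminator.forward_logits(xx, yy, train=True)
    d_loss, dgrad = nn.bce_with_logits(logits, np.broadcast_to(target, logits.shape))
    discriminator.backward(dgrad)
    opt_d.step(discriminator.params())

    # --- generator: fool the (updated) discriminator + L1 to target
    logits_fake = discriminator.forward_logits(x, fake, train=True)
    g_adv, ggrad = nn.bce_with_logits(logits_fake, np.ones_like(logits_fake))
    grad_fake = discriminator.backward(ggrad)
    diff = fake - y
    g_l1 = float(np.mean(np.abs(diff)))
    grad_l1 = config.l1_weight * np.sign(diff) / diff.size
    generator.backward(grad_fake + grad_l1.astype(nn.F))
    opt_g.step(generator.params())

    rec = {
        "d_loss": d_loss,
        "g_adv": g_adv,
        "g_l1": g_l1,
        "g_total": g_adv + config.l1_weight * g_l1,
    }
    if not all(np.isfinite(v) for v in rec.values()):
        raise RuntimeError(f"non-finite loss encountered: {rec}")
    return rec


def _validation_ssim(generator: UNetGenerator, pairs: list[TrainingPair]) -> float:
    from ..quality import MetricsConfig, ssim

    cfg = MetricsConfig()
    vals = []
    for p in pairs:
        pred = generator.predict(p.intensity_tile[None, None])[0, 0]
        vals.append(
            ssim((pred + 1) * 127.5, (p.phase_tile + 1) * 127.5, cfg)
        )
    return float(np.mean(vals)) if vals else float("nan")


def train(
    dataset: DatasetSplit,
    config: GanConfig,
    pitch_um: float = 0.086250,
) -> TrainedModel:
    """Train the cGAN on a dataset split.

    Shuffling, dropout and weight initialization all derive from
    ``config.seed``; two runs with identical inputs are identical.
    The epoch with the best validation SSIM provides the retained
    generator parameters.  ``epochs = 0`` returns the initialized,
    untrained model with an empty history.
    """
    if not dataset.train and config.epochs > 0:
        raise ValueError("training split is empty")
    generator = UNetGenerator(config)
    discriminator = PatchDiscriminator(config)
    model = TrainedModel(
        generator, discriminator, config, [], dataset.phase_range, pitch_um
    )
    if config.epochs == 0:
        return model
    opt_g = nn.Adam(config.learning_rate)
    opt_d = nn.Adam(config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    best = (-np.inf, None)
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset.train))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [dataset.train[i] for i in idx]
            try:
                losses.append(
                    cgan_step(generator, discriminator, batch, config, opt_g, opt_d)
                )
            except RuntimeError as e:
                raise RuntimeError(
                    f"training aborted at epoch {epoch}, batch {start // config.batch_size}: {e}"
                ) from e
        record = {k: float(np.mean([l[k] for l in losses])) for k in losses[0]}
        record["epoch"] = epoch
        record["val_ssim"] = _validation_ssim(generator, dataset.validation)
        if dataset.validation and np.isnan(record["val_ssim"]):
            raise RuntimeError(f"validation SSIM is NaN at epoch {epoch}")
        model.history.append(record)
        if not dataset.validation or record["val_ssim"] > best[0]:
            best = (record["val_ssim"], _snapshot(generator))
    if best[1] is not None:
        _restore(generator, best[1])
    return model


def infer(
    model: TrainedModel,
    intensity_frame: NDArray[np.floating],
    normalization: tuple[float, float] | None = None,
) -> PhaseMap:
    """Single-shot phase inference from one defocused intensity frame.

    The frame is center-cropped to the training tile size (frames
    smaller than the tile are rejected), min-max normalized (pass
    ``normalization`` to reuse a known record), pushed through the
    generator once, and denormalized to radians with the phase range
    stored in the checkpoint.
    """
    frame = np.asarray(intensity_frame, dtype=float)
    t = model.config.tile
    if frame.shape[0] < t or frame.shape[1] < t:
        raise ValueError(
            f"frame {frame.shape} is smaller than the {t} px model tile"
        )
    r0 = (frame.shape[0] - t) // 2
    c0 = (frame.shape[1] - t) // 2
    tile = frame[r0 : r0 + t, c0 : c0 + t]
    norm, _ = normalize_tile(tile, normalization)
    pred = model.generator.predict(norm[None, None])[0, 0]
    phase = denormalize_tile(pred.astype(float), model.phase_range)
    return PhaseMap(phase, model.pitch_um, normalization=model.phase_range)


# --- checkpointing ---------------------------------------------------------

_ARRAY_ATTRS = ("W", "b", "gamma", "beta", "run_mean", "run_var")


def _layers(model_part) -> list:
    if isinstance(model_part, UNetGenerator):
        blocks = [*model_part.enc, *model_part.dec, model_part.final]
    else:
        blocks = [model_part.net]
    return [l for blk in blocks for l in blk.layers]


def _snapshot(part) -> list[dict]:
    out = []
    for layer in _layers(part):
        d = {}
        for a in _ARRAY_ATTRS:
            v = getattr(layer, a, None)
            if isinstance(v, np.ndarray):
                d[a] = v.copy()
        out.append(d)
    return out


def _restore(part, snap: list[dict]) -> None:
    for layer, d in zip(_layers(part), snap):
        for a, v in d.items():
            setattr(layer, a, v.copy())


def save_model(model: TrainedModel, path) -> None:
    """Write a checkpoint: one .npz archive with parameters + metadata."""
    arrays: dict[str, np.ndarray] = {}
    for prefix, part in (("g", model.generator), ("d", model.discriminator)):
        for i, d in enumerate(_snapshot(part)):
            for a, v in d.items():
                arrays[f"{prefix}{i:03d}_{a}"] = v
    meta = {
        "config": model.config.__dict__,
        "history": model.history,
        "phase_range": model.phase_range,
        "pitch_um": model.pitch_um,
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> TrainedModel:
    """Reload a checkpoint bit-identically."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        config = GanConfig(**meta["config"])
        generator = UNetGenerator(config)
        discriminator = PatchDiscriminator(config)
        for prefix, part in (("g", generator), ("d", discriminator)):
            for i, layer in enumerate(_layers(part)):
                for a in _ARRAY_ATTRS:
                    key = f"{prefix}{i:03d}_{a}"
                    if key in f:
                        setattr(layer, a, f[key].copy())
    return TrainedModel(
        generator,
        discriminator,
        config,
        meta["history"],
        tuple(meta["phase_range"]),
        float(meta["pitch_um"]),
    )
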
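"""Paired intensity -> phase dataset construction.

Every defocused frame of a through-focus stack is paired with that
stack's single conventional-TIE phase map; a network trained on such
pairs learns to map an intensity image from *any* defocus plane inside
the recorded range to the in-focus quantitative phase.  This module
extracts ROI tiles, normalizes them to [-1, 1] with invertible records,
splits train/validation/test disjointly by source object, and reads and
writes the dataset as HDF5 or paired PNG directories.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
from numpy.typing import NDArray

from .phantoms import IntensityStack
from .tie import PhaseMap

__all__ = [
    "TrainingPair",
    "DatasetSplit",
    "extract_rois",
    "build_pairs",
    "normalize_tile",
    "denormalize_tile",
    "save_dataset_h5",
    "load_dataset_h5",
    "save_dataset_png",
    "load_dataset_png",
]


def normalize_tile(
    tile: NDArray[np.floating],
    record: tuple[float, float] | None = None,
) -> tuple[NDArray[np.floating], tuple[float, float]]:
    """Min-max normalize a tile to [-1, 1], returning the (min, max) record.

    Pass an explicit ``record`` to normalize against a shared range
    (values are then clipped to [-1, 1]).  Constant tiles map to 0.
    """
    tile = np.asarray(tile, dtype=float)
    if record is None:
        lo, hi = float(tile.min()), float(tile.max())
    else:
        lo, hi = record
    if hi <= lo:
        return np.zeros_like(tile), (lo, hi)
    out = (tile - lo) / (hi - lo) * 2.0 - 1.0
    if record is not None:
        out = np.clip(out, -1.0, 1.0)
    return out, (lo, hi)


def denormalize_tile(
    tile: NDArray[np.floating], record: tuple[float, float]
) -> NDArray[np.floating]:
    """Invert :func:`normalize_tile` given its (min, max) record."""
    lo, hi = record
    if hi <= lo:
        return np.full_like(np.asarray(tile, dtype=float), lo)
    return (np.asarray(tile, dtype=float) + 1.0) / 2.0 * (hi - lo) + lo


@dataclass
class TrainingPair:
    """One normalized intensity tile and its phase target.

    ``intensity_norm`` and ``phase_norm`` are the (min, max) records that
    invert the [-1, 1] normalization; ``source_id`` identifies the
    physical object the tile came from (split hygiene is enforced on it).
    """

    intensity_tile: NDArray[np.floating]
    phase_tile: NDArray[np.floating]
    defocus_z_um: float
    intensity_norm: tuple[float, float]
    phase_norm: tuple[float, float]
    source_id: str

    def __post_init__(self) -> None:
        if self.intensity_tile.shape != self.phase_tile.shape:
            raise ValueError("intensity and phase tiles must share a shape")


@dataclass
class DatasetSplit:
    """Train/validation/test partition of training pairs.

    ``phase_range`` is the dataset-global (min, max) in radians used to
    normalize every phase tile; it is what makes inferred phase maps
    quantitative.
    """

    train: list[TrainingPair]
    validation: list[TrainingPair]
    test: list[TrainingPair]
    seed: int
    phase_range: tuple[float, float]

    def source_ids(self, split: str) -> set[str]:
        return {p.source_id for p in getattr(self, split)}


def extract_rois(
    frame: NDArray[np.floating],
    centers: Sequence[tuple[int, int]],
    tile: int = 256,
) -> list[NDArray[np.floating]]:
    """Cut tile x tile regions of interest around pixel centers.

    ``centers`` are (x, y) pixel coordinates (column, row).  Centers
    closer than tile/2 to an edge are rejected with a diagnostic naming
    the offending coordinates.  Pixel values are copied unmodified.
    """
    if tile % 2:
        raise ValueError("tile size must be even")
    frame = np.asarray(frame)
    ny, nx = frame.shape
    half = tile // 2
    out = []
    for cx, cy in centers:
        if not (half <= cx <= nx - half and half <= cy <= ny - half):
            raise ValueError(
                f"ROI center ({cx}, {cy}) is closer than {half} px to the edge "
                f"of a {nx} x {ny} frame"
            )
        out.append(frame[cy - half : cy + half, cx - half : cx + half].copy())
    return out


def build_pairs(
    stacks: Sequence[IntensityStack],
    phases: Sequence[PhaseMap],
    z_selection: Literal["all"] | Sequence[float] = "all",
    split_sizes: tuple[int, int, int] = (700, 100, 100),
    seed: int = 0,
    mismatched_fraction: float = 0.0,
) -> DatasetSplit:
    """Pair defocused frames with their stack's TIE phase map and split.

    Each selected frame of stack ``i`` becomes one pair targeting
    ``phases[i]`` (one phase map per stack -- this is what teaches the
    network defocus robustness).  The split is disjoint by source
    object: all pairs from one stack land in the same split.  Whole
    stacks are dealt to train, validation, then test in seeded shuffled
    order, and each split is truncated (seeded) to the exact requested
    size.

    ``mismatched_fraction`` deliberately re-targets that fraction of
    the *training* pairs onto a different object's phase map, a
    regularization sometimes used to keep the discriminator from
    saturating; off by default.
    """
    if len(stacks) != len(phases):
        raise ValueError(
            f"got {len(stacks)} stacks but {len(phases)} phase maps"
        )
    n_train, n_val, n_test = split_sizes
    rng = np.random.default_rng(seed)

    lo = min(float(p.phase_rad.min()) for p in phases)
    hi = max(float(p.phase_rad.max()) for p in phases)
    phase_range = (lo, hi)

    per_source: list[list[TrainingPair]] = []
    for i, (stack, phase) in enumerate(zip(stacks, phases)):
        sid = f"obj{i:04d}"
        ph_norm, _ = normalize_tile(phase.phase_rad, phase_range)
        pairs = []
        for z, frame in zip(stack.z_positions_um, stack.frames):
            if z_selection != "all" and not any(
                np.isclose(z, zz) for zz in z_selection
            ):
                continue
            inten, irec = normalize_tile(frame)
            pairs.append(
                TrainingPair(inten, ph_norm, float(z), irec, phase_range, sid)
            )
        per_source.append(pairs)

    total = sum(len(p) for p in per_source)
    if n_train + n_val + n_test > total:
        raise ValueError(
            f"requested split sizes {split_sizes} exceed the {total} available pairs"
        )

    order = rng.permutation(len(per_source))
    splits: list[list[TrainingPair]] = [[], [], []]
    wanted = [n_train, n_val, n_test]
    cursor = 0
    for k in range(3):
        while len(splits[k]) < wanted[k]:
            if cursor >= len(order):
                raise ValueError("ran out of source objects while splitting")
            splits[k].extend(per_source[order[cursor]])
            cursor += 1
        if len(splits[k]) > wanted[k]:
            keep = rng.permutation(len(splits[k]))[: wanted[k]]
            splits[k] = [splits[k][j] for j in sorted(keep)]

    if mismatched_fraction > 0 and len(splits[0]) > 1:
        n_swap = int(round(mismatched_fraction * len(splits[0])))
        for j in rng.choice(len(splits[0]), size=n_swap, replace=False):
            others = [
                p for p in splits[0] if p.source_id != splits[0][j].source_id
            ]
            donor = others[int(rng.integers(len(others)))]
            splits[0][j] = TrainingPair(
                splits[0][j].intensity_tile,
                donor.phase_tile,
                splits[0][j].defocus_z_um,
                splits[0][j].intensity_norm,
                donor.phase_norm,
                splits[0][j].source_id,
            )
    return DatasetSplit(splits[0], splits[1], splits[2], seed, phase_range)


_SPLITS = ("train", "validation", "test")


def save_dataset_h5(split: DatasetSplit, path: str | Path) -> None:
    """Write a dataset to HDF5 (groups train/validation/test)."""
    with h5py.File(path, "w") as f:
        f.attrs["seed"] = split.seed
        f.attrs["phase_range"] = split.phase_range
        for name in _SPLITS:
            pairs = getattr(split, name)
            g = f.create_group(name)
            if not pairs:
                continue
            g.create_dataset(
                "intensity", data=np.stack([p.intensity_tile for p in pairs])
            )
            g.create_dataset("phase", data=np.stack([p.phase_tile for p in pairs]))
            g.create_dataset("z", data=[p.defocus_z_um for p in pairs])
            g.create_dataset(
                "norm_min",
                data=[[p.intensity_norm[0], p.phase_norm[0]] for p in pairs],
            )
            g.create_dataset(
                "norm_max",
                data=[[p.intensity_norm[1], p.phase_norm[1]] for p in pairs],
            )
            g.create_dataset(
                "source_id",
                data=np.array([p.source_id for p in pairs], dtype="S"),
            )


def load_dataset_h5(path: str | Path) -> DatasetSplit:
    """Read a dataset written by :func:`save_dataset_h5`."""
    with h5py.File(path, "r") as f:
        phase_range = tuple(float(v) for v in f.attrs["phase_range"])
        out: dict[str, list[TrainingPair]] = {}
        for name in _SPLITS:
            g = f[name]
            pairs: list[TrainingPair] = []
            if "intensity" in g:
                n = g["intensity"].shape[0]
                for i in range(n):
                    pairs.append(
                        TrainingPair(
                            g["intensity"][i],
                            g["phase"][i],
                            float(g["z"][i]),
                            (float(g["norm_min"][i, 0]), float(g["norm_max"][i, 0])),
                            (float(g["norm_min"][i, 1]), float(g["norm_max"][i, 1])),
                            g["source_id"][i].decode(),
                        )
                    )
            out[name] = pairs
        return DatasetSplit(
            out["train"],
            out["validation"],
            out["test"],
            int(f.attrs["seed"]) if "seed" in f.attrs else 0,
            phase_range,
        )


def save_dataset_png(split: DatasetSplit, out_dir: str | Path) -> None:
    """Write the dataset as paired 16-bit PNG directories plus a JSON index."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    index: dict = {"seed": split.seed, "phase_range": split.phase_range, "splits": {}}
    for name in _SPLITS:
        pairs = getattr(split, name)
        d = out_dir / name
        d.mkdir(parents=True, exist_ok=True)
        entries = []
        for i, p in enumerate(pairs):
            for kind, tile in (("intensity", p.intensity_tile), ("phase", p.phase_tile)):
                img = np.round((tile + 1.0) / 2.0 * 65535.0).astype(np.uint16)
                iio.imwrite(d / f"{i:05d}_{kind}.png", img)
            entries.append(
                {
                    "z_um": p.defocus_z_um,
                    "intensity_norm": list(p.intensity_norm),
                    "phase_norm": list(p.phase_norm),
                    "source_id": p.source_id,
                }
            )
        index["splits"][name] = entries
    (out_dir / "index.json").write_text(json.dumps(index, indent=1))


def load_dataset_png(out_dir: str | Path) -> DatasetSplit:
    """Read a dataset written by :func:`save_dataset_png`.

    16-bit quantization limits the round-trip to ~1/65535 of each
    tile's range.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    index = json.loads((out_dir / "index.json").read_text())
    out: dict[str, list[TrainingPair]] = {}
    for name in _SPLITS:
        pairs = []
        for i, e in enumerate(index["splits"][name]):
            tiles = {}
            for kind in ("intensity", "phase"):
                img = iio.imread(out_dir / name / f"{i:05d}_{kind}.png")
                tiles[kind] = img.astype(float) / 65535.0 * 2.0 - 1.0
            pairs.append(
                TrainingPair(
                    tiles["intensity"],
                    tiles["phase"],
                    float(e["z_um"]),
                    tuple(e["intensity_norm"]),
                    tuple(e["phase_norm"]),
                    e["source_id"],
                )
            )
        out[name] = pairs
    return DatasetSplit(
        out["train"],
        out["validation"],
        out["test"],
        int(index["seed"]),
        tuple(index["phase_range"]),
    )
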
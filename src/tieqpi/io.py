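"""Disk formats: TIFF stacks with YAML sidecars, phase maps, previews.

An intensity stack is stored as a multi-page 16-bit TIFF plus a sidecar
YAML recording the z positions, pixel pitch, wavelength and the
normalization scale that maps the 16-bit integers back to intensity
units.  Phase maps are stored as 32-bit float TIFF plus an 8-bit PNG
preview whose (min, max) in radians is recorded in a sidecar.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .phantoms import IntensityStack, OpticalConfig
from .tie import PhaseMap

__all__ = [
    "save_stack",
    "load_stack",
    "save_phase",
    "load_phase",
]


def save_stack(stack: IntensityStack, path: str | Path) -> None:
    """Write a stack as multi-page 16-bit TIFF + ``<stem>.yaml`` sidecar."""
    path = Path(path)
    scale = max(float(np.max(f)) for f in stack.frames)
    scale = scale if scale > 0 else 1.0
    pages = np.stack(
        [np.round(np.asarray(f) / scale * 65535.0).astype(np.uint16) for f in stack.frames]
    )
    tifffile.imwrite(path, pages)
    sidecar = {
        "z_positions_um": [float(z) for z in stack.z_positions_um],
        "pitch_um": float(stack.pitch_um),
        "wavelength_um": float(stack.config.wavelength_um),
        "medium_index": float(stack.config.medium_index),
        "intensity_scale": scale,
        "in_focus_index": stack.in_focus_index,
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_stack(
    path: str | Path,
    z_positions_um: list[float] | None = None,
    config: OpticalConfig | None = None,
) -> IntensityStack:
    """Read a stack written by :func:`save_stack`, or a plain TIFF/PNG
    sequence given an explicit z list.

    ``path`` may be a multi-page TIFF (with or without sidecar) or a
    directory of single-page TIFF/PNG files in sorted name order.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml") if path.is_file() else path / "stack.yaml"
    sidecar = (
        yaml.safe_load(sidecar_path.read_text()) if sidecar_path.exists() else {}
    )
    if path.is_dir():
        import imageio.v3 as iio

        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff", ".png")
        )
        frames = [np.asarray(iio.imread(p), dtype=float) for p in files]
    else:
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        frames = [np.asarray(p, dtype=float) for p in pages]
    scale = sidecar.get("intensity_scale")
    if scale:
        frames = [f / 65535.0 * scale for f in frames]
    z = z_positions_um or sidecar.get("z_positions_um")
    if z is None:
        raise ValueError(f"no z positions: pass z_positions_um or provide {sidecar_path}")
    if len(z) != len(frames):
        raise ValueError(f"{len(z)} z positions for {len(frames)} frames")
    cfg = config or OpticalConfig()
    if "wavelength_um" in sidecar:
        cfg = OpticalConfig(
            wavelength_um=sidecar["wavelength_um"],
            camera_pixel_um=sidecar.get("pitch_um", cfg.pitch_um)
            * cfg.magnification,
            magnification=cfg.magnification,
            numerical_aperture=cfg.numerical_aperture,
            medium_index=sidecar.get("medium_index", cfg.medium_index),
        )
    return IntensityStack(
        list(z),
        frames,
        float(sidecar.get("pitch_um", cfg.pitch_um)),
        cfg,
        in_focus_index=sidecar.get("in_focus_index"),
    )


def save_phase(phase: PhaseMap, path: str | Path) -> None:
    """Write phase as 32-bit float TIFF + 8-bit PNG preview + sidecar."""
    import imageio.v3 as iio

    path = Path(path)
    tifffile.imwrite(path, phase.phase_rad.astype(np.float32))
    preview = phase.to_uint8()  # records (min, max) on the map
    iio.imwrite(path.with_suffix(".png"), preview)
    sidecar = {
        "pitch_um": float(phase.pitch_um),
        "preview_min_rad": phase.normalization[0],
        "preview_max_rad": phase.normalization[1],
    }
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def load_phase(path: str | Path) -> PhaseMap:
    """Read a phase map written by :func:`save_phase`."""
    path = Path(path)
    arr = np.asarray(tifffile.imread(path), dtype=float)
    sidecar_path = path.with_suffix(".yaml")
    pitch = 0.086250
    norm = None
    if sidecar_path.exists():
        sidecar = yaml.safe_load(sidecar_path.read_text())
        pitch = sidecar.get("pitch_um", pitch)
        if "preview_min_rad" in sidecar:
            norm = (sidecar["preview_min_rad"], sidecar["preview_max_rad"])
    return PhaseMap(arr, pitch, normalization=norm)
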
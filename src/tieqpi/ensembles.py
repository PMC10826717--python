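"""Randomized phantom ensembles: the synthetic study conditions.

Produces populations of bead fields and cell-like fields together with
their through-focus stacks and conventional-TIE ground-truth phase
maps, emulating the experimental protocol: a z-stack per object over
+/-60 um in 15 um steps, the in-focus TIE reconstruction as the phase
target, every defocused frame as a potential network input.

The default geometry is a scaled-down field of view (64 px tiles at a
0.1725 um object pitch, i.e. a 20x view of an 11 um patch) so that
ensembles of tens of objects simulate and train in minutes on a CPU;
the optical constants keep their experimental values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .phantoms import (
    BeadSpec,
    CellSpec,
    ComplexField,
    IntensityStack,
    OpticalConfig,
    generate_stack,
    make_bead_field,
    make_cell_field,
)
from .tie import PhaseMap, TieConfig, tie_solve

__all__ = [
    "DEFAULT_Z_UM",
    "scaled_optics",
    "bead_ensemble",
    "cell_ensemble",
    "simulate_training_set",
]

#: The recorded defocus planes: +/-60 um in 15 um steps.
DEFAULT_Z_UM: tuple[float, ...] = (-60.0, -45.0, -30.0, -15.0, 0.0, 15.0, 30.0, 45.0, 60.0)


def scaled_optics(magnification: float = 20.0) -> OpticalConfig:
    """Experimental optical constants at a reduced magnification.

    Lowering the magnification from 40x to 20x doubles the object-plane
    pitch (0.1725 um), so a 64 px tile covers an 11 um field -- enough
    for a handful of beads or one small cell while keeping FFTs cheap.
    """
    return OpticalConfig(magnification=magnification)


def bead_ensemble(
    n_fields: int,
    shape: tuple[int, int] = (64, 64),
    config: OpticalConfig | None = None,
    seed: int = 0,
    n_beads: tuple[int, int] = (4, 8),
    diameter_um: tuple[float, float] = (2.0, 4.0),
    attenuation_per_um: float = 0.0,
) -> list[ComplexField]:
    """Random fields of non-identical microbeads.

    Each field holds ``n_beads`` (uniform in the half-open range) beads
    with diameters drawn from ``diameter_um``, positioned so every bead
    fits the field of view.  Bead refractive index is the polystyrene
    value (1.68) against water (1.33).
    """
    config = config or scaled_optics()
    rng = np.random.default_rng(seed)
    half_x = shape[1] * config.pitch_um / 2.0
    half_y = shape[0] * config.pitch_um / 2.0
    fields = []
    for _ in range(n_fields):
        grid = None
        for _ in range(int(rng.integers(n_beads[0], n_beads[1]))):
            d = float(rng.uniform(*diameter_um))
            r = d / 2.0
            cx = float(rng.uniform(-(half_x - r - 0.1), half_x - r - 0.1))
            cy = float(rng.uniform(-(half_y - r - 0.1), half_y - r - 0.1))
            spec = BeadSpec(
                diameter_um=d,
                attenuation_per_um=attenuation_per_um,
                centers=((cx, cy),),
            )
            f = make_bead_field(spec, shape, config)
            grid = f.grid if grid is None else grid * f.grid
        fields.append(ComplexField(grid, config.pitch_um))
    return fields


def cell_ensemble(
    n_fields: int,
    shape: tuple[int, int] = (64, 64),
    config: OpticalConfig | None = None,
    seed: int = 0,
    radius_um: tuple[float, float] = (2.5, 4.0),
    smoothness_um: float = 1.0,
) -> list[ComplexField]:
    """Random unstained-cell-like pure-phase fields (one cell per field)."""
    config = config or scaled_optics()
    rng = np.random.default_rng(seed)
    fields = []
    for _ in range(n_fields):
        spec = CellSpec(
            radius_um=float(rng.uniform(*radius_um)),
            nucleus_radius_um=float(rng.uniform(0.8, 1.5)),
            smoothness_um=smoothness_um,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        fields.append(make_cell_field(spec, shape, config))
    return fields


def simulate_training_set(
    fields: Sequence[ComplexField],
    z_list: Sequence[float] = DEFAULT_Z_UM,
    config: OpticalConfig | None = None,
    tie_config: TieConfig | None = None,
    noise_photons: float | None = None,
    seed: int = 0,
) -> tuple[list[IntensityStack], list[PhaseMap]]:
    """Record a stack per field and reconstruct its in-focus TIE phase.

    Returns (stacks, phase maps); the phase maps are the conventional
    TIE reconstructions that serve as training targets and evaluation
    ground truth, exactly as in the experimental dataset protocol.
    """
    config = config or scaled_optics()
    tie_config = tie_config or TieConfig()
    rng = np.random.default_rng(seed)
    stacks, phases = [], []
    for field in fields:
        stack = generate_stack(
            field,
            list(z_list),
            config,
            noise_photons=noise_photons,
            seed=int(rng.integers(0, 2**31 - 1)) if noise_photons else None,
        )
        stacks.append(stack)
        phases.append(tie_solve(stack, tie_config, config))
    return stacks, phases
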
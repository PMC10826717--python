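"""Synthetic phase-object phantoms and scalar free-space propagation.

This module generates the complex object fields used throughout the
pipeline -- polystyrene-like microbeads immersed in water and smooth
cell-like phase blobs -- and propagates them to arbitrary defocus planes
with the angular-spectrum method, producing through-focus intensity
stacks like the ones a brightfield microscope with a motorized z-stage
records.

Units are micrometres everywhere; phase is in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import gaussian_filter

__all__ = [
    "OpticalConfig",
    "ComplexField",
    "BeadSpec",
    "CellSpec",
    "IntensityStack",
    "make_bead_field",
    "make_cell_field",
    "propagate",
    "generate_stack",
]


@dataclass(frozen=True)
class OpticalConfig:
    """Physical constants of the imaging system.

    The defaults describe a red LED (spectrally weighted mean wavelength
    627 nm), a 3.45 um camera pixel behind a 40x / 0.65 NA objective, and
    a water immersion medium (n = 1.33).  The object-plane sampling is
    the camera pixel divided by the magnification: 0.086250 um at the
    defaults.
    """

    wavelength_um: float = 0.627
    camera_pixel_um: float = 3.45
    magnification: float = 40.0
    numerical_aperture: float = 0.65
    medium_index: float = 1.33

    def __post_init__(self) -> None:
        if self.wavelength_um <= 0:
            raise ValueError("wavelength_um must be positive")
        if self.magnification <= 0:
            raise ValueError("magnification must be positive")
        if not (0 < self.numerical_aperture < self.medium_index):
            raise ValueError(
                "numerical_aperture must lie in (0, medium_index); got "
                f"NA={self.numerical_aperture}, n={self.medium_index}"
            )

    @property
    def pitch_um(self) -> float:
        """Object-plane sampling interval (camera pixel / magnification)."""
        return self.camera_pixel_um / self.magnification


@dataclass
class ComplexField:
    """A 2-D complex scalar field u(x, y) = A(x, y) exp(i phi(x, y)).

    ``grid`` is the complex amplitude on a uniformly sampled grid with
    pixel pitch ``pitch_um``.  Intensity is ``|u|**2`` and phase is
    ``angle(u)``.
    """

    grid: NDArray[np.complexfloating]
    pitch_um: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.complex128)
        if self.grid.ndim != 2:
            raise ValueError("field grid must be 2-D")
        if any(s % 2 for s in self.grid.shape):
            raise ValueError("field grid sides must be even (FFT friendliness)")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("field grid contains non-finite entries")
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def intensity(self) -> NDArray[np.floating]:
        return np.abs(self.grid) ** 2

    @property
    def phase(self) -> NDArray[np.floating]:
        return np.angle(self.grid)

    @property
    def power(self) -> float:
        """Total power: sum of |u|^2 times the pixel area."""
        return float(np.sum(self.intensity)) * self.pitch_um**2


@dataclass(frozen=True)
class BeadSpec:
    """Spherical microbead phantom.

    Defaults describe 4 um polystyrene-like beads (n = 1.68) in water
    (n = 1.33) with a linear attenuation coefficient of 0.843 um^-1.
    ``centers`` are (x, y) positions in micrometres relative to the
    field centre.
    """

    diameter_um: float = 4.0
    bead_index: float = 1.68
    attenuation_per_um: float = 0.843
    centers: tuple[tuple[float, float], ...] = ((0.0, 0.0),)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ValueError("diameter_um must be positive")


@dataclass(frozen=True)
class CellSpec:
    """Smooth random phase blob emulating an unstained cell.

    The phantom is a band-limited random texture confined to an
    elliptical cytoplasm with a denser nucleus; phase is non-negative
    and reproducible for a fixed seed.  Phase ranges are (low, high)
    bounds in radians; ``smoothness_um`` is the shortest spatial period
    retained by the band-limiting filter.
    """

    cytoplasm_phase_rad: tuple[float, float] = (0.3, 1.2)
    nucleus_phase_rad: tuple[float, float] = (1.0, 2.5)
    smoothness_um: float = 2.0
    radius_um: float = 8.0
    nucleus_radius_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.cytoplasm_phase_rad, self.nucleus_phase_rad):
            if lo < 0 or hi < lo:
                raise ValueError("phase ranges must satisfy 0 <= low <= high")
        if self.smoothness_um <= 0:
            raise ValueError("smoothness_um must be positive")


@dataclass
class IntensityStack:
    """Through-focus intensity stack: one frame per axial position."""

    z_positions_um: list[float]
    frames: list[NDArray[np.floating]]
    pitch_um: float
    config: OpticalConfig = field(default_factory=OpticalConfig)
    in_focus_index: int | None = None

    def __post_init__(self) -> None:
        if len(self.z_positions_um) != len(self.frames):
            raise ValueError("one frame is required per z position")
        z = np.asarray(self.z_positions_um, dtype=float)
        if len(z) > 1 and not np.all(np.diff(z) > 0):
            raise ValueError("z_positions_um must be strictly increasing")
        for fr in self.frames:
            if np.any(np.asarray(fr) < 0):
                raise ValueError("intensity frames must be non-negative")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_at(self, z_um: float, atol: float = 1e-9) -> NDArray[np.floating]:
        z = np.asarray(self.z_positions_um)
        i = int(np.argmin(np.abs(z - z_um)))
        if abs(z[i] - z_um) > atol:
            raise KeyError(
                f"no frame at z = {z_um} um; available z: {list(z)}"
            )
        return self.frames[i]


def _grid_coords(shape: tuple[int, int], pitch: float):
    """Centred physical coordinates (um) for a grid; x along axis 1."""
    ny, nx = shape
    y = (np.arange(ny) - ny / 2) * pitch
    x = (np.arange(nx) - nx / 2) * pitch
    return np.meshgrid(x, y)  # X, Y each (ny, nx)


def make_bead_field(
    spec: BeadSpec,
    shape: tuple[int, int] = (256, 256),
    config: OpticalConfig | None = None,
) -> ComplexField:
    """Complex field directly behind a plane of spherical beads.

    Under the projection approximation a sphere of diameter d at
    transverse distance rho from its centre has thickness
    h(rho) = 2 sqrt((d/2)^2 - rho^2).  The optical phase is
    phi = 2 pi (n_bead - n_medium) h / lambda and the amplitude is
    exp(-mu h / 2) for an intensity attenuation coefficient mu.

    Raises ``ValueError`` if any bead does not fit inside the field of
    view.
    """
    config = config or OpticalConfig()
    pitch = config.pitch_um
    X, Y = _grid_coords(shape, pitch)
    r = spec.diameter_um / 2.0
    half_x = shape[1] * pitch / 2.0
    half_y = shape[0] * pitch / 2.0
    thickness = np.zeros(shape, dtype=float)
    for cx, cy in spec.centers:
        if abs(cx) + r > half_x or abs(cy) + r > half_y:
            raise ValueError(
                f"bead at ({cx}, {cy}) um with radius {r} um does not fit in "
                f"the {2 * half_x:.2f} x {2 * half_y:.2f} um field of view"
            )
        rho2 = (X - cx) ** 2 + (Y - cy) ** 2
        inside = rho2 < r**2
        thickness[inside] += 2.0 * np.sqrt(r**2 - rho2[inside])
    delta_n = spec.bead_index - config.medium_index
    phase = 2.0 * np.pi * delta_n * thickness / config.wavelength_um
    amplitude = np.exp(-spec.attenuation_per_um * thickness / 2.0)
    return ComplexField(amplitude * np.exp(1j * phase), pitch)


def make_cell_field(
    spec: CellSpec,
    shape: tuple[int, int] = (256, 256),
    config: OpticalConfig | None = None,
) -> ComplexField:
    """Pure-phase cell-like phantom: smooth random blob plus nucleus.

    A white-noise texture is hard band-limited in the Fourier domain at
    the cutoff 1 / smoothness_um, rescaled into the requested phase
    ranges, and confined to a soft elliptical cytoplasm mask with a
    denser off-centre nucleus.  Output is deterministic for a fixed
    ``spec.seed``.
    """
    config = config or OpticalConfig()
    pitch = config.pitch_um
    rng = np.random.default_rng(spec.seed)
    ny, nx = shape

    noise = rng.standard_normal(shape)
    fy = np.fft.fftfreq(ny, d=pitch)
    fx = np.fft.fftfreq(nx, d=pitch)
    FX, FY = np.meshgrid(fx, fy)
    cutoff = 1.0 / spec.smoothness_um
    keep = FX**2 + FY**2 <= cutoff**2
    texture = np.real(np.fft.ifft2(np.fft.fft2(noise) * keep))
    span = texture.max() - texture.min()
    if span > 0:
        texture = (texture - texture.min()) / span  # -> [0, 1]

    X, Y = _grid_coords(shape, pitch)
    # mild random ellipticity and nucleus offset make fields distinct
    ecc = 1.0 + 0.3 * rng.uniform(-1, 1)
    cnx, cny = rng.uniform(-0.2, 0.2, 2) * spec.radius_um
    rho_c = np.sqrt((X / ecc) ** 2 + (Y * ecc) ** 2) / spec.radius_um
    rho_n = np.sqrt((X - cnx) ** 2 + (Y - cny) ** 2) / spec.nucleus_radius_um
    # super-Gaussian masks: ~1 inside, smooth roll-off at the boundary
    cyto = np.exp(-(rho_c**8))
    nucl = np.exp(-(rho_n**4))

    c_lo, c_hi = spec.cytoplasm_phase_rad
    n_lo, n_hi = spec.nucleus_phase_rad
    # nucleus blends over (not adds to) the cytoplasm so the peak phase
    # stays within the nucleus range
    cyto_part = cyto * (c_lo + (c_hi - c_lo) * texture)
    nucl_part = n_lo + (n_hi - n_lo) * texture
    phase = cyto_part * (1.0 - nucl) + nucl * nucl_part
    # re-apply the band limit (masking reintroduces high frequencies at
    # the smooth boundary), then lift by the minimum: a DC shift stays
    # inside the band, so the field is band-limited AND non-negative
    phase = np.real(np.fft.ifft2(np.fft.fft2(phase) * keep))
    if phase.min() < 0.0:
        phase = phase - phase.min()
    return ComplexField(np.exp(1j * phase), pitch)


def _transfer_function(
    shape: tuple[int, int],
    pitch: float,
    dz_um: float,
    config: OpticalConfig,
    model: Literal["angular_spectrum", "fresnel"],
) -> NDArray[np.complexfloating]:
    ny, nx = shape
    fy = np.fft.fftfreq(ny, d=pitch)
    fx = np.fft.fftfreq(nx, d=pitch)
    FX, FY = np.meshgrid(fx, fy)
    f2 = FX**2 + FY**2
    n_over_lambda = config.medium_index / config.wavelength_um
    if model == "angular_spectrum":
        arg = n_over_lambda**2 - f2
        kz = np.sqrt(np.clip(arg, 0.0, None))
        H = np.exp(2j * np.pi * dz_um * kz)
        H[arg < 0] = 0.0  # evanescent components removed
    elif model == "fresnel":
        H = np.exp(
            2j * np.pi * n_over_lambda * dz_um
            - 1j * np.pi * config.wavelength_um / config.medium_index * dz_um * f2
        )
    else:
        raise ValueError(f"unknown propagation model: {model!r}")
    return H


def propagate(
    field: ComplexField,
    dz_um: float,
    config: OpticalConfig | None = None,
    model: Literal["angular_spectrum", "fresnel"] = "angular_spectrum",
    pad: bool = False,
) -> ComplexField:
    """Propagate a field by a signed axial distance dz (um).

    The default is the exact scalar angular-spectrum transfer function
    H = exp(i 2 pi dz sqrt((n/lambda)^2 - u^2 - v^2)) with evanescent
    components set to zero; ``model="fresnel"`` selects the paraxial
    (Fresnel) transfer function instead.  With ``pad=True`` the field
    is edge-padded to twice its size before the FFT and cropped back,
    suppressing periodic wrap-around at the cost of exact unitarity.
    """
    config = config or OpticalConfig()
    if dz_um == 0.0:
        return ComplexField(field.grid.copy(), field.pitch_um)
    u = field.grid
    if pad:
        ny, nx = u.shape
        u = np.pad(u, ((ny // 2, ny // 2), (nx // 2, nx // 2)), mode="edge")
    H = _transfer_function(u.shape, field.pitch_um, dz_um, config, model)
    out = np.fft.ifft2(np.fft.fft2(u) * H)
    if pad:
        out = out[ny // 2 : ny // 2 + ny, nx // 2 : nx // 2 + nx]
    return ComplexField(out, field.pitch_um)


def generate_stack(
    field: ComplexField,
    z_list: Sequence[float],
    config: OpticalConfig | None = None,
    noise_photons: float | None = None,
    seed: int | None = None,
    model: Literal["angular_spectrum", "fresnel"] = "angular_spectrum",
) -> IntensityStack:
    """Record the through-focus intensity stack of an object field.

    ``z_list`` must be sorted ascending (um).  Propagation uses internal
    2x edge padding to suppress wrap-around artefacts.  If
    ``noise_photons`` is given, Poisson shot noise with that expected
    photon count per pixel at unit intensity is applied (seeded), and
    frames are rescaled back to intensity units.
    """
    config = config or OpticalConfig()
    z = list(z_list)
    if not z:
        raise ValueError("z_list must be non-empty")
    if any(b <= a for a, b in zip(z, z[1:])):
        raise ValueError(f"z_list must be sorted strictly ascending, got {z}")
    rng = np.random.default_rng(seed) if noise_photons is not None else None
    frames = []
    for dz in z:
        out = propagate(field, dz, config, model=model, pad=True)
        frame = out.intensity
        if rng is not None:
            frame = rng.poisson(frame * noise_photons) / noise_photons
        frames.append(frame)
    z_arr = np.asarray(z, float)
    focus = int(np.argmin(np.abs(z_arr))) if np.min(np.abs(z_arr)) < 1e-9 else None
    return IntensityStack(z, frames, field.pitch_um, config, in_focus_index=focus)
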
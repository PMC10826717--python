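"""Transport-of-intensity phase retrieval.

The transport of intensity equation (TIE) relates the axial derivative
of intensity of a paraxial beam to its transverse phase:

    dI/dz = -(lambda / 2 pi) div(I grad phi)

Given an in-focus frame and a symmetric defocus pair, the phase follows
from two FFT Poisson solves (Teague's auxiliary-function solution):

    phi = invlap[ div( (1/I) grad invlap( -(2 pi / lambda) dI/dz ) ) ]

The solver here implements that solution with a regularized spectral
inverse Laplacian, mirror (Neumann-like) or periodic boundaries, and an
intensity floor guarding the 1/I division.  A Tamura-coefficient
autofocus picks the in-focus frame of a stack, and measured phase is
converted to physical thickness via h = lambda phi / (2 pi delta_n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from numpy.typing import NDArray

from .phantoms import IntensityStack, OpticalConfig

__all__ = [
    "PhaseMap",
    "TieConfig",
    "ThicknessMap",
    "axial_derivative",
    "inverse_laplacian",
    "tie_solve",
    "tamura_coefficient",
    "select_focus",
    "phase_to_thickness",
]


@dataclass
class PhaseMap:
    """A 2-D phase image in radians with its physical pixel pitch.

    ``normalization`` records the (min, max) in radians used when the
    map was rendered to 8 bits, permitting quantitative inversion.
    """

    phase_rad: NDArray[np.floating]
    pitch_um: float
    normalization: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.phase_rad = np.asarray(self.phase_rad, dtype=float)
        if not np.all(np.isfinite(self.phase_rad)):
            raise ValueError("phase map contains non-finite values")

    def to_uint8(self) -> NDArray[np.uint8]:
        """Render to 8 bits, storing the normalization record."""
        lo = float(self.phase_rad.min())
        hi = float(self.phase_rad.max())
        self.normalization = (lo, hi)
        span = hi - lo if hi > lo else 1.0
        return np.round((self.phase_rad - lo) / span * 255.0).astype(np.uint8)

    @classmethod
    def from_uint8(
        cls, img: NDArray[np.uint8], normalization: tuple[float, float], pitch_um: float
    ) -> "PhaseMap":
        lo, hi = normalization
        phase = img.astype(float) / 255.0 * (hi - lo) + lo
        return cls(phase, pitch_um, normalization=normalization)


@dataclass(frozen=True)
class TieConfig:
    """Numerical knobs of the TIE solver.

    ``poisson_regularizer_eps`` is added to the spectral denominator
    4 pi^2 (u^2 + v^2) of the inverse Laplacian (units um^-2); the DC
    mode is always nulled.  ``intensity_floor_fraction`` clamps the
    in-focus intensity at that fraction of its maximum before the 1/I
    division.  ``boundary="mirror"`` evaluates all spectral operators on
    the even (reflected) extension of the field, suppressing periodic
    wrap-around artefacts.
    """

    derivative_scheme: Literal["central", "forward"] = "central"
    poisson_regularizer_eps: float = 0.0
    intensity_floor_fraction: float = 1e-3
    boundary: Literal["mirror", "periodic"] = "mirror"

    def __post_init__(self) -> None:
        if self.poisson_regularizer_eps < 0:
            raise ValueError("poisson_regularizer_eps must be >= 0")
        if not (0 < self.intensity_floor_fraction < 1):
            raise ValueError("intensity_floor_fraction must lie in (0, 1)")


@dataclass
class ThicknessMap:
    """Physical thickness h(x, y) in micrometres with the delta-n used."""

    thickness_um: NDArray[np.floating]
    delta_n: float
    pitch_um: float


def _freqs(shape: tuple[int, int], pitch: float):
    fy = np.fft.fftfreq(shape[0], d=pitch)
    fx = np.fft.fftfreq(shape[1], d=pitch)
    return np.meshgrid(fx, fy)  # FX, FY


def _mirror_extend(f: NDArray) -> NDArray:
    """Even 2x2 reflection: makes spectral operators Neumann-like."""
    top = np.concatenate([f, f[:, ::-1]], axis=1)
    return np.concatenate([top, top[::-1, :]], axis=0)


def axial_derivative(
    stack: IntensityStack,
    at_z: float = 0.0,
    config: TieConfig | None = None,
) -> NDArray[np.floating]:
    """Estimate dI/dz (intensity per um) at an axial position.

    The central scheme uses the symmetric neighbours of ``at_z``:
    (I(z + dz) - I(z - dz)) / (2 dz); the forward scheme uses ``at_z``
    and its next neighbour.  Raises ``ValueError`` naming the available
    planes if the required frames are missing.
    """
    config = config or TieConfig()
    z = np.asarray(stack.z_positions_um, float)
    i0 = int(np.argmin(np.abs(z - at_z)))
    if abs(z[i0] - at_z) > 1e-9:
        raise ValueError(f"no frame at z = {at_z} um; available z: {list(z)}")
    if config.derivative_scheme == "central":
        if i0 == 0 or i0 == len(z) - 1:
            raise ValueError(
                f"central derivative at z = {at_z} um needs both neighbours; "
                f"available z: {list(z)}"
            )
        dz_minus = z[i0] - z[i0 - 1]
        dz_plus = z[i0 + 1] - z[i0]
        if not np.isclose(dz_minus, dz_plus):
            raise ValueError(
                f"central derivative needs equal spacing around z = {at_z}; "
                f"got {dz_minus} and {dz_plus} um"
            )
        return (stack.frames[i0 + 1] - stack.frames[i0 - 1]) / (2.0 * dz_plus)
    if i0 == len(z) - 1:
        raise ValueError(
            f"forward derivative at z = {at_z} um needs the next plane; "
            f"available z: {list(z)}"
        )
    return (stack.frames[i0 + 1] - stack.frames[i0]) / (z[i0 + 1] - z[i0])


def inverse_laplacian(
    f: NDArray[np.floating],
    pitch_um: float,
    config: TieConfig | None = None,
) -> NDArray[np.floating]:
    """Solve the Poisson equation lap(g) = f spectrally.

    The Fourier symbol of the Laplacian is -4 pi^2 (u^2 + v^2); the DC
    mode is nulled (the solution is defined up to a constant, returned
    with zero mean).  With mirror boundaries the field is evenly
    extended before the FFT and the result cropped back.
    """
    config = config or TieConfig()
    f = np.asarray(f, dtype=float)
    ny, nx = f.shape
    work = _mirror_extend(f) if config.boundary == "mirror" else f
    FX, FY = _freqs(work.shape, pitch_um)
    denom = -(4.0 * np.pi**2 * (FX**2 + FY**2) + config.poisson_regularizer_eps)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(denom != 0.0, 1.0 / np.where(denom == 0.0, 1.0, denom), 0.0)
    inv[0, 0] = 0.0  # DC nulled even when eps > 0
    g = np.real(np.fft.ifft2(np.fft.fft2(work) * inv))
    g = g[:ny, :nx]
    return g - g.mean()


def _spectral_gradient(f: NDArray, pitch: float, mirror: bool):
    ny, nx = f.shape
    work = _mirror_extend(f) if mirror else f
    FX, FY = _freqs(work.shape, pitch)
    F = np.fft.fft2(work)
    gx = np.real(np.fft.ifft2(2j * np.pi * FX * F))[:ny, :nx]
    gy = np.real(np.fft.ifft2(2j * np.pi * FY * F))[:ny, :nx]
    return gx, gy


def _spectral_divergence(vx: NDArray, vy: NDArray, pitch: float, mirror: bool):
    ny, nx = vx.shape
    if mirror:
        # odd extension keeps the vector field consistent with the even
        # extension of the scalars it was derived from
        wx = _mirror_extend(vx)
        wx[:, nx:] *= -1.0
        wy = _mirror_extend(vy)
        wy[ny:, :] *= -1.0
    else:
        wx, wy = vx, vy
    FX, FY = _freqs(wx.shape, pitch)
    dx = np.real(np.fft.ifft2(2j * np.pi * FX * np.fft.fft2(wx)))
    dy = np.real(np.fft.ifft2(2j * np.pi * FY * np.fft.fft2(wy)))
    return (dx + dy)[:ny, :nx]


def tie_solve(
    stack: IntensityStack,
    config: TieConfig | None = None,
    optical: OpticalConfig | None = None,
    at_z: float | None = None,
) -> PhaseMap:
    """Recover phase from an in-focus frame and a defocus pair.

    Implements Teague's two-Poisson-solve solution of the TIE.  The
    in-focus plane defaults to the stack's flagged frame (or the frame
    nearest z = 0); pass ``at_z`` to reconstruct treating another plane
    as focus.  The returned phase is mean-subtracted: the TIE determines
    phase only up to an additive constant.
    """
    config = config or TieConfig()
    optical = optical or stack.config
    if at_z is None:
        if stack.in_focus_index is not None:
            at_z = float(stack.z_positions_um[stack.in_focus_index])
        else:
            z = np.asarray(stack.z_positions_um)
            at_z = float(z[np.argmin(np.abs(z))])
    didz = axial_derivative(stack, at_z, config)
    i_focus = stack.frame_at(at_z)

    # defocus happens in the immersion medium, so the transport equation
    # sees the wavelength in the medium, lambda / n
    lam_eff = optical.wavelength_um / optical.medium_index
    rhs = -(2.0 * np.pi / lam_eff) * didz
    mirror = config.boundary == "mirror"
    psi = inverse_laplacian(rhs, stack.pitch_um, config)
    gx, gy = _spectral_gradient(psi, stack.pitch_um, mirror)
    floor = config.intensity_floor_fraction * float(i_focus.max())
    i_safe = np.maximum(i_focus, floor)
    div = _spectral_divergence(gx / i_safe, gy / i_safe, stack.pitch_um, mirror)
    phi = inverse_laplacian(div, stack.pitch_um, config)
    phi = phi - phi.mean()
    return PhaseMap(phi, stack.pitch_um)


def tamura_coefficient(image: NDArray[np.floating]) -> float:
    """Tamura sharpness: sqrt(std / mean) of pixel intensities.

    Scale-invariant (population standard deviation).  Rejects images
    with non-positive mean.
    """
    img = np.asarray(image, dtype=float)
    mu = img.mean()
    if mu <= 0:
        raise ValueError("Tamura coefficient requires a positive-mean image")
    return float(np.sqrt(img.std() / mu))


def select_focus(stack: IntensityStack, mode: Literal["min", "max"] = "min") -> int:
    """Index of the frame extremizing the Tamura coefficient.

    Pure-phase objects show least intensity contrast in focus, hence the
    default ``mode="min"``; absorbing objects are sharpest in focus and
    call for ``mode="max"``.  Ties break toward the frame nearest z = 0.
    """
    if len(stack) < 3:
        raise ValueError("focus selection needs at least 3 frames")
    values = np.array([tamura_coefficient(fr) for fr in stack.frames])
    best = values.min() if mode == "min" else values.max()
    candidates = np.flatnonzero(np.isclose(values, best, rtol=1e-12, atol=1e-12))
    z = np.asarray(stack.z_positions_um)
    return int(candidates[np.argmin(np.abs(z[candidates]))])


def phase_to_thickness(
    phase: PhaseMap,
    delta_n: float,
    optical: OpticalConfig | None = None,
) -> ThicknessMap:
    """Convert phase to physical thickness: h = lambda phi / (2 pi delta_n)."""
    if delta_n == 0:
        raise ValueError("delta_n must be non-zero")
    optical = optical or OpticalConfig()
    h = optical.wavelength_um * phase.phase_rad / (2.0 * np.pi * delta_n)
    return ThicknessMap(h, delta_n, phase.pitch_um)
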
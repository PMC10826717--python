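"""Image-quality metrics and the defocus-sweep evaluation.

Implements the four full-reference metrics used to score phase
reconstructions against ground truth -- MSE, PSNR, the universal image
quality index (UIQI), and SSIM -- plus the sweep protocol that compares
conventional TIE reconstruction and single-shot network inference at
every defocus plane of an ensemble of stacks.

Metrics are computed on 8-bit renderings of the phase maps (dynamic
range L = 255) by default, the scale on which the headline MSE/PSNR
magnitudes are meaningful; raw-radian evaluation is available by
passing the maps directly with an appropriate ``dynamic_range_L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from numpy.typing import NDArray

from .phantoms import IntensityStack
from .tie import PhaseMap, TieConfig, tie_solve

if TYPE_CHECKING:  # pragma: no cover
    from .gan.training import TrainedModel

__all__ = [
    "MetricsConfig",
    "MetricsReport",
    "mse",
    "psnr",
    "uiqi",
    "ssim",
    "evaluate_sweep",
    "render_phase_8bit",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Constants of the metric suite.

    ``dynamic_range_L`` is the L of PSNR and of the SSIM stabilizers
    c1 = (K1 L)^2, c2 = (K2 L)^2.  ``ssim_window`` sets the sliding
    window side for the windowed mean-SSIM (and windowed UIQI);
    ``windowed=False`` computes the single whole-image (global) value
    instead.  ``population_variance`` selects the divide-by-N estimator
    (default) over divide-by-(N-1).
    """

    dynamic_range_L: float = 255.0
    K1: float = 0.01
    K2: float = 0.03
    ssim_window: int = 8
    windowed: bool = True
    population_variance: bool = True

    def __post_init__(self) -> None:
        if self.dynamic_range_L <= 0:
            raise ValueError("dynamic_range_L must be positive")
        if not (0 < self.K1 < 1 and 0 < self.K2 < 1):
            raise ValueError("K1 and K2 must lie in (0, 1)")


@dataclass
class MetricsReport:
    """Per-image metric records plus aggregates for one method."""

    method: str
    records: list[dict] = field(default_factory=list)
    config: MetricsConfig = field(default_factory=MetricsConfig)

    def add(self, id: str, z_um: float, x: NDArray, y: NDArray) -> dict:
        rec = {
            "id": id,
            "z_um": float(z_um),
            "ssim": ssim(x, y, self.config),
            "mse": mse(x, y),
            "psnr": psnr(x, y, self.config),
            "uiqi": uiqi(x, y, self.config),
        }
        self.records.append(rec)
        return rec

    def aggregate(self, key: str, bins: int = 10) -> dict:
        vals = np.array([r[key] for r in self.records])
        finite = vals[np.isfinite(vals)]
        hist, edges = np.histogram(finite, bins=bins)
        return {
            "min": float(finite.min()),
            "max": float(finite.max()),
            "mean": float(finite.mean()),
            "hist": hist.tolist(),
            "hist_edges": edges.tolist(),
        }

    def per_z_mean(self, key: str) -> dict[float, float]:
        """Mean of a metric at each defocus position (the sweep curve)."""
        out: dict[float, list[float]] = {}
        for r in self.records:
            out.setdefault(r["z_um"], []).append(r[key])
        return {z: float(np.mean(v)) for z, v in sorted(out.items())}

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "records": self.records,
            "aggregates": {k: self.aggregate(k) for k in ("ssim", "mse", "psnr", "uiqi")},
        }


def _check_shapes(x: NDArray, y: NDArray) -> tuple[NDArray, NDArray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    return x, y


def mse(x: NDArray, y: NDArray) -> float:
    """Mean squared error (1/N) sum (x_i - y_i)^2."""
    x, y = _check_shapes(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: NDArray, y: NDArray, config: MetricsConfig | None = None) -> float:
    """Peak signal-to-noise ratio 10 log10(L^2 / MSE) in dB.

    Identical images have zero MSE and are reported as +inf.
    """
    config = config or MetricsConfig()
    m = mse(x, y)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(config.dynamic_range_L**2 / m))


def _moments(x: NDArray, y: NDArray, config: MetricsConfig):
    """Whole-image means, variances and covariance."""
    ddof = 0 if config.population_variance else 1
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=ddof)
    vy = y.var(ddof=ddof)
    n = x.size
    cov = float(((x - mx) * (y - my)).sum() / (n - ddof))
    return mx, my, vx, vy, cov


def _window_moments(x: NDArray, y: NDArray, config: MetricsConfig):
    """Sliding-window moments over all (valid) w x w windows."""
    w = config.ssim_window
    if min(x.shape) < w:
        raise ValueError(f"images smaller than the {w} px metric window")
    ddof = 0 if config.population_variance else 1
    xv = np.lib.stride_tricks.sliding_window_view(x, (w, w)).reshape(-1, w * w)
    yv = np.lib.stride_tricks.sliding_window_view(y, (w, w)).reshape(-1, w * w)
    mx = xv.mean(axis=1)
    my = yv.mean(axis=1)
    vx = xv.var(axis=1, ddof=ddof)
    vy = yv.var(axis=1, ddof=ddof)
    cov = ((xv - mx[:, None]) * (yv - my[:, None])).sum(axis=1) / (w * w - ddof)
    return mx, my, vx, vy, cov


def ssim(x: NDArray, y: NDArray, config: MetricsConfig | None = None) -> float:
    """Structural similarity index.

    SSIM = (2 mx my + c1)(2 cov + c2) / ((mx^2 + my^2 + c1)(vx + vy + c2))
    with c1 = (K1 L)^2, c2 = (K2 L)^2.  Windowed mode (default) averages
    the index over all sliding ``ssim_window`` windows; global mode
    evaluates it once on whole-image moments.
    """
    config = config or MetricsConfig()
    x, y = _check_shapes(x, y)
    c1 = (config.K1 * config.dynamic_range_L) ** 2
    c2 = (config.K2 * config.dynamic_range_L) ** 2
    mom = _window_moments(x, y, config) if config.windowed else _moments(x, y, config)
    mx, my, vx, vy, cov = mom
    val = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(np.mean(val))


def uiqi(
    x: NDArray,
    y: NDArray,
    config: MetricsConfig | None = None,
    stabilized: bool = True,
) -> float:
    """Universal image quality index.

    UIQI = 4 cov mx my / ((vx + vy)(mx^2 + my^2)), the product of the
    correlation, luminance and contrast factors; range [-1, 1].  With
    ``stabilized=True`` (default) the SSIM constants c1, c2 are added to
    the degenerate-prone denominators, which keeps constant images
    defined; the unstabilized form is the printed one.  Windowing
    follows ``config.windowed`` like SSIM.
    """
    config = config or MetricsConfig()
    x, y = _check_shapes(x, y)
    c1 = (config.K1 * config.dynamic_range_L) ** 2 if stabilized else 0.0
    c2 = (config.K2 * config.dynamic_range_L) ** 2 if stabilized else 0.0
    mom = _window_moments(x, y, config) if config.windowed else _moments(x, y, config)
    mx, my, vx, vy, cov = mom
    num = (2 * cov + c2) * (2 * mx * my + c1)
    den = (vx + vy + c2) * (mx**2 + my**2 + c1)
    with np.errstate(divide="ignore", invalid="ignore"):
        val = num / den
    return float(np.mean(val))


def render_phase_8bit(
    phase: PhaseMap, record: tuple[float, float]
) -> NDArray[np.floating]:
    """Render a phase map to the 0..255 scale with a shared (min, max).

    Both reconstruction and ground truth must be rendered with the SAME
    record (normally the ground truth's range) so that metric values
    reflect radian-scale disagreement.
    """
    lo, hi = record
    span = hi - lo if hi > lo else 1.0
    return np.clip((phase.phase_rad - lo) / span, 0.0, 1.0) * 255.0


def evaluate_sweep(
    model: "TrainedModel",
    stacks: Sequence[IntensityStack],
    ground_truth: Sequence[PhaseMap],
    config: MetricsConfig | None = None,
    tie_config: TieConfig | None = None,
) -> tuple[MetricsReport, MetricsReport]:
    """Score conventional TIE vs single-shot inference across defocus.

    For every stack and every interior plane z, (a) a conventional TIE
    reconstruction treats z as the focus plane and uses its bracketing
    pair, (b) the trained model maps the single frame at z to phase.
    Both are rendered to 8 bits with the ground truth's range and scored
    against it.  Edge planes without a bracketing pair are skipped.
    Returns (tie report, model report).
    """
    from .gan.training import infer

    config = config or MetricsConfig()
    tie_config = tie_config or TieConfig()
    if len(stacks) != len(ground_truth):
        raise ValueError("one ground-truth phase map is required per stack")
    rep_tie = MetricsReport("tie", config=config)
    rep_gan = MetricsReport("tie-gan", config=config)
    for i, (stack, gt) in enumerate(zip(stacks, ground_truth)):
        lo, hi = float(gt.phase_rad.min()), float(gt.phase_rad.max())
        gt8 = render_phase_8bit(gt, (lo, hi))
        z = stack.z_positions_um
        for j in range(len(z)):
            frame_id = f"obj{i:04d}_z{z[j]:+.1f}"
            interior = 0 < j < len(z) - 1 and np.isclose(
                z[j] - z[j - 1], z[j + 1] - z[j]
            )
            if interior:
                rec = tie_solve(stack, tie_config, stack.config, at_z=z[j])
                rec.phase_rad += gt.phase_rad.mean() - rec.phase_rad.mean()
                rep_tie.add(frame_id, z[j], render_phase_8bit(rec, (lo, hi)), gt8)
            pred = infer(model, stack.frames[j])
            pred.phase_rad += gt.phase_rad.mean() - pred.phase_rad.mean()
            rep_gan.add(frame_id, z[j], render_phase_8bit(pred, (lo, hi)), gt8)
    return rep_tie, rep_gan
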
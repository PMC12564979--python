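"""Attention heatmaps and their Shannon entropy.

Each fixation contributes an isotropic Gaussian kernel centred on its
centroid; kernels are weighted by the fraction of total fixation time the
fixation accounts for and summed into a single probability distribution
over the pixel grid,

    f(x, y) = sum_f  d_f * N((x_f, y_f), sigma^2 I),   sum_f d_f = 1,

which is renormalised and fed to the Shannon entropy

    H = - sum_xy p(x, y) log p(x, y),

reported in bits (base 2) by default. High entropy means visual attention
spread widely over the screen; the theoretical maximum for a 1280 x 1024
grid is log2(1280*1024) ~ 20.32 bits, and a single kernel with sigma = 30
px yields ~ 13.9 bits (the discrete sum approaches the differential
entropy log2(2 pi e sigma^2) when sigma spans many pixels).

Kernels are evaluated at pixel centres (integer coordinates), truncated at
``truncate_sd`` standard deviations (default 5, keeping the entropy of a
truncated kernel within 1e-5 bits of the untruncated sum) and renormalised
over their on-screen support, so kernels near an edge lose no mass and
every heatmap sums to exactly one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import DomainError, TrialInvalidError, ValidationError
from .fixation import DetectionParams, Fixation, detect_fixations
from .io import GazeStream

#: Cells below this mass are treated as exact zeros in the entropy sum.
_MASS_FLOOR = 1e-300


@dataclass(frozen=True)
class HeatmapParams:
    """Kernel and grid parameters for heatmap construction."""

    sigma_px: float = 30.0
    grid_w: int = 1280
    grid_h: int = 1024
    truncate_sd: float = 5.0
    log_base: float = 2.0

    def __post_init__(self) -> None:
        if self.sigma_px <= 0:
            raise DomainError("sigma_px must be strictly positive")
        if self.truncate_sd < 3:
            raise DomainError("truncate_sd below 3 SDs loses non-negligible mass")
        if self.grid_w < 1 or self.grid_h < 1:
            raise DomainError("grid dimensions must be positive integers")
        if self.log_base not in (2.0, math.e):
            raise DomainError("log_base must be 2 or e")

    @classmethod
    def from_config(cls, config: RunConfig) -> "HeatmapParams":
        return cls(
            sigma_px=config.sigma_px,
            grid_w=config.screen_w,
            grid_h=config.screen_h,
            log_base=config.log_base,
        )

    @property
    def max_entropy(self) -> float:
        return math.log(self.grid_w * self.grid_h) / math.log(self.log_base)


@dataclass
class HeatmapField:
    """A normalised attention distribution over the pixel grid.

    ``values`` has shape ``(grid_h, grid_w)`` (row = y, column = x, image
    convention) and sums to 1 within 1e-9.
    """

    values: np.ndarray
    weights: np.ndarray
    f_num: int

    def __post_init__(self) -> None:
        if self.f_num < 1:
            raise ValidationError("a heatmap requires at least one fixation")
        if (self.values < 0).any():
            raise ValidationError("heatmap values must be non-negative")
        if abs(float(self.values.sum()) - 1.0) > 1e-9:
            raise ValidationError("heatmap values must sum to 1")


@dataclass(frozen=True)
class EntropyResult:
    """Shannon entropy of a heatmap, with the count of contributing cells."""

    H: float
    n_nonzero_cells: int


def _kernel_patch(x_f: float, y_f: float, params: HeatmapParams):
    """Truncated Gaussian kernel patch and its top-left grid offset.

    The patch covers pixel centres within ``truncate_sd * sigma`` of the
    centre in each axis, clipped to the grid, and is renormalised to sum 1.
    """
    r = params.truncate_sd * params.sigma_px
    x0 = max(0, int(math.ceil(x_f - r)))
    x1 = min(params.grid_w - 1, int(math.floor(x_f + r)))
    y0 = max(0, int(math.ceil(y_f - r)))
    y1 = min(params.grid_h - 1, int(math.floor(y_f + r)))
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    inv2s2 = 1.0 / (2.0 * params.sigma_px**2)
    gx = np.exp(-((xs - x_f) ** 2) * inv2s2)
    gy = np.exp(-((ys - y_f) ** 2) * inv2s2)
    patch = np.outer(gy, gx)
    patch /= patch.sum()
    return patch, x0, y0


def fixation_kernel(x_f: float, y_f: float, params: HeatmapParams) -> np.ndarray:
    """Full-grid field of a single fixation's Gaussian kernel.

    Sums to 1; its maximum sits in the cell containing the centre.
    """
    if not (0 <= x_f < params.grid_w and 0 <= y_f < params.grid_h):
        raise DomainError(f"kernel centre ({x_f}, {y_f}) outside the grid")
    field = np.zeros((params.grid_h, params.grid_w))
    patch, x0, y0 = _kernel_patch(x_f, y_f, params)
    field[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]] = patch
    return field


def build_heatmap(fixations: list[Fixation], params: HeatmapParams) -> HeatmapField:
    """Accumulate duration-weighted fixation kernels into one distribution.

    Fixation weights are ``d_f = duration_f / sum(durations)``; the summed
    field is renormalised so the result is a probability distribution
    regardless of edge effects. Invariant to fixation ordering.
    """
    if not fixations:
        raise TrialInvalidError("cannot build a heatmap from zero fixations")
    durations = np.array([f.duration for f in fixations], dtype=float)
    if (durations <= 0).any():
        raise DomainError("fixation durations must be strictly positive")
    weights = durations / durations.sum()
    field = np.zeros((params.grid_h, params.grid_w))
    for w, f in zip(weights, fixations):
        if not (0 <= f.x < params.grid_w and 0 <= f.y < params.grid_h):
            raise DomainError(f"fixation centroid ({f.x}, {f.y}) outside the grid")
        patch, x0, y0 = _kernel_patch(f.x, f.y, params)
        field[y0 : y0 + patch.shape[0], x0 : x0 + patch.shape[1]] += w * patch
    field /= field.sum()
    return HeatmapField(values=field, weights=weights, f_num=len(fixations))


def entropy(field: HeatmapField | np.ndarray, params: HeatmapParams) -> EntropyResult:
    """Shannon entropy of a normalised heatmap, in the configured base.

    Uses the convention 0 * log 0 = 0. Raises if the field's mass deviates
    from 1 by more than 1e-6.
    """
    values = field.values if isinstance(field, HeatmapField) else np.asarray(field)
    total = float(values.sum())
    if abs(total - 1.0) > 1e-6:
        raise ValidationError(f"field is not normalised (sum = {total!r})")
    p = values[values > _MASS_FLOOR]
    h = -float(np.sum(p * np.log(p))) / math.log(params.log_base)
    return EntropyResult(H=max(h, 0.0), n_nonzero_cells=int(p.size))


def compute_trial_entropy(
    stream: GazeStream,
    detection: DetectionParams | None = None,
    params: HeatmapParams | None = None,
) -> EntropyResult:
    """Heatmap entropy of one trial: detect fixations, build, measure.

    Raises :class:`TrialInvalidError` when the stream yields no fixations;
    such trials are excluded from analysis rather than scored 0.
    """
    detection = detection or DetectionParams()
    params = params or HeatmapParams()
    fixations = detect_fixations(stream, detection)
    if not fixations:
        raise TrialInvalidError(
            f"trial {stream.trial_id or '<unnamed>'}: no fixations detected"
        )
    return entropy(build_heatmap(fixations, params), params)


def render_heatmap_png(field: HeatmapField, path, dpi: int = 72) -> None:
    """Render a heatmap to PNG with a perceptually uniform colormap.

    Visualisation only — the analysis never reads these files back.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 8 * field.values.shape[0] / field.values.shape[1]))
    ax.imshow(field.values, cmap="viridis", origin="upper", interpolation="nearest")
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    fig.savefig(path, dpi=dpi, bbox_inches="tight")
    plt.close(fig)
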
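"""Dispersion-threshold (I-DT) fixation detection.

A fixation is a maximal run of consecutive gaze samples whose positional
dispersion — (max x - min x) + (max y - min y) — stays at or below a
threshold, and whose time span reaches a minimum duration. The detector
grows a window rightward from the current start: once the window covers the
minimum duration and its dispersion is within the threshold, it keeps
extending until the next sample would break the threshold, emits the
fixation, and restarts after it; otherwise it slides the start by one
sample. Samples flagged invalid break windows — no interpolation is done
across tracking loss, so fixations are never fabricated across gaps.

The dispersion threshold is specified in degrees of visual angle and
converted to pixels from the viewing geometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .errors import DomainError, ValidationError
from .io import GazeStream

#: Tolerance for comparing time spans against the minimum duration, to
#: absorb floating-point noise in 1/rate timestamp grids.
_T_EPS = 1e-9


@dataclass(frozen=True)
class Fixation:
    """A detected fixation: centroid, time span and member-sample count."""

    x: float
    y: float
    t_start: float
    t_end: float
    n_samples: int

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass(frozen=True)
class DetectionParams:
    """I-DT parameters: minimum duration (s) and dispersion threshold (px)."""

    min_dur_s: float = 0.1
    disp_thresh_px: float = 39.6

    def __post_init__(self) -> None:
        if self.min_dur_s <= 0 or self.disp_thresh_px <= 0:
            raise DomainError("detection parameters must be strictly positive")

    @classmethod
    def from_config(cls, config: RunConfig) -> "DetectionParams":
        return cls(
            min_dur_s=config.min_fix_dur_s,
            disp_thresh_px=degrees_to_pixels(
                config.dispersion_deg,
                config.viewing_distance_cm,
                config.pixels_per_cm,
            ),
        )


def degrees_to_pixels(
    angle_deg: float, viewing_distance_cm: float, pixels_per_cm: float
) -> float:
    """Convert a visual angle to an on-screen extent in pixels.

    Uses the exact chord formula ``2 d tan(angle/2) * pixels_per_cm`` for a
    viewer at distance ``d`` looking perpendicular to the screen. Monotone
    increasing in each argument; 0 degrees maps to 0 px.
    """
    if angle_deg < 0 or viewing_distance_cm <= 0 or pixels_per_cm <= 0:
        raise DomainError("angle must be >= 0 and geometry strictly positive")
    return 2.0 * viewing_distance_cm * math.tan(math.radians(angle_deg) / 2.0) * pixels_per_cm


def dispersion(x: np.ndarray, y: np.ndarray) -> float:
    """I-DT dispersion of a sample window: x-range plus y-range, in pixels."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0:
        raise DomainError("dispersion of an empty window is undefined")
    return float((x.max() - x.min()) + (y.max() - y.min()))


def _detect_in_run(t, x, y, params: DetectionParams) -> list[Fixation]:
    """Greedy I-DT on one contiguous run of valid samples."""
    n = t.size
    out: list[Fixation] = []
    i = 0
    while i < n - 1:
        # initial window: the samples spanning the minimum duration
        j = int(np.searchsorted(t, t[i] + params.min_dur_s - _T_EPS, side="left"))
        if j >= n:
            break
        xmin = x[i : j + 1].min()
        xmax = x[i : j + 1].max()
        ymin = y[i : j + 1].min()
        ymax = y[i : j + 1].max()
        if (xmax - xmin) + (ymax - ymin) > params.disp_thresh_px:
            i += 1
            continue
        # extend rightward while the threshold holds
        while j + 1 < n:
            nxmin = min(xmin, x[j + 1])
            nxmax = max(xmax, x[j + 1])
            nymin = min(ymin, y[j + 1])
            nymax = max(ymax, y[j + 1])
            if (nxmax - nxmin) + (nymax - nymin) > params.disp_thresh_px:
                break
            xmin, xmax, ymin, ymax = nxmin, nxmax, nymin, nymax
            j += 1
        out.append(
            Fixation(
                x=float(x[i : j + 1].mean()),
                y=float(y[i : j + 1].mean()),
                t_start=float(t[i]),
                t_end=float(t[j]),
                n_samples=j - i + 1,
            )
        )
        i = j + 1
    return out


def detect_fixations(stream: GazeStream, params: DetectionParams) -> list[Fixation]:
    """Segment a gaze stream into fixations with the I-DT algorithm.

    Returns time-ordered, non-overlapping fixations; a stream too short to
    span the minimum duration yields an empty list. Invalid samples split
    the stream into independent runs.
    """
    if stream.t.size > 1 and not np.all(np.diff(stream.t) > 0):
        raise ValidationError("gaze stream timestamps must be strictly increasing")
    fixations: list[Fixation] = []
    idx = np.flatnonzero(stream.valid)
    if idx.size == 0:
        return fixations
    # split valid indices into contiguous runs
    breaks = np.flatnonzero(np.diff(idx) > 1)
    for run in np.split(idx, breaks + 1):
        if run.size < 2:
            continue
        fixations.extend(
            _detect_in_run(stream.t[run], stream.x[run], stream.y[run], params)
        )
    return fixations


def fixations_to_frame(fixations: list[Fixation]):
    """Tabulate fixations as a DataFrame (``x_f,y_f,t_start,t_end,duration,n_samples``)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "x_f": f.x,
                "y_f": f.y,
                "t_start": f.t_start,
                "t_end": f.t_end,
                "duration": f.duration,
                "n_samples": f.n_samples,
            }
            for f in fixations
        ],
        columns=["x_f", "y_f", "t_start", "t_end", "duration", "n_samples"],
    )
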
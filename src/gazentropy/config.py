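"""Run configuration shared across the pipeline stages.

All lengths are in screen pixels, all times in seconds unless a field name
says otherwise. The defaults describe the experimental setup the pipeline
was designed around: a 1280x1024 display viewed from 60 cm, gaze sampled at
100 Hz, attention heatmaps built from a Gaussian kernel with sigma = 30 px
(about 0.5 degrees of visual angle at that distance).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError

#: Logarithm bases accepted for the entropy computation.
_LOG_BASES = {"2": 2.0, "e": math.e, 2: 2.0, 2.0: 2.0, math.e: math.e}


@dataclass
class RunConfig:
    """Configuration for a full detection -> heatmap -> entropy -> stats run.

    Parameters
    ----------
    screen_w, screen_h
        Pixel grid dimensions of the display.
    sigma_px
        Standard deviation of the Gaussian heatmap kernel, in pixels.
    min_fix_dur_ms
        Minimum fixation duration for the dispersion-threshold detector.
    dispersion_deg
        I-DT dispersion threshold expressed in degrees of visual angle.
    viewing_distance_cm, pixels_per_cm
        Geometry used to convert the threshold to pixels. 37.8 px/cm is a
        96-dpi-class display; the resulting pixel threshold is logged.
    log_base
        ``2`` for entropy in bits (default) or ``e`` for nats.
    max_drop_frac
        A trial whose fraction of dropped gaze samples exceeds this is
        excluded from analysis.
    """

    screen_w: int = 1280
    screen_h: int = 1024
    sigma_px: float = 30.0
    min_fix_dur_ms: float = 100.0
    dispersion_deg: float = 1.0
    viewing_distance_cm: float = 60.0
    pixels_per_cm: float = 37.8
    log_base: float = 2.0
    rate_hz: float = 100.0
    max_drop_frac: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.log_base not in _LOG_BASES:
            raise ValidationError(f"log_base must be 2 or e, got {self.log_base!r}")
        self.log_base = _LOG_BASES[self.log_base]
        for name in (
            "screen_w",
            "screen_h",
            "sigma_px",
            "min_fix_dur_ms",
            "dispersion_deg",
            "viewing_distance_cm",
            "pixels_per_cm",
            "rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if not 0 <= self.max_drop_frac <= 1:
            raise ValidationError("max_drop_frac must lie in [0, 1]")

    @property
    def min_fix_dur_s(self) -> float:
        return self.min_fix_dur_ms / 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["log_base"] not in (2.0,):
            d["log_base"] = "e"
        else:
            d["log_base"] = 2
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a config file; keyword arguments override file values."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)
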
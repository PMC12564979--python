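"""Synthetic gaze, trial and rating generation.

The study's raw eye-tracking data are not public, so this module emulates
the dataset the analysis assumes: 16 participants x 15 trials balanced over
three task types (240 trials), per-type heatmap-entropy (HE) distributions,
response times (RT) generated from per-type linear models with residual
variance implied by each model's coefficient of determination, ordered
Likert difficulty ratings, and genders with no injected effect.

Two generation modes are exposed:

* **fast** (default) — HE values are drawn directly from the per-type
  normal distributions; suitable for statistics-only work where the
  spatial pipeline is not exercised.
* **full** — each trial gets an actual fixation pattern whose computed
  heatmap entropy matches the drawn target, synthesized into a 100 Hz gaze
  stream; HE is then *recomputed* through detection -> KDE -> entropy, so
  the whole chain is exercised end to end.

Entropy targeting works through a calibration curve: for k well-separated
equal-weight fixation clusters the heatmap is a near-disjoint mixture, so
its entropy is approximately (single-kernel entropy) + log2 k bits. The
curve tabulates the actually computed mean entropy per k; a target is hit
by picking the bracketing k and skewing one cluster's weight, solving the
mixture-entropy equation for the skew.

The RT model is RT = intercept + slope * HE + eps with eps ~ N(0, s_eps)
and s_eps = |slope| * sd(HE) * sqrt((1 - R2)/R2), which makes the
population R2 equal the configured target. RT values are left unclamped by
default: the configured Type-1 line is negative at low HE, so any
positivity floor censors the lower tail and attenuates the recoverable
slope. Setting ``rt_floor_s`` enforces positivity at that cost.

All randomness flows from one integer seed; per-trial substreams are
derived from (seed, participant index, trial index) so datasets are
reproducible and order-independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import CalibrationError, DomainError, ValidationError
from .fixation import DetectionParams, Fixation, detect_fixations
from .heatmap import HeatmapParams, build_heatmap, entropy
from .io import GazeStream

logger = logging.getLogger(__name__)

#: Questions available per task type; trials sample from this pool
#: without replacement within a participant.
QUESTIONS_PER_TYPE = 8


@dataclass(frozen=True)
class ScopeModel:
    """Linear RT model for one scope (a task type or the pooled data)."""

    slope: float
    intercept: float
    r2: float

    def residual_sd(self, he_sd: float) -> float:
        if not 0 < self.r2 < 1:
            raise ValidationError("r2 target must lie strictly between 0 and 1")
        return abs(self.slope) * he_sd * math.sqrt((1 - self.r2) / self.r2)


@dataclass
class GeneratorConfig:
    """Defaults describe the emulated study conditions.

    ``he_params`` maps task type to (mean, SD) of heatmap entropy in bits;
    ``rt_models`` maps each scope (task type or ``"overall"``) to its
    linear model. ``rt_floor_s`` is ``None`` by default — see the module
    docstring for why clamping is off.
    """

    n_participants: int = 16
    trials_per_participant: int = 15
    task_types: tuple[int, ...] = (1, 2, 3)
    he_params: dict = field(
        default_factory=lambda: {1: (16.46, 0.92), 2: (16.05, 0.50), 3: (16.18, 0.65)}
    )
    rt_models: dict = field(
        default_factory=lambda: {
            "overall": ScopeModel(4.28, -64.76, 0.354),
            1: ScopeModel(5.188, -78.494, 0.377),
            2: ScopeModel(1.496, -20.697, 0.178),
            3: ScopeModel(2.987, -44.326, 0.342),
        }
    )
    likert_means: dict = field(default_factory=lambda: {1: 2.5, 2: 4.0, 3: 5.5})
    likert_sd: float = 1.0
    rate_hz: float = 100.0
    noise_sd_px: float = 2.0
    base_total_fix_s: float = 4.0
    min_fix_dur_s: float = 0.12
    rt_floor_s: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trials_per_participant % len(self.task_types):
            raise ValidationError(
                "trials_per_participant must be divisible by the number of task types"
            )
        if self.trials_per_participant // len(self.task_types) > QUESTIONS_PER_TYPE:
            raise ValidationError(
                f"at most {QUESTIONS_PER_TYPE} trials per type per participant "
                "(question pool exhausted)"
            )
        for t, (m, s) in self.he_params.items():
            if s <= 0:
                raise ValidationError(f"he_sd for type {t} must be positive")
        if self.rt_floor_s is not None and self.rt_floor_s <= 0:
            raise ValidationError("rt_floor_s must be strictly positive when set")

    @property
    def trials_per_type(self) -> int:
        return self.trials_per_participant // len(self.task_types)


@dataclass
class SyntheticTrial:
    """One generated trial with its ground truth attached."""

    participant: str
    gender: str
    task_type: int
    question_id: str
    rt_s: float
    he_bits: float
    target_he: float
    fixations: list[Fixation] | None = None
    stream: GazeStream | None = None


# --------------------------------------------------------------------------
# Entropy calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone map from cluster count k to expected heatmap entropy (bits)."""

    ks: np.ndarray
    he: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.he) <= 0):
            raise CalibrationError("calibration curve is not strictly increasing")

    @property
    def lo(self) -> float:
        return float(self.he[0])

    @property
    def hi(self) -> float:
        return float(self.he[-1])


_CURVE_CACHE: dict[tuple, CalibrationCurve] = {}


def _edge_margin(params: HeatmapParams) -> float:
    # keep kernels fully on-screen so no mass is truncated at edges
    return params.truncate_sd * params.sigma_px + 5.0


def _cluster_centers(
    k: int, params: HeatmapParams, rng: np.random.Generator
) -> np.ndarray:
    """k jittered-grid cluster centres, well separated and away from edges."""
    margin = _edge_margin(params)
    uw = params.grid_w - 2 * margin
    uh = params.grid_h - 2 * margin
    if uw <= 0 or uh <= 0:
        raise DomainError("grid too small for the kernel margin")
    ncols = max(1, math.ceil(math.sqrt(k * uw / uh)))
    nrows = math.ceil(k / ncols)
    sw, sh = uw / ncols, uh / nrows
    cells = rng.choice(ncols * nrows, size=k, replace=False)
    jitter = min(15.0, sw / 6.0, sh / 6.0)
    cx = margin + (cells % ncols + 0.5) * sw + rng.uniform(-jitter, jitter, k)
    cy = margin + (cells // ncols + 0.5) * sh + rng.uniform(-jitter, jitter, k)
    return np.column_stack([cx, cy])


def _pattern_entropy(centers: np.ndarray, weights: np.ndarray, params: HeatmapParams) -> float:
    """Computed heatmap entropy of a weighted cluster pattern (one fixation
    per cluster, durations proportional to weights)."""
    fixations = [
        Fixation(x=float(cx), y=float(cy), t_start=i, t_end=i + float(w), n_samples=2)
        for i, ((cx, cy), w) in enumerate(zip(centers, weights))
    ]
    return entropy(build_heatmap(fixations, params), params).H


def calibrate_entropy_control(
    params: HeatmapParams,
    rng: np.random.Generator | int = 0,
    k_max: int = 32,
    reps: int = 4,
) -> CalibrationCurve:
    """Tabulate mean computed entropy for k = 1..k_max equal-weight clusters.

    The curve is averaged over ``reps`` random placements per k and
    smoothed with pool-adjacent-violators before the strict-monotonicity
    check; results are cached per (params, k_max, reps, seed) when an
    integer seed is given.
    """
    key = None
    if isinstance(rng, (int, np.integer)):
        key = (params, k_max, reps, int(rng))
        if key in _CURVE_CACHE:
            return _CURVE_CACHE[key]
        rng = np.random.default_rng([int(rng), 0x5EED])
    ks = np.arange(1, k_max + 1)
    he = np.empty(k_max)
    for i, k in enumerate(ks):
        vals = [
            _pattern_entropy(_cluster_centers(k, params, rng), np.full(k, 1.0 / k), params)
            for _ in range(reps)
        ]
        he[i] = float(np.mean(vals))
    he = _pava(he)
    if np.any(np.diff(he) <= 1e-9):
        raise CalibrationError("calibration curve not increasing after smoothing")
    curve = CalibrationCurve(ks=ks, he=he)
    if key is not None:
        _CURVE_CACHE[key] = curve
    return curve


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators isotonic smoothing (increasing)."""
    y = y.astype(float).copy()
    n = y.size
    w = np.ones(n)
    i = 0
    while i < n - 1:
        if y[i] > y[i + 1]:
            pooled = (w[i] * y[i] + w[i + 1] * y[i + 1]) / (w[i] + w[i + 1])
            y[i] = y[i + 1] = pooled
            w[i] = w[i + 1] = w[i] + w[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    return y


def _mixture_entropy_excess(k: int, alpha: float) -> float:
    """Mixing entropy (bits) of k unit weights plus one weight alpha."""
    total = k + alpha
    return math.log2(total) - (alpha * math.log2(alpha)) / total if alpha > 0 else math.log2(k)


def generate_fixation_pattern(
    target_he: float,
    params: HeatmapParams,
    rng: np.random.Generator,
    curve: CalibrationCurve | None = None,
    total_fix_s: float = 4.0,
    min_fix_dur_s: float = 0.12,
) -> list[Fixation]:
    """Fixation set whose computed heatmap entropy approximates a target.

    Inverts the calibration curve: picks the cluster count k bracketing the
    target and interpolates by down-weighting one extra cluster (solving
    the mixture-entropy equation for the weight by bisection). Durations
    are proportional to weights, scaled so the shortest fixation is still
    detectable; back-to-back timestamps are assigned.
    """
    if not 0 <= target_he <= params.max_entropy:
        raise DomainError(f"target entropy {target_he} outside [0, {params.max_entropy:.2f}]")
    if curve is None:
        curve = calibrate_entropy_control(params)

    if target_he <= curve.lo:
        weights = np.ones(1)
    elif target_he >= curve.hi:
        logger.warning(
            "target %.2f bits above calibrated range (%.2f); clamping", target_he, curve.hi
        )
        weights = np.full(curve.ks[-1], 1.0 / curve.ks[-1])
    else:
        k = int(np.searchsorted(curve.he, target_he, side="right"))  # he[k-1] <= t < he[k]
        frac = (target_he - curve.he[k - 1]) / (curve.he[k] - curve.he[k - 1])
        want = math.log2(k) + frac * (math.log2(k + 1) - math.log2(k))
        lo, hi = 1e-4, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if _mixture_entropy_excess(k, mid) < want:
                lo = mid
            else:
                hi = mid
        alpha = 0.5 * (lo + hi)
        weights = np.concatenate([np.ones(k), [alpha]])
        weights /= weights.sum()

    centers = _cluster_centers(len(weights), params, rng)
    # scale total fixation time so the lightest cluster stays detectable
    total = max(total_fix_s, min_fix_dur_s / weights.min())
    durations = weights * total
    fixations = []
    t = 0.0
    for (cx, cy), dur in zip(centers, durations):
        fixations.append(
            Fixation(x=float(cx), y=float(cy), t_start=t, t_end=t + float(dur), n_samples=2)
        )
        t += float(dur)
    return fixations


# --------------------------------------------------------------------------
# Gaze synthesis
# --------------------------------------------------------------------------


def generate_gaze_stream(
    fixations: list[Fixation],
    rate_hz: float = 100.0,
    noise_sd_px: float = 2.0,
    rng: np.random.Generator | None = None,
    trial_id: str = "",
    n_transition: int = 2,
    screen_w: int = 1280,
    screen_h: int = 1024,
) -> GazeStream:
    """Sample a gaze stream around a fixation sequence at ``rate_hz``.

    Each fixation emits ``round(duration * rate)`` samples jittered around
    its centroid with isotropic Gaussian noise; consecutive fixations are
    joined by a few high-velocity transition samples along the straight
    line between centroids, which the detector rejects as saccades.
    """
    if not fixations:
        raise DomainError("need at least one fixation to synthesize gaze")
    if any(f.duration <= 0 for f in fixations):
        raise DomainError("fixation durations must be strictly positive")
    rng = rng or np.random.default_rng()
    xs: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for i, f in enumerate(fixations):
        n = max(2, round(f.duration * rate_hz))
        xs.append(f.x + rng.normal(0, noise_sd_px, n))
        ys.append(f.y + rng.normal(0, noise_sd_px, n))
        if i + 1 < len(fixations):
            nxt = fixations[i + 1]
            frac = np.arange(1, n_transition + 1) / (n_transition + 1)
            xs.append(f.x + frac * (nxt.x - f.x) + rng.normal(0, noise_sd_px, n_transition))
            ys.append(f.y + frac * (nxt.y - f.y) + rng.normal(0, noise_sd_px, n_transition))
    x = np.clip(np.concatenate(xs), 0, screen_w - 1e-6)
    y = np.clip(np.concatenate(ys), 0, screen_h - 1e-6)
    t = np.arange(x.size) / rate_hz
    return GazeStream(t=t, x=x, y=y, rate_hz=rate_hz, trial_id=trial_id)


# --------------------------------------------------------------------------
# Trial and dataset generation
# --------------------------------------------------------------------------


def _trial_rng(seed: int, p_idx: int, t_idx: int) -> np.random.Generator:
    """Stable per-trial substream: independent of generation order."""
    return np.random.default_rng([seed, p_idx, t_idx])


def generate_trial(
    participant: str,
    task_type: int,
    config: GeneratorConfig,
    rng: np.random.Generator,
    mode: str = "fast",
    question_id: str = "",
    heatmap_params: HeatmapParams | None = None,
    curve: CalibrationCurve | None = None,
) -> SyntheticTrial:
    """Generate one trial of the given type.

    In fast mode HE is the drawn target itself; in full mode a fixation
    pattern is synthesized, rendered into gaze, and HE is recomputed through
    the detection -> heatmap -> entropy chain. RT always follows the type's
    linear model evaluated at the *achieved* HE.
    """
    if task_type not in config.he_params:
        raise ValidationError(f"no HE parameters for task type {task_type}")
    mean, sd = config.he_params[task_type]
    model: ScopeModel = config.rt_models[task_type]
    target_he = float(rng.normal(mean, sd))

    fixations = stream = None
    if mode == "fast":
        he = target_he
    elif mode == "full":
        heatmap_params = heatmap_params or HeatmapParams()
        clamped_target = min(max(target_he, 0.0), heatmap_params.max_entropy)
        fixations = generate_fixation_pattern(
            clamped_target,
            heatmap_params,
            rng,
            curve=curve,
            total_fix_s=config.base_total_fix_s,
            min_fix_dur_s=config.min_fix_dur_s,
        )
        stream = generate_gaze_stream(
            fixations,
            rate_hz=config.rate_hz,
            noise_sd_px=config.noise_sd_px,
            rng=rng,
            trial_id=f"{participant}_{question_id}",
            screen_w=heatmap_params.grid_w,
            screen_h=heatmap_params.grid_h,
        )
        detected = detect_fixations(stream, DetectionParams.from_config(RunConfig()))
        if not detected:
            raise CalibrationError("synthesized stream produced no fixations")
        he = entropy(build_heatmap(detected, heatmap_params), heatmap_params).H
    else:
        raise ValidationError(f"unknown generation mode {mode!r}")

    eps = float(rng.normal(0.0, model.residual_sd(sd)))
    rt = model.intercept + model.slope * he + eps
    if config.rt_floor_s is not None:
        rt = max(rt, config.rt_floor_s)
    return SyntheticTrial(
        participant=participant,
        gender="",
        task_type=task_type,
        question_id=question_id,
        rt_s=rt,
        he_bits=he,
        target_he=target_he,
        fixations=fixations,
        stream=stream,
    )


def generate_dataset(
    config: GeneratorConfig | None = None,
    mode: str = "fast",
    heatmap_params: HeatmapParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, GazeStream]]:
    """Generate the full synthetic dataset.

    Returns ``(trials, ratings, streams)``: a trial table with achieved HE
    and model RT, a per-participant-per-type Likert rating table with
    ordered type means, and (full mode only) the raw gaze streams keyed by
    trial id. Genders are balanced and carry no injected effect. Two runs
    with the same config are identical row for row.
    """
    config = config or GeneratorConfig()
    curve = None
    if mode == "full":
        heatmap_params = heatmap_params or HeatmapParams()
        curve = calibrate_entropy_control(heatmap_params, rng=config.seed)

    rows = []
    streams: dict[str, GazeStream] = {}
    ratings_rows = []
    for p_idx in range(config.n_participants):
        participant = f"P{p_idx + 1:02d}"
        gender = "F" if p_idx < config.n_participants // 2 else "M"
        # per-participant question sampling, without replacement within type
        q_rng = np.random.default_rng([config.seed, 0xA11, p_idx])
        questions = {
            t: q_rng.choice(QUESTIONS_PER_TYPE, size=config.trials_per_type, replace=False) + 1
            for t in config.task_types
        }
        t_idx = 0
        for task_type in config.task_types:
            for j in range(config.trials_per_type):
                trial = generate_trial(
                    participant,
                    task_type,
                    config,
                    _trial_rng(config.seed, p_idx, t_idx),
                    mode=mode,
                    question_id=f"T{task_type}Q{questions[task_type][j]}",
                    heatmap_params=heatmap_params,
                    curve=curve,
                )
                trial.gender = gender
                rows.append(
                    {
                        "participant": trial.participant,
                        "gender": gender,
                        "task_type": trial.task_type,
                        "question_id": trial.question_id,
                        "rt_s": trial.rt_s,
                        "he_bits": trial.he_bits,
                        "target_he": trial.target_he,
                    }
                )
                if trial.stream is not None:
                    streams[trial.stream.trial_id] = trial.stream
                t_idx += 1
        r_rng = np.random.default_rng([config.seed, 0x11F, p_idx])
        for task_type in config.task_types:
            raw = r_rng.normal(config.likert_means[task_type], config.likert_sd)
            ratings_rows.append(
                {
                    "participant": participant,
                    "task_type": task_type,
                    "rating": int(np.clip(round(raw), 1, 7)),
                }
            )
    trials = pd.DataFrame(rows)
    ratings = pd.DataFrame(ratings_rows)
    return trials, ratings, streams
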
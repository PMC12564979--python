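"""Reading and writing gaze streams, trial tables, ratings and reports.

File formats are deliberately plain:

* gaze file — CSV/TSV with header ``t,x,y[,valid]``; ``t`` in seconds from
  trial start (a ``t_ms`` column may be used instead, in milliseconds);
* trial table — CSV ``participant,gender,task_type,question_id,rt_s``;
* ratings table — CSV ``participant,task_type,rating`` (7-point Likert).

Coordinates follow the image convention: origin at the top-left corner,
x rightward, y downward, 0-based pixel indices; gaze positions are
real-valued, grid cells are unit pixels. Samples flagged invalid or lying
off screen are dropped (not clamped) on read, and the drop count is kept on
the stream so downstream exclusion rules can act on it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

TASK_TYPES = (1, 2, 3)

TRIAL_COLUMNS = ["participant", "gender", "task_type", "question_id", "rt_s"]
RATING_COLUMNS = ["participant", "task_type", "rating"]


@dataclass
class GazeStream:
    """Ordered, timestamped gaze samples for one trial.

    ``t`` is seconds from trial start and must be strictly increasing;
    ``valid`` marks samples the tracker reported as good and on-screen.
    ``n_dropped`` counts samples removed on read so that
    ``n_dropped + len(stream)`` equals the raw sample count.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    rate_hz: float = 100.0
    trial_id: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.t.shape == self.x.shape == self.y.shape == self.valid.shape):
            raise ValidationError("t, x, y, valid must have equal length")
        if self.t.size and (not np.all(np.isfinite(self.t)) or self.t[0] < 0):
            raise ValidationError("timestamps must be finite and non-negative")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            raise ValidationError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def drop_fraction(self) -> float:
        total = len(self) + self.n_dropped
        return self.n_dropped / total if total else 0.0


def read_gaze_csv(path: str | Path, config: RunConfig | None = None) -> GazeStream:
    """Read a gaze CSV/TSV into a :class:`GazeStream`.

    Samples with ``valid`` false, non-finite coordinates, or positions off
    the configured screen are dropped; the number dropped is recorded on the
    returned stream and logged.
    """
    config = config or RunConfig()
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty gaze file") from None
    if df.empty:
        raise EmptyInputError(f"{path}: gaze file has no samples")
    if "t" not in df.columns and "t_ms" in df.columns:
        df = df.rename(columns={"t_ms": "t"})
        df["t"] = df["t"] / 1000.0
    missing = {"t", "x", "y"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if "valid" not in df.columns:
        df["valid"] = True

    df = df.sort_values("t", kind="stable").reset_index(drop=True)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    ok = (
        df["valid"].astype(bool).to_numpy()
        & np.isfinite(x)
        & np.isfinite(y)
        & (x >= 0)
        & (x < config.screen_w)
        & (y >= 0)
        & (y < config.screen_h)
    )
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d/%d invalid or off-screen samples", path.name, n_dropped, len(df))
    return GazeStream(
        t=df["t"].to_numpy(float)[ok],
        x=x[ok],
        y=y[ok],
        rate_hz=config.rate_hz,
        trial_id=path.stem,
        n_dropped=n_dropped,
    )


def write_gaze_csv(stream: GazeStream, path: str | Path) -> None:
    """Write a gaze stream back to CSV (columns ``t,x,y,valid``)."""
    df = pd.DataFrame(
        {"t": stream.t, "x": stream.x, "y": stream.y, "valid": stream.valid.astype(int)}
    )
    df.to_csv(path, index=False, float_format="%.10g")


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read and validate a trial table.

    Returns a DataFrame with columns ``participant, gender, task_type,
    question_id, rt_s`` (plus ``he_bits`` if present). Task types must be
    in {1, 2, 3} and response times strictly positive.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: empty trial file") from None
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: trial table is empty", path.name)
        return df
    df["task_type"] = df["task_type"].astype(int)
    bad_type = ~df["task_type"].isin(TASK_TYPES)
    if bad_type.any():
        raise ValidationError(
            f"{path}: task_type outside {{1,2,3}} in rows {list(df.index[bad_type])}"
        )
    if (df["rt_s"] <= 0).any():
        raise ValidationError(f"{path}: non-positive response times present")
    return df


def write_trials_csv(trials: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in TRIAL_COLUMNS + ["he_bits"] if c in trials.columns]
    trials[cols].to_csv(path, index=False, float_format="%.10g")


def read_ratings_csv(path: str | Path) -> pd.DataFrame:
    """Read a 7-point Likert difficulty-rating table."""
    df = pd.read_csv(path)
    missing = set(RATING_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        logger.warning("%s: ratings table is empty", Path(path).name)
        return df
    if not df["rating"].isin(range(1, 8)).all():
        raise ValidationError(f"{path}: ratings must be integers in 1..7")
    if not df["task_type"].isin(TASK_TYPES).all():
        raise ValidationError(f"{path}: task_type outside {{1,2,3}}")
    return df


def write_ratings_csv(ratings: pd.DataFrame, path: str | Path) -> None:
    ratings[RATING_COLUMNS].to_csv(path, index=False)


def write_report(results, out_dir: str | Path) -> dict[str, Path]:
    """Write an analysis results bundle as a set of CSV tables.

    Emits ``per_trial.csv``, ``descriptives.csv``, ``overall_fit.csv``,
    ``per_type_fits.csv``, ``anova.csv`` and ``gender_tests.csv`` with a
    deterministic column order; rerunning on identical input produces
    byte-identical files.
    """
    from .stats import AnalysisResults  # local import to avoid a cycle

    if not isinstance(results, AnalysisResults):
        raise ValidationError("write_report expects an AnalysisResults bundle")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    per_trial = results.trials.copy()
    cols = [c for c in TRIAL_COLUMNS + ["he_bits"] if c in per_trial.columns]
    paths["per_trial"] = out / "per_trial.csv"
    per_trial[cols].to_csv(paths["per_trial"], index=False, float_format="%.10g")

    paths["descriptives"] = out / "descriptives.csv"
    results.descriptives.to_csv(paths["descriptives"], index=False, float_format="%.6g")

    def fit_row(scope, fit):
        return {
            "scope": scope,
            "n": fit.n,
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r": fit.r,
            "r2": fit.r2,
            "p": fit.p,
        }

    paths["overall_fit"] = out / "overall_fit.csv"
    pd.DataFrame([fit_row("overall", results.overall)]).to_csv(
        paths["overall_fit"], index=False, float_format="%.6g"
    )
    paths["per_type_fits"] = out / "per_type_fits.csv"
    pd.DataFrame(
        [fit_row(f"type{k}", f) for k, f in sorted(results.per_type.items())]
    ).to_csv(paths["per_type_fits"], index=False, float_format="%.6g")

    paths["anova"] = out / "anova.csv"
    if results.anova is not None:
        fstat, p = results.anova
        pd.DataFrame([{"effect": "task_type_on_rating", "F": fstat, "p": p}]).to_csv(
            paths["anova"], index=False, float_format="%.6g"
        )
    else:
        pd.DataFrame(columns=["effect", "F", "p"]).to_csv(paths["anova"], index=False)

    paths["gender_tests"] = out / "gender_tests.csv"
    rows = [
        {"scope": scope, "variable": var, "t": t, "p": p}
        for (scope, var), (t, p) in sorted(results.gender_tests.items())
    ]
    pd.DataFrame(rows, columns=["scope", "variable", "t", "p"]).to_csv(
        paths["gender_tests"], index=False, float_format="%.6g"
    )
    return paths
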
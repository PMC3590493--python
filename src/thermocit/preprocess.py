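"""Preprocessing: AOI maxima, decimation, baseline correction, FTCVs.

The raw measurement per response window is, frame by frame, the maximum
temperature inside the analyst-drawn area of interest (AOI) over the
periorbital region.  The facial temperature change value (FTCV) of a
participant for a relevance class is the mean over that class's windows
of the window-mean AOI maximum, minus the participant's baseline mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError

PLAUSIBLE_RANGE_C = (20.0, 45.0)
_UNIFORM_TOL_S = 1e-9

CONDITIONS = ("guilty", "innocent")
RELEVANCES = ("RE", "IR")


@dataclass(frozen=True, eq=False)
class FunctionSample:
    """One question-response trajectory with its design labels."""

    participant_id: str
    condition: str
    question_id: str
    relevance: str
    times: np.ndarray
    temps: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        temps = np.asarray(self.temps, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "temps", temps)
        if self.condition not in CONDITIONS:
            raise ValidationError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.relevance not in RELEVANCES:
            raise ValidationError(f"relevance must be one of {RELEVANCES}, got {self.relevance!r}")
        if times.ndim != 1 or temps.ndim != 1 or len(times) != len(temps):
            raise ValidationError("times and temps must be 1-D arrays of equal length")
        if len(times) < 2:
            raise ValidationError("a function sample needs at least 2 points")
        if abs(times[0]) > _UNIFORM_TOL_S:
            raise ValidationError("times must start at 0 (window-relative seconds)")
        dt = np.diff(times)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.ptp(dt) > _UNIFORM_TOL_S:
            raise ValidationError("times must be uniformly spaced")
        if not np.all(np.isfinite(temps)):
            raise ValidationError("temps must be finite (interpolate gaps first)")
        if temps.min() < PLAUSIBLE_RANGE_C[0] or temps.max() > PLAUSIBLE_RANGE_C[1]:
            # constant message so the default warning filter reports it once
            warnings.warn(
                f"temperatures outside the plausible skin range {PLAUSIBLE_RANGE_C} degC",
                stacklevel=2,
            )

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class FtcvRecord:
    """Facial temperature change value of one participant for one relevance class."""

    participant_id: str
    relevance: str
    ftcv: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ftcv):
            raise ValidationError("ftcv must be finite")


def aoi_max_series(frames: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-frame maximum temperature over the masked (AOI) pixels.

    ``frames`` is a (n_frames, rows, cols) stack; ``mask`` a boolean grid
    of the same spatial shape with at least one True cell.
    """
    frames = np.asarray(frames, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if frames.ndim != 3:
        raise ValidationError("frames must be a 3-D stack (n_frames, rows, cols)")
    if mask.shape != frames.shape[1:]:
        raise ValidationError(f"mask shape {mask.shape} does not match frame shape {frames.shape[1:]}")
    if not mask.any():
        raise ValidationError("AOI mask has no selected pixel")
    return frames[:, mask].max(axis=1)


def decimate(sample: FunctionSample, keep_every: int) -> FunctionSample:
    """Keep indices 0, k, 2k, ... of the sample (labels unchanged)."""
    if not isinstance(keep_every, (int, np.integer)) or keep_every < 1:
        raise ValidationError(f"keep_every must be an integer >= 1, got {keep_every!r}")
    return replace(sample, times=sample.times[::keep_every], temps=sample.temps[::keep_every])


def baseline_correct(sample: FunctionSample, baseline_mean_c: float) -> FunctionSample:
    """Subtract the participant's baseline mean from every temperature."""
    if not np.isfinite(baseline_mean_c):
        raise ValidationError("baseline mean must be finite")
    with warnings.catch_warnings():
        # corrected values are deviations around 0 degC by construction
        warnings.simplefilter("ignore")
        return replace(sample, temps=sample.temps - baseline_mean_c)


def baseline_mean(series) -> float:
    """Mean of the 1-minute pre-questioning baseline reading."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValidationError("baseline series is empty")
    if not np.all(np.isfinite(series)):
        raise ValidationError("baseline series must be finite")
    return float(series.mean())


def interpolate_gaps(temps: np.ndarray, max_gap: int = 3) -> np.ndarray:
    """Fill runs of at most *max_gap* consecutive NaNs by linear interpolation.

    Edge gaps are filled with the nearest valid value; a longer run means
    the sample is unusable and raises ValidationError.
    """
    temps = np.asarray(temps, dtype=float).copy()
    isnan = ~np.isfinite(temps)
    if not isnan.any():
        return temps
    if isnan.all():
        raise ValidationError("all values missing")
    # longest run of consecutive NaNs
    run = 0
    for flag in isnan:
        run = run + 1 if flag else 0
        if run > max_gap:
            raise ValidationError(f"gap of more than {max_gap} consecutive missing frames")
    idx = np.arange(len(temps))
    temps[isnan] = np.interp(idx[isnan], idx[~isnan], temps[~isnan])
    return temps


def compute_ftcv(samples: list, baseline: float) -> dict:
    """FTCV per relevance class for one participant's response windows.

    Each class's FTCV is the mean over its windows of the window-mean
    temperature, minus the baseline mean.
    """
    if not samples:
        raise ValidationError("no samples given")
    pid = samples[0].participant_id
    if any(s.participant_id != pid for s in samples):
        raise ValidationError("compute_ftcv expects samples from a single participant")
    out = {}
    for relevance in RELEVANCES:
        window_means = [float(s.temps.mean()) for s in samples if s.relevance == relevance]
        if not window_means:
            raise ValidationError(f"participant {pid} has no {relevance} sample")
        out[relevance] = FtcvRecord(
            participant_id=pid,
            relevance=relevance,
            ftcv=float(np.mean(window_means) - baseline),
        )
    return out


def ftcv_table(dataset, baselines: dict | None = None):
    """FTCVs for every participant of a dataset, as arrays per (condition, relevance).

    Returns dict {(condition, relevance): np.ndarray of per-participant FTCVs},
    ordered by participant id.  ``baselines`` defaults to the dataset's own.
    """
    if baselines is None:
        baselines = dataset.baselines
    by_pid: dict = {}
    for s in dataset.samples:
        by_pid.setdefault(s.participant_id, []).append(s)
    table: dict = {}
    for pid in sorted(by_pid):
        group = by_pid[pid]
        records = compute_ftcv(group, baselines[pid])
        for relevance, rec in records.items():
            table.setdefault((group[0].condition, relevance), []).append(rec.ftcv)
    return {k: np.asarray(v) for k, v in table.items()}
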
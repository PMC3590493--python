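"""Synthetic CIT thermal-session generator.

Each generated trajectory is

    temp(t) = baseline_p + drift_q * t / window
              + delta_{condition,relevance} * g(t)
              + AR(1) smooth noise + sensor noise,

quantized to the camera's heat resolution.  ``g`` is a fixed smooth
unit-peak onset template (``sin^2`` ramp reaching 1 at 5 s) standing in
for the sympathetically driven periorbital warming; ``delta`` is composed
from the three effect amplitudes under a sum-to-zero two-way
parameterization, so the functional-ANOVA ground truth is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .design import StudyDesign
from .errors import ValidationError
from .preprocess import FunctionSample

T_PEAK_S = 5.0  # onset template reaches its unit peak here

CONDITION_SIGN = {"guilty": 1.0, "innocent": -1.0}
RELEVANCE_SIGN = {"RE": 1.0, "IR": -1.0}


def effect_template(times: np.ndarray, window_s: float = 10.0) -> np.ndarray:
    """Smooth unit-peak onset: sin^2(pi * min(t, t_peak) / (2 t_peak)).

    Rises from 0 with zero initial slope and plateaus at 1 from 5 s on.
    """
    t = np.minimum(np.asarray(times, dtype=float), T_PEAK_S)
    return np.sin(np.pi * t / (2.0 * T_PEAK_S)) ** 2


def cell_delta(design: StudyDesign, condition: str, relevance: str) -> float:
    """Peak elevation of the (condition, relevance) cell above the grand mean.

    Sum-to-zero coefficients are half the reported level differences.
    """
    sa = CONDITION_SIGN[condition]
    sb = RELEVANCE_SIGN[relevance]
    return 0.5 * (
        design.effect_main_condition * sa
        + design.effect_main_relevance * sb
        + design.effect_interaction * sa * sb
    )


def true_effects(design: StudyDesign, grid: np.ndarray, baseline_corrected: bool = True) -> dict:
    """Ground-truth effect functions on *grid* for the two-way decomposition.

    Returns mu(t), alpha(t) (guilty side), beta(t) (RE side) and gamma(t)
    (guilty-RE side).  With ``baseline_corrected=False`` the expected
    baseline contributions (unweighted over the four cells) are added to
    mu and alpha.
    """
    g = effect_template(grid, design.window_s)
    out = {
        "mu": 0.0 * g,
        "alpha": 0.5 * design.effect_main_condition * g,
        "beta": 0.5 * design.effect_main_relevance * g,
        "gamma": 0.5 * design.effect_interaction * g,
    }
    if not baseline_corrected:
        out["mu"] = out["mu"] + 0.5 * (design.baseline_mean_g + design.baseline_mean_i)
        out["alpha"] = out["alpha"] + 0.5 * (design.baseline_mean_g - design.baseline_mean_i)
    return out


@dataclass
class ThermalDataset:
    """A full synthetic session batch: one FunctionSample per (participant,
    question) plus the per-participant baseline temperatures."""

    samples: list
    baselines: dict
    design: StudyDesign

    def __post_init__(self) -> None:
        expected = self.design.n_functions
        if len(self.samples) != expected:
            raise ValidationError(
                f"dataset must hold {expected} samples (participants x questions), got {len(self.samples)}"
            )

    def subset(self, relevance: str | None = None, condition: str | None = None) -> list:
        out = self.samples
        if relevance is not None:
            out = [s for s in out if s.relevance == relevance]
        if condition is not None:
            out = [s for s in out if s.condition == condition]
        return out


def _ar1_noise(rng: np.random.Generator, shape: tuple, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis with marginal SD *sd*."""
    if sd == 0.0:
        return np.zeros(shape)
    w = rng.standard_normal(shape)
    if phi == 0.0:
        return sd * w
    # scale innovations so the marginal variance is sd^2 from the first sample
    w[..., 0] *= sd
    w[..., 1:] *= sd * np.sqrt(1.0 - phi * phi)
    return lfilter([1.0], [1.0, -phi], w, axis=-1)


def _participant_ids(design: StudyDesign) -> list:
    g = [f"G{i + 1:02d}" for i in range(design.n_guilty)]
    i = [f"I{j + 1:02d}" for j in range(design.n_innocent)]
    return g + i


def generate_dataset(design: StudyDesign) -> ThermalDataset:
    """Generate one complete synthetic dataset; identical seed, identical data."""
    rng = np.random.default_rng(design.seed)
    n_t = design.n_samples_per_function
    times = np.arange(n_t) / design.rate_hz
    g_t = effect_template(times, design.window_s)

    ids = _participant_ids(design)
    conditions = ["guilty"] * design.n_guilty + ["innocent"] * design.n_innocent
    baselines = {}
    samples = []
    n_q = design.n_questions
    for pid, cond in zip(ids, conditions):
        if cond == "guilty":
            b = design.baseline_mean_g + design.baseline_sd_g * rng.standard_normal()
        else:
            b = design.baseline_mean_i + design.baseline_sd_i * rng.standard_normal()
        baselines[pid] = float(b)
        drift_slopes = design.drift_sd * rng.standard_normal(n_q)
        smooth_noise = _ar1_noise(rng, (n_q, n_t), design.ar_coef, design.noise_smooth_sd)
        sensor_noise = design.noise_sensor_sd * rng.standard_normal((n_q, n_t)) if design.noise_sensor_sd else 0.0
        for q in range(n_q):
            relevance = "RE" if q < design.n_relevant else "IR"
            delta = cell_delta(design, cond, relevance)
            temps = b + drift_slopes[q] * times / design.window_s + delta * g_t + smooth_noise[q]
            if design.noise_sensor_sd:
                temps = temps + sensor_noise[q]
            if design.quantization_step > 0:
                temps = np.round(temps / design.quantization_step) * design.quantization_step
            samples.append(
                FunctionSample(
                    participant_id=pid,
                    condition=cond,
                    question_id=f"Q{q + 1:02d}",
                    relevance=relevance,
                    times=times.copy(),
                    temps=temps,
                )
            )
    return ThermalDataset(samples=samples, baselines=baselines, design=design)


@dataclass
class FrameSet:
    """Per-sample stacks of 2-D temperature grids plus the AOI mask.

    ``frames[i]`` has shape (n_times, rows, cols) and corresponds to
    ``dataset.samples[i]``; the single hottest in-mask pixel of each frame
    carries the trajectory value, and a cold "fiducial marker" pixel (the
    metallic tracking sticker, which images far below skin temperature)
    sits outside the AOI.
    """

    frames: list
    mask: np.ndarray
    dataset: ThermalDataset
    fiducial: tuple


FIDUCIAL_TEMP_C = 15.0


def generate_frames(design: StudyDesign, grid_shape: tuple = (8, 8)) -> FrameSet:
    """Render each generated trajectory as a stack of thermal frames."""
    rows, cols = grid_shape
    if rows < 3 or cols < 3:
        raise ValidationError(f"grid_shape must be at least 3x3, got {grid_shape}")
    mask = np.zeros((rows, cols), dtype=bool)
    mask[1:-1, 1:-1] = True  # AOI = interior block; border is outside
    if not mask.any():
        raise ValidationError("AOI mask is empty")
    fiducial = (0, 0)
    hotspot = (rows // 2, cols // 2)

    dataset = generate_dataset(design)
    frames = []
    for sample in dataset.samples:
        n_t = len(sample.times)
        background = float(np.min(sample.temps) - 5.0)  # cooler than any skin reading
        stack = np.full((n_t, rows, cols), background)
        stack[:, hotspot[0], hotspot[1]] = sample.temps
        stack[:, fiducial[0], fiducial[1]] = FIDUCIAL_TEMP_C
        frames.append(stack)
    return FrameSet(frames=frames, mask=mask, dataset=dataset, fiducial=fiducial)
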
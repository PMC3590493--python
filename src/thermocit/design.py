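"""Study design parameters for the synthetic CIT thermal-imaging session.

The defaults reproduce the layout of the emulated study: 18 guilty and 12
innocent participants, each asked 3 crime-relevant (RE) and 12 irrelevant
(IR) sub-questions, with a 10 s response window sampled at 30 Hz, group
baseline temperatures of 35.83 +/- 0.59 degC (guilty) and 36.03 +/- 0.78
degC (innocent), and a thermal camera quantizing at 0.08 degC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .errors import ValidationError


@dataclass(frozen=True)
class StudyDesign:
    """Parameters of one synthetic CIT session batch.

    The three ``effect_*`` amplitudes are peak *differences* between factor
    levels on the scale the study reports (guilty minus innocent, RE minus
    IR, and the extra guilty-RE elevation); internally they map onto
    sum-to-zero two-way model terms with coefficients of half these values,
    all multiplied by a smooth unit-peak onset template.
    """

    n_guilty: int = 18
    n_innocent: int = 12
    n_relevant: int = 3
    n_irrelevant: int = 12
    window_s: float = 10.0
    rate_hz: float = 30.0
    baseline_mean_g: float = 35.83
    baseline_sd_g: float = 0.59
    baseline_mean_i: float = 36.03
    baseline_sd_i: float = 0.78
    effect_main_condition: float = 0.55
    effect_main_relevance: float = 0.33
    effect_interaction: float = 0.90
    noise_smooth_sd: float = 0.15
    noise_sensor_sd: float = 0.02
    drift_sd: float = 0.05
    quantization_step: float = 0.08
    ar_coef: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_guilty", "n_innocent", "n_relevant", "n_irrelevant"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 1:
                raise ValidationError(f"{name} must be an integer >= 1, got {v!r}")
        if not self.window_s > 0:
            raise ValidationError(f"window_s must be > 0, got {self.window_s}")
        if not self.rate_hz > 0:
            raise ValidationError(f"rate_hz must be > 0, got {self.rate_hz}")
        for name in ("baseline_sd_g", "baseline_sd_i", "noise_smooth_sd", "noise_sensor_sd", "drift_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.quantization_step < 0:
            raise ValidationError("quantization_step must be >= 0")
        if not 0 <= self.ar_coef < 1:
            raise ValidationError("ar_coef must lie in [0, 1)")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not math.isfinite(v):
                raise ValidationError(f"{f.name} must be finite")

    @property
    def n_participants(self) -> int:
        return self.n_guilty + self.n_innocent

    @property
    def n_questions(self) -> int:
        return self.n_relevant + self.n_irrelevant

    @property
    def n_samples_per_function(self) -> int:
        """Points per response window: round(window_s * rate_hz)."""
        return int(round(self.window_s * self.rate_hz))

    @property
    def n_functions(self) -> int:
        return self.n_participants * self.n_questions

    def replace(self, **kwargs) -> "StudyDesign":
        from dataclasses import replace

        return replace(self, **kwargs)


def noiseless(design: StudyDesign) -> StudyDesign:
    """Copy of *design* with every random/noise component switched off."""
    return design.replace(
        baseline_sd_g=0.0,
        baseline_sd_i=0.0,
        noise_smooth_sd=0.0,
        noise_sensor_sd=0.0,
        drift_sd=0.0,
        quantization_step=0.0,
    )


# field names, used by config loading to reject unknown keys
DESIGN_FIELDS = tuple(f.name for f in fields(StudyDesign))
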
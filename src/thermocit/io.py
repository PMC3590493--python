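"""File formats and run configuration.

The interchange format is a long CSV with exactly the columns
``participant_id,condition,question_id,relevance,time_s,temp_c``; one
FunctionSample per (participant, question).  Baselines travel in a
two-column sidecar CSV.  Run configuration is a YAML/JSON mapping with
one block per pipeline stage; unknown keys are rejected at load time.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DESIGN_FIELDS, StudyDesign
from .errors import ParseError, ValidationError
from .generate import ThermalDataset
from .preprocess import CONDITIONS, RELEVANCES, FunctionSample
from .smoothing import BasisSystem

LONG_CSV_COLUMNS = ["participant_id", "condition", "question_id", "relevance", "time_s", "temp_c"]


def write_long_csv(dataset: ThermalDataset | list, path) -> None:
    """Write samples to the long CSV (times and temps at full precision)."""
    samples = dataset.samples if isinstance(dataset, ThermalDataset) else dataset
    frames = []
    for s in samples:
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": s.participant_id,
                    "condition": s.condition,
                    "question_id": s.question_id,
                    "relevance": s.relevance,
                    "time_s": s.times,
                    "temp_c": s.temps,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.17g")


def read_long_csv(path, design: StudyDesign | None = None) -> ThermalDataset | list:
    """Parse the long CSV back into FunctionSamples.

    Returns a ThermalDataset when *design* is given (sample count is then
    validated against it), else the plain list of samples.  Baselines are
    not part of this file; see read_baselines_csv.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != LONG_CSV_COLUMNS:
        raise ParseError(
            f"{path}: header must be exactly {','.join(LONG_CSV_COLUMNS)}, got {','.join(map(str, df.columns))}"
        )
    for col, allowed in (("condition", CONDITIONS), ("relevance", RELEVANCES)):
        bad = df.index[~df[col].isin(allowed)]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, plus header line
            raise ParseError(f"{path} row {row}: invalid {col} value {df[col].iloc[bad[0]]!r}")
    dup = df.duplicated(subset=["participant_id", "question_id", "time_s"])
    if dup.any():
        row = int(df.index[dup][0]) + 2
        raise ParseError(f"{path} row {row}: duplicate (participant, question, time)")
    samples = []
    for (pid, qid), g in df.groupby(["participant_id", "question_id"], sort=True):
        g = g.sort_values("time_s")
        conditions = g["condition"].unique()
        relevances = g["relevance"].unique()
        if len(conditions) != 1 or len(relevances) != 1:
            raise ParseError(f"{path}: inconsistent labels for ({pid}, {qid})")
        samples.append(
            FunctionSample(
                participant_id=str(pid),
                condition=str(conditions[0]),
                question_id=str(qid),
                relevance=str(relevances[0]),
                times=g["time_s"].to_numpy(dtype=float),
                temps=g["temp_c"].to_numpy(dtype=float),
            )
        )
    if design is not None:
        baselines = {}
        return ThermalDataset(samples=samples, baselines=baselines, design=design)
    return samples


def write_baselines_csv(baselines: dict, path) -> None:
    pd.DataFrame(
        {"participant_id": list(baselines), "baseline_c": list(baselines.values())}
    ).to_csv(path, index=False, float_format="%.17g")


def read_baselines_csv(path) -> dict:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["participant_id", "baseline_c"]:
        raise ParseError(f"{path}: header must be participant_id,baseline_c")
    return dict(zip(df["participant_id"].astype(str), df["baseline_c"].astype(float)))


def write_basis_json(basis: BasisSystem, path) -> None:
    Path(path).write_text(json.dumps(basis.to_dict()))


def read_basis_json(path) -> BasisSystem:
    return BasisSystem.from_dict(json.loads(Path(path).read_text()))


def write_coefficients_csv(functions: list, path) -> None:
    """One row per smoothed function: labels then basis coefficients."""
    rows = []
    for f in functions:
        row = {
            "participant_id": f.participant_id,
            "condition": f.condition,
            "question_id": f.question_id,
            "relevance": f.relevance,
        }
        row.update({f"c{k}": v for k, v in enumerate(f.coefficients)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# run configuration


def _check_keys(section: str, given: dict, allowed) -> None:
    unknown = set(given) - set(allowed)
    if unknown:
        raise ValidationError(f"unknown key(s) in config section {section!r}: {sorted(unknown)}")


@dataclass(frozen=True)
class PreprocessConfig:
    decimate_every: int = 5
    max_gap: int = 3

    def __post_init__(self) -> None:
        if self.decimate_every < 1:
            raise ValidationError("decimate_every must be >= 1")
        if self.max_gap < 0:
            raise ValidationError("max_gap must be >= 0")


@dataclass(frozen=True)
class SmoothStageConfig:
    lam: float = 10.0
    order: int = 4
    n_basis: int | None = None  # None -> saturated (one knot per point)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if self.order < 2:
            raise ValidationError("order must be >= 2")
        if self.n_basis is not None and self.n_basis < self.order:
            raise ValidationError("n_basis must be >= order")


@dataclass(frozen=True)
class FanovaStageConfig:
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0.0 < self.ci_level < 1.0:
            raise ValidationError("ci_level must lie in (0, 1)")


@dataclass(frozen=True)
class DiscriminantStageConfig:
    rho_grid: tuple = tuple(10.0 ** k for k in range(-2, 9))
    use_loocv: bool = True
    rho: float = 10.0

    def __post_init__(self) -> None:
        if not self.rho_grid or any(r < 0 for r in self.rho_grid):
            raise ValidationError("rho_grid must be nonempty with values >= 0")
        if self.rho < 0:
            raise ValidationError("rho must be >= 0")


@dataclass(frozen=True)
class RunConfig:
    """Validated parameters for a full pipeline run."""

    simulate: StudyDesign = field(default_factory=StudyDesign)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    smooth: SmoothStageConfig = field(default_factory=SmoothStageConfig)
    fanova: FanovaStageConfig = field(default_factory=FanovaStageConfig)
    discriminate: DiscriminantStageConfig = field(default_factory=DiscriminantStageConfig)
    seed: int | None = None
    input_csv: str | None = None
    baselines_csv: str | None = None
    outdir: str = "results"
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw or {})
        _check_keys("<root>", raw, [f.name for f in fields(cls)])
        kwargs = {}
        for name, klass in (
            ("simulate", StudyDesign),
            ("preprocess", PreprocessConfig),
            ("smooth", SmoothStageConfig),
            ("fanova", FanovaStageConfig),
            ("discriminate", DiscriminantStageConfig),
        ):
            if name in raw:
                section = dict(raw.pop(name) or {})
                allowed = DESIGN_FIELDS if klass is StudyDesign else [f.name for f in fields(klass)]
                _check_keys(name, section, allowed)
                if "rho_grid" in section:
                    section["rho_grid"] = tuple(section["rho_grid"])
                kwargs[name] = klass(**section)
        kwargs.update(raw)
        cfg = cls(**kwargs)
        if cfg.seed is not None:
            object.__setattr__(cfg, "simulate", cfg.simulate.replace(seed=int(cfg.seed)))
        return cfg

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if str(path).endswith(".json"):
            raw = json.loads(text)
        else:
            raw = yaml.safe_load(text)
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["discriminate"]["rho_grid"] = list(d["discriminate"]["rho_grid"])
        return d


def dump_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
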
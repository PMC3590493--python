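"""Two-way functional ANOVA on condition (guilty/innocent) x relevance (RE/IR).

At each grid point t the model is the saturated two-way layout with
sum-to-zero (+/-1) coding,

    y_i(t) = mu(t) + alpha(t) x_cond,i + beta(t) x_rel,i
             + gamma(t) x_cond,i x_rel,i + eps_i(t),

fit by per-observation least squares.  Because the model is saturated,
the fitted cell means equal the observed cell means and the effect
functions are the unweighted cell-mean decomposition, which holds for
unbalanced cells as well.  Confidence bands are pointwise t-intervals
from the pointwise residual variance with N - 4 degrees of freedom;
functions are treated as independent observations (no within-participant
correlation adjustment) and no multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .preprocess import FunctionSample
from .smoothing import SmoothFunction

EFFECTS = ("mu", "alpha", "beta", "gamma")
_COND_SIGN = {"guilty": 1.0, "innocent": -1.0}
_REL_SIGN = {"RE": 1.0, "IR": -1.0}
CELLS = (("guilty", "RE"), ("guilty", "IR"), ("innocent", "RE"), ("innocent", "IR"))


@dataclass
class FanovaResult:
    """Estimated effect functions on a grid, plus optional pointwise bands.

    ``alpha`` is the guilty-side condition effect (innocent side is its
    negative), ``beta`` the RE-side relevance effect and ``gamma`` the
    guilty-RE interaction cell of the sum-to-zero decomposition.
    """

    grid: np.ndarray
    mu: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    n_functions: int
    cell_means: dict = field(default_factory=dict)
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)
    ci_level: float | None = None

    def effect(self, name: str) -> np.ndarray:
        if name not in EFFECTS:
            raise ValidationError(f"unknown effect {name!r}; expected one of {EFFECTS}")
        return getattr(self, name)


def _design_codes(functions) -> tuple:
    xa = np.array([_COND_SIGN[f.condition] for f in functions])
    xb = np.array([_REL_SIGN[f.relevance] for f in functions])
    for a, b in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        if not np.any((xa == a) & (xb == b)):
            cond = "guilty" if a > 0 else "innocent"
            rel = "RE" if b > 0 else "IR"
            raise ValidationError(f"empty design cell: {cond}-{rel}")
    return xa, xb


def _response_matrix(functions, grid: np.ndarray) -> np.ndarray:
    rows = []
    for f in functions:
        if isinstance(f, SmoothFunction):
            rows.append(f(grid))
        elif isinstance(f, FunctionSample):
            if len(f.times) != len(grid) or np.max(np.abs(f.times - grid)) > 1e-9:
                raise ValidationError("raw FunctionSample grids must match the evaluation grid")
            rows.append(f.temps)
        else:
            raise ValidationError(f"unsupported function type {type(f).__name__}")
    return np.stack(rows, axis=0)


def fit_fanova(functions: list, grid) -> FanovaResult:
    """Fit the pointwise two-way model on *grid*.

    *functions* may be SmoothFunctions (evaluated on the grid) or raw
    FunctionSamples already observed on the grid; all four design cells
    must be nonempty.
    """
    grid = np.asarray(grid, dtype=float)
    if len(functions) < 4:
        raise ValidationError("need at least 4 functions (one per design cell)")
    xa, xb = _design_codes(functions)
    Y = _response_matrix(functions, grid)
    X = np.column_stack([np.ones_like(xa), xa, xb, xa * xb])
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    mu, alpha, beta, gamma = coef
    cell_means = {
        (c, r): mu + _COND_SIGN[c] * alpha + _REL_SIGN[r] * beta + _COND_SIGN[c] * _REL_SIGN[r] * gamma
        for c, r in CELLS
    }
    return FanovaResult(
        grid=grid,
        mu=mu,
        alpha=alpha,
        beta=beta,
        gamma=gamma,
        n_functions=len(functions),
        cell_means=cell_means,
    )


def pointwise_ci(result: FanovaResult, functions: list, level: float = 0.95) -> dict:
    """Pointwise t confidence bands for each effect function.

    At each grid point the band is estimate +/- t_{df,(1+level)/2} * SE,
    with SE from the pointwise residual variance (df = N - 4) and the
    design matrix; stored on *result* and returned as
    {effect: (lower, upper)}.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError("level must lie in (0, 1)")
    xa, xb = _design_codes(functions)
    if len(functions) != result.n_functions:
        raise ValidationError("functions do not match the fitted result")
    df = len(functions) - 4
    if df < 1:
        raise ValidationError("insufficient residual degrees of freedom")
    Y = _response_matrix(functions, result.grid)
    X = np.column_stack([np.ones_like(xa), xa, xb, xa * xb])
    coef = np.vstack([result.mu, result.alpha, result.beta, result.gamma])
    resid = Y - X @ coef
    s2 = (resid ** 2).sum(axis=0) / df
    xtx_inv = np.linalg.inv(X.T @ X)
    tcrit = stats.t.ppf(0.5 * (1.0 + level), df)
    bands = {}
    for j, name in enumerate(EFFECTS):
        half = tcrit * np.sqrt(np.maximum(s2, 0.0) * xtx_inv[j, j])
        est = result.effect(name)
        result.ci_lower[name] = est - half
        result.ci_upper[name] = est + half
        bands[name] = (result.ci_lower[name], result.ci_upper[name])
    result.ci_level = level
    return bands


def effect_significant(result: FanovaResult, effect_name: str) -> np.ndarray:
    """Boolean grid indicator: True where the pointwise CI excludes zero."""
    if effect_name not in result.ci_lower:
        raise ValidationError("compute pointwise_ci before querying significance")
    return (result.ci_lower[effect_name] > 0.0) | (result.ci_upper[effect_name] < 0.0)


def effects_table(result: FanovaResult):
    """Tidy per-(time, term) table of estimates and bands (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for name in EFFECTS:
        est = result.effect(name)
        lo = result.ci_lower.get(name)
        hi = result.ci_upper.get(name)
        for k, t in enumerate(result.grid):
            rows.append(
                {
                    "time_s": float(t),
                    "term": name,
                    "estimate": float(est[k]),
                    "ci_lower": float(lo[k]) if lo is not None else np.nan,
                    "ci_upper": float(hi[k]) if hi is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)
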
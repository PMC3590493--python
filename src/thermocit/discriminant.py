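"""Penalized Fisher functional discriminant analysis.

The discriminant direction is a weight function w(t) = sum_a w_a phi_a(t)
maximizing the penalized Rayleigh quotient

    (w' B w) / (w' (W + rho R) w),

where B is the between-class scatter and W the pooled within-class
*covariance* (scatter divided by n - 2, the standard penalized-
discriminant normalization, so rho is on the covariance scale) of the
basis coefficient vectors under the basis inner product (i.e. wrapped on
both sides with the Gram matrix G), and R is the second-derivative
roughness penalty.  For two classes B has rank one and the leading
generalized eigenvector has the closed form

    w  propto  (W + rho R)^{-1} G (m_guilty - m_innocent),

which is how the fit is computed; the equivalence with the explicit
generalized eigenproblem is exercised in the test suite.  Scores are the
functional inner products int w(t) x(t) dt = w' G c_x, computed exactly
through G.  The decision threshold is the midpoint of the projected
class means (equal-prior rule), with the sign convention that the guilty
class projects higher.  The roughness penalty rho is chosen by
leave-one-*function*-out cross-validation on classification error, ties
broken toward the larger (smoother) rho.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .errors import DegenerateInputError, ValidationError
from .smoothing import BasisSystem, SmoothFunction

DEFAULT_RHO_GRID = tuple(10.0 ** k for k in range(-2, 9))

GUILTY, INNOCENT = "guilty", "innocent"


@dataclass(frozen=True)
class DiscriminantConfig:
    rho: float = 10.0
    rho_grid: tuple = DEFAULT_RHO_GRID
    penalty_derivative_order: int = 2

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValidationError("rho must be >= 0")
        if len(self.rho_grid) == 0 or any(r < 0 for r in self.rho_grid):
            raise ValidationError("rho_grid must be nonempty with values >= 0")
        if self.penalty_derivative_order != 2:
            raise ValidationError("only the second-derivative penalty is supported")


@dataclass
class DiscriminantModel:
    weight: SmoothFunction
    rho: float
    threshold: float
    class_means_projected: dict
    eigenvalue: float

    def __post_init__(self) -> None:
        g = self.class_means_projected[GUILTY]
        i = self.class_means_projected[INNOCENT]
        if g < i:
            raise ValidationError("sign convention violated: guilty mean must project highest")
        if g > i and not (i < self.threshold < g):
            raise ValidationError("threshold must lie strictly between distinct class means")


@dataclass
class ClassificationReport:
    n_total: int
    n_correct: int
    assignments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_correct > self.n_total:
            raise ValidationError("n_correct cannot exceed n_total")

    @property
    def rate_correct(self) -> float:
        """Correct-classification rate in percent."""
        return 100.0 * self.n_correct / self.n_total

    @property
    def rate_misclassified(self) -> float:
        return 100.0 * (self.n_total - self.n_correct) / self.n_total

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_correct": self.n_correct,
            "rate_correct": round(self.rate_correct, 2),
            "rate_misclassified": round(self.rate_misclassified, 2),
        }


def _labels_of(functions, labels) -> np.ndarray:
    if labels is None:
        labels = [f.condition for f in functions]
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(functions):
        raise ValidationError("labels length must match functions")
    bad = set(labels) - {GUILTY, INNOCENT}
    if bad:
        raise ValidationError(f"unknown class labels: {sorted(bad)}")
    return labels


def _common_basis(functions) -> BasisSystem:
    basis = functions[0].basis
    for f in functions[1:]:
        if f.basis is not basis:
            if f.basis.order != basis.order or len(f.basis.knots) != len(basis.knots) \
                    or np.max(np.abs(f.basis.knots - basis.knots)) > 1e-12:
                raise ValidationError("all functions must share one basis")
    return basis


def _fit_direction(D: np.ndarray, labels: np.ndarray, rho: float, R: np.ndarray) -> tuple:
    """Closed-form penalized Fisher direction from G-transformed rows D = C G.

    Returns (w, projected class means dict, eigenvalue).  The within
    covariance, between scatter and class means of D are exactly the
    G-wrapped quantities of the coefficient rows.
    """
    n = len(D)
    masks = {cls: labels == cls for cls in (GUILTY, INNOCENT)}
    Sw = np.zeros((D.shape[1], D.shape[1]))
    means = {}
    for cls, mask in masks.items():
        rows = D[mask]
        m = rows.mean(axis=0)
        means[cls] = m
        centered = rows - m
        Sw += centered.T @ centered
    Sw /= max(n - 2, 1)
    delta = means[GUILTY] - means[INNOCENT]
    M = Sw + rho * R
    try:
        factor = cho_factor(M)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError(
            "penalized within-class covariance is singular; increase rho"
        ) from exc
    if not np.any(delta):
        w = np.zeros(D.shape[1])
        return w, {cls: 0.0 for cls in means}, 0.0
    w = cho_solve(factor, delta)
    # Rayleigh quotient of the rank-one between scatter at the solution
    n_g, n_i = masks[GUILTY].sum(), masks[INNOCENT].sum()
    b_coef = n_g * n_i / n  # B = b_coef * delta delta'
    eigenvalue = float(b_coef * (w @ delta) ** 2 / (w @ M @ w))
    proj = {cls: float(w @ m) for cls, m in means.items()}
    if proj[GUILTY] < proj[INNOCENT]:
        w = -w
        proj = {cls: -v for cls, v in proj.items()}
    return w, proj, eigenvalue


def fit_fld(functions: list, labels=None, config: DiscriminantConfig = DiscriminantConfig()) -> DiscriminantModel:
    """Fit the penalized functional Fisher discriminant at config.rho."""
    labels = _labels_of(functions, labels)
    for cls in (GUILTY, INNOCENT):
        if np.sum(labels == cls) < 2:
            raise ValidationError(f"class {cls!r} needs at least 2 functions")
    basis = _common_basis(functions)
    C = np.stack([f.coefficients for f in functions])
    D = C @ basis.gram_matrix
    w, proj, eigenvalue = _fit_direction(D, labels, config.rho, basis.penalty_matrix)
    return DiscriminantModel(
        weight=SmoothFunction(basis=basis, coefficients=w),
        rho=config.rho,
        threshold=0.5 * (proj[GUILTY] + proj[INNOCENT]),
        class_means_projected=proj,
        eigenvalue=eigenvalue,
    )


def project(model: DiscriminantModel, fn: SmoothFunction) -> float:
    """Score of a function: int w(t) fn(t) dt via the basis Gram matrix."""
    basis = model.weight.basis
    _common_basis([model.weight, fn])
    return float(model.weight.coefficients @ basis.gram_matrix @ fn.coefficients)


def classify(model: DiscriminantModel, functions: list, labels=None) -> ClassificationReport:
    """Assign guilty iff the projection exceeds the threshold; report rates."""
    labels = _labels_of(functions, labels)
    assignments = []
    n_correct = 0
    for f, truth in zip(functions, labels):
        score = project(model, f)
        predicted = GUILTY if score > model.threshold else INNOCENT
        correct = predicted == truth
        n_correct += correct
        assignments.append(
            {"participant_id": f.participant_id, "question_id": f.question_id,
             "score": score, "predicted": predicted, "truth": truth, "correct": bool(correct)}
        )
    return ClassificationReport(n_total=len(functions), n_correct=n_correct, assignments=assignments)


def loocv_select_rho(functions: list, labels=None, rho_grid=DEFAULT_RHO_GRID) -> tuple:
    """Choose rho by leave-one-function-out classification error.

    Returns (selected_rho, {rho: cv_error}).  Ties go to the largest
    (smoothest) rho.  Per-fold scatter is obtained by rank-one downdates
    of the full-sample class sums, so the cost per fold is one Cholesky
    factorization.
    """
    rho_grid = tuple(rho_grid)
    if not rho_grid:
        raise ValidationError("rho_grid must be nonempty")
    labels = _labels_of(functions, labels)
    for cls in (GUILTY, INNOCENT):
        if np.sum(labels == cls) < 3:
            raise ValidationError(
                f"class {cls!r} needs at least 3 functions so every training fold keeps both classes"
            )
    basis = _common_basis(functions)
    R = basis.penalty_matrix
    C = np.stack([f.coefficients for f in functions])
    D = C @ basis.gram_matrix
    n, nb = D.shape
    masks = {cls: labels == cls for cls in (GUILTY, INNOCENT)}
    sums = {cls: D[mask].sum(axis=0) for cls, mask in masks.items()}
    outer = {cls: D[mask].T @ D[mask] for cls, mask in masks.items()}
    counts = {cls: int(mask.sum()) for cls, mask in masks.items()}

    cv_error = {}
    for rho in rho_grid:
        errors = 0
        for i in range(n):
            cls_i = labels[i]
            d_i = D[i]
            cnt = dict(counts)
            cnt[cls_i] -= 1
            means = {}
            Sw = np.zeros((nb, nb))
            for cls in (GUILTY, INNOCENT):
                s = sums[cls] - (d_i if cls == cls_i else 0.0)
                o = outer[cls] - (np.outer(d_i, d_i) if cls == cls_i else 0.0)
                m = s / cnt[cls]
                means[cls] = m
                Sw += o - cnt[cls] * np.outer(m, m)
            Sw /= n - 3
            delta = means[GUILTY] - means[INNOCENT]
            try:
                factor = cho_factor(Sw + rho * R)
            except np.linalg.LinAlgError as exc:
                raise DegenerateInputError(
                    f"penalized within-class covariance singular at rho={rho:g}"
                ) from exc
            w = cho_solve(factor, delta)
            pg, pi = float(w @ means[GUILTY]), float(w @ means[INNOCENT])
            if pg < pi:
                w, pg, pi = -w, -pg, -pi
            predicted = GUILTY if float(w @ d_i) > 0.5 * (pg + pi) else INNOCENT
            errors += predicted != labels[i]
        cv_error[rho] = errors / n
    best = min(cv_error, key=lambda r: (cv_error[r], -r))
    return best, cv_error
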
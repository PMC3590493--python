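"""Roughness-penalty B-spline smoothing of temperature trajectories.

A trajectory y observed at times t_1..t_n is represented as
x(t) = sum_a c_a phi_a(t) on a clamped B-spline basis, with coefficients
minimizing

    sum_i (y_i - x(t_i))^2 + lambda * int (x''(t))^2 dt.

The normal equations are (Phi' Phi + lambda R) c = Phi' y, where R is the
second-derivative penalty matrix, assembled exactly by per-interval
Gauss-Legendre quadrature (the integrand is piecewise polynomial).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline

from .errors import DegenerateInputError, ValidationError
from .preprocess import FunctionSample

_DOMAIN_TOL = 1e-9


@dataclass(frozen=True, eq=False)
class BasisSystem:
    """Clamped (open-uniform) B-spline basis on [0, window_s].

    ``order`` is the spline order (degree + 1; 4 = cubic).  ``knots`` is
    the full knot vector including the repeated boundary knots.
    """

    order: int
    knots: np.ndarray
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def n_basis(self) -> int:
        return len(self.knots) - self.order

    @property
    def domain(self) -> tuple:
        return (float(self.knots[0]), float(self.knots[-1]))

    def evaluate(self, times, nu: int = 0) -> np.ndarray:
        """Matrix of basis-function values (or nu-th derivatives) at *times*.

        Shape (len(times), n_basis).  Derivatives above the spline degree
        are identically zero.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        n = self.n_basis
        if nu > self.degree:
            return np.zeros((len(times), n))
        spl = BSpline(self.knots, np.eye(n), self.degree, extrapolate=True)
        if nu:
            spl = spl.derivative(nu)
        return spl(times)

    def _quadrature(self, npts: int) -> tuple:
        """Gauss-Legendre nodes/weights over each inter-knot interval."""
        breaks = np.unique(self.knots)
        xg, wg = leggauss(npts)
        a, b = breaks[:-1], breaks[1:]
        half = 0.5 * (b - a)
        nodes = (half[:, None] * (xg[None, :] + 1.0) + a[:, None]).ravel()
        weights = (half[:, None] * wg[None, :]).ravel()
        return nodes, weights

    def _moment_matrix(self, nu: int) -> np.ndarray:
        """int D^nu phi_a(t) D^nu phi_b(t) dt, exact for the piecewise
        polynomial integrand (degree 2*(degree - nu))."""
        key = ("moment", nu)
        if key not in self._cache:
            if nu > self.degree:
                m = np.zeros((self.n_basis, self.n_basis))
            else:
                npts = max(self.degree - nu + 1, 1)
                nodes, weights = self._quadrature(npts)
                d = self.evaluate(nodes, nu=nu)
                m = d.T @ (weights[:, None] * d)
                m = 0.5 * (m + m.T)
            self._cache[key] = m
        return self._cache[key]

    @property
    def penalty_matrix(self) -> np.ndarray:
        """Second-derivative roughness penalty R."""
        return self._moment_matrix(2)

    @property
    def penalty_sqrt(self) -> np.ndarray:
        """A matrix L with L'L = R (symmetric eigen square root).

        Used to solve the penalized normal equations as an augmented
        least-squares problem, which stays stable for very large lambda
        where forming Phi'Phi + lambda R loses precision.
        """
        key = ("penalty_sqrt",)
        if key not in self._cache:
            evals, evecs = np.linalg.eigh(self.penalty_matrix)
            # zero out the numerically-null space (constant+linear span) so
            # that lambda -> infinity shrinks toward it, not through it
            evals = np.where(evals > 1e-12 * evals.max(), evals, 0.0)
            self._cache[key] = np.sqrt(evals)[:, None] * evecs.T
        return self._cache[key]

    @property
    def gram_matrix(self) -> np.ndarray:
        """Basis Gram matrix G[a,b] = int phi_a phi_b dt (exact)."""
        return self._moment_matrix(0)

    def to_dict(self) -> dict:
        return {"order": self.order, "knots": [float(k) for k in self.knots]}

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSystem":
        return cls(order=int(d["order"]), knots=np.asarray(d["knots"], dtype=float))


@dataclass(frozen=True)
class SmoothConfig:
    """Roughness-penalty weight; the study's default is lambda = 10."""

    lam: float = 10.0
    penalty_derivative_order: int = 2

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValidationError("lambda must be >= 0")
        if self.penalty_derivative_order != 2:
            raise ValidationError("only the second-derivative penalty is supported")


@dataclass(frozen=True, eq=False)
class SmoothFunction:
    """A smoothed trajectory in basis-coefficient form, labels carried along."""

    basis: BasisSystem
    coefficients: np.ndarray
    participant_id: str | None = None
    condition: str | None = None
    question_id: str | None = None
    relevance: str | None = None

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if coef.shape != (self.basis.n_basis,):
            raise ValidationError("coefficient vector length must equal n_basis")
        if not np.all(np.isfinite(coef)):
            raise ValidationError("coefficients must be finite")

    def __call__(self, times) -> np.ndarray:
        return evaluate(self, times)


def build_basis(window_s: float, n_basis: int, order: int = 4) -> BasisSystem:
    """Clamped B-spline basis with uniform interior knots on [0, window_s]."""
    if order < 2:
        raise ValidationError("order must be >= 2")
    if n_basis < order:
        raise ValidationError(f"n_basis ({n_basis}) must be >= order ({order})")
    if window_s <= 0:
        raise ValidationError("window_s must be > 0")
    n_interior = n_basis - order
    interior = np.linspace(0.0, window_s, n_interior + 2)[1:-1]
    knots = np.concatenate([np.zeros(order), interior, np.full(order, window_s)])
    return BasisSystem(order=order, knots=knots)


def default_basis(window_s: float, n_points: int, order: int = 4) -> BasisSystem:
    """Saturated-knot basis: one knot per observation point (n_basis = n + order - 2)."""
    return build_basis(window_s, n_points + order - 2, order)


def _solve_penalized(phi: np.ndarray, y: np.ndarray, lam: float, basis: BasisSystem) -> np.ndarray:
    """Minimize ||y - phi c||^2 + lam c'Rc via the augmented LS system
    [phi; sqrt(lam) L] c ~ [y; 0] with L'L = R (QR/SVD, stable in lam)."""
    n_basis = phi.shape[1]
    if lam > 0:
        a = np.vstack([phi, np.sqrt(lam) * basis.penalty_sqrt])
        zeros_shape = (n_basis,) + (() if y.ndim == 1 else (y.shape[1],))
        rhs = np.concatenate([y, np.zeros(zeros_shape)], axis=0)
    else:
        a, rhs = phi, y
    coef, _, rank, _ = np.linalg.lstsq(a, rhs, rcond=None)
    if rank < n_basis:
        raise DegenerateInputError(
            "singular smoothing system; increase lambda or reduce n_basis"
        )
    return coef


def smooth(sample: FunctionSample, basis: BasisSystem, config: SmoothConfig = SmoothConfig()) -> SmoothFunction:
    """Penalized least-squares fit of one trajectory."""
    if len(sample.times) < basis.n_basis and config.lam == 0:
        raise ValidationError("unpenalized fit needs at least n_basis observations")
    phi = basis.evaluate(sample.times)
    coef = _solve_penalized(phi, sample.temps, config.lam, basis)
    return SmoothFunction(
        basis=basis,
        coefficients=coef,
        participant_id=sample.participant_id,
        condition=sample.condition,
        question_id=sample.question_id,
        relevance=sample.relevance,
    )


def smooth_many(samples: list, basis: BasisSystem, config: SmoothConfig = SmoothConfig()) -> list:
    """Smooth many trajectories sharing one time grid with a single factorization."""
    if not samples:
        return []
    times = samples[0].times
    for s in samples[1:]:
        if len(s.times) != len(times) or np.max(np.abs(s.times - times)) > _DOMAIN_TOL:
            raise ValidationError("smooth_many requires a common time grid")
    if len(times) < basis.n_basis and config.lam == 0:
        raise ValidationError("unpenalized fit needs at least n_basis observations")
    phi = basis.evaluate(times)
    Y = np.stack([s.temps for s in samples], axis=1)
    coefs = _solve_penalized(phi, Y, config.lam, basis)
    return [
        SmoothFunction(
            basis=basis,
            coefficients=coefs[:, j],
            participant_id=s.participant_id,
            condition=s.condition,
            question_id=s.question_id,
            relevance=s.relevance,
        )
        for j, s in enumerate(samples)
    ]


def evaluate(fn: SmoothFunction, times) -> np.ndarray:
    """Evaluate a smoothed function; times must lie in the basis domain."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    lo, hi = fn.basis.domain
    if times.min() < lo - _DOMAIN_TOL or times.max() > hi + _DOMAIN_TOL:
        raise ValidationError(f"evaluation times outside the basis domain [{lo}, {hi}]")
    return fn.basis.evaluate(times) @ fn.coefficients


def roughness(fn: SmoothFunction) -> float:
    """Integrated squared second derivative, c' R c (>= 0)."""
    c = fn.coefficients
    value = float(c @ fn.basis.penalty_matrix @ c)
    return max(value, 0.0)
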
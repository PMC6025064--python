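"""Penalized B-spline smoothing of time-intensity and importance series.

Discretely sampled curves (raw time-intensity ratings, or relative-
importance values on a time grid) are represented as B-spline basis
expansions so they can be evaluated anywhere in the observed time
domain and differentiated analytically.  Smoothing minimises

    sum_j (y_j - f(t_j))^2  +  lambda * int f''(t)^2 dt

over coefficient vectors of the basis expansion f = sum_k c_k B_k.
When ``lambda`` is not supplied it is chosen by generalized
cross-validation over a fixed log-spaced grid, which keeps the whole
procedure deterministic.

Defaults follow common functional-data practice: cubic splines
(order 4), equally spaced knots, at most 20 basis functions, roughness
penalty on the second derivative, and no extrapolation outside the
observed domain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

from .exceptions import NumericalError, ValidationError

__all__ = [
    "BSplineBasis",
    "FunctionalCurve",
    "BSplineSmoother",
    "make_bspline_basis",
    "smooth_penalized",
    "eval_curve",
]

GCV_GRID = np.logspace(-6, 4, 41)
_DOMAIN_EPS = 1e-9


@dataclass(frozen=True)
class BSplineBasis:
    """B-spline basis on [t_min, t_max]: n_basis = order + #interior knots."""

    t_min: float
    t_max: float
    order: int
    interior_knots: tuple

    def __post_init__(self):
        if self.t_max <= self.t_min:
            raise ValidationError("t_max must exceed t_min")
        if self.order < 1:
            raise ValidationError("order must be >= 1")
        ik = tuple(float(k) for k in self.interior_knots)
        object.__setattr__(self, "interior_knots", ik)
        if any(k <= self.t_min or k >= self.t_max for k in ik):
            raise ValidationError("interior knots must lie strictly inside the domain")
        if any(b < a for a, b in zip(ik, ik[1:])):
            raise ValidationError("interior knots must be nondecreasing")

    @property
    def n_basis(self) -> int:
        return self.order + len(self.interior_knots)

    @property
    def degree(self) -> int:
        return self.order - 1

    @property
    def knots(self) -> np.ndarray:
        """Full (clamped) knot vector."""
        return np.concatenate([
            np.full(self.order, self.t_min),
            np.asarray(self.interior_knots, dtype=float),
            np.full(self.order, self.t_max),
        ])

    def _check_domain(self, t: np.ndarray):
        if np.any(t < self.t_min - _DOMAIN_EPS) or np.any(t > self.t_max + _DOMAIN_EPS):
            raise ValidationError(
                f"time outside basis domain [{self.t_min}, {self.t_max}]; "
                "no extrapolation"
            )

    def design_matrix(self, t, deriv: int = 0) -> np.ndarray:
        """Matrix B with B[j, k] = d^deriv B_k / dt^deriv at t_j."""
        t = np.asarray(t, dtype=float).ravel()
        self._check_domain(t)
        tc = np.clip(t, self.t_min, self.t_max)
        kn = self.knots
        if deriv == 0:
            return BSpline.design_matrix(tc, kn, self.degree,
                                         extrapolate=False).toarray()
        B = np.empty((tc.size, self.n_basis))
        for k in range(self.n_basis):
            c = np.zeros(self.n_basis)
            c[k] = 1.0
            B[:, k] = BSpline(kn, c, self.degree)(tc, nu=deriv)
        return B

    def penalty_matrix(self, deriv: int = 2) -> np.ndarray:
        """Gram matrix of deriv-th basis derivatives, by exact Gauss quadrature.

        The integrand on each knot span is a polynomial of degree at
        most 2*(degree - deriv); order-of-basis Gauss points per span
        integrate it exactly.
        """
        spans = np.unique(np.concatenate([[self.t_min],
                                          np.asarray(self.interior_knots),
                                          [self.t_max]]))
        npts = max(self.order, 3)
        xg, wg = leggauss(npts)
        P = np.zeros((self.n_basis, self.n_basis))
        for a, b in zip(spans[:-1], spans[1:]):
            if b <= a:
                continue
            mid, half = 0.5 * (a + b), 0.5 * (b - a)
            tq = mid + half * xg
            Bq = self.design_matrix(tq, deriv=deriv)
            P += half * (Bq * wg[:, None]).T @ Bq
        return P

    def to_dict(self) -> dict:
        return {"t_min": self.t_min, "t_max": self.t_max, "order": self.order,
                "interior_knots": list(self.interior_knots)}

    @classmethod
    def from_dict(cls, d: dict) -> "BSplineBasis":
        return cls(d["t_min"], d["t_max"], d["order"],
                   tuple(d["interior_knots"]))


def make_bspline_basis(t_min: float, t_max: float, n_basis: int,
                       order: int = 4) -> BSplineBasis:
    """Basis with ``n_basis`` functions and equally spaced interior knots."""
    if n_basis < order:
        raise ValidationError(f"n_basis ({n_basis}) must be >= order ({order})")
    n_interior = n_basis - order
    interior = np.linspace(t_min, t_max, n_interior + 2)[1:-1]
    return BSplineBasis(float(t_min), float(t_max), int(order), tuple(interior))


@dataclass
class FunctionalCurve:
    """One smooth curve: basis expansion with a label."""

    basis: BSplineBasis
    coefficients: np.ndarray
    label: str = ""

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float).ravel()
        if c.shape != (self.basis.n_basis,):
            raise ValidationError(
                f"expected {self.basis.n_basis} coefficients, got {c.shape}"
            )
        self.coefficients = c

    def __call__(self, t, deriv: int = 0):
        return self.basis.design_matrix(t, deriv=deriv) @ self.coefficients

    @property
    def domain(self):
        return (self.basis.t_min, self.basis.t_max)

    def derivative_curve(self, deriv: int = 1) -> "FunctionalCurve":
        """The derivative as a curve over the same knot span (lower order)."""
        sp = BSpline(self.basis.knots, self.coefficients,
                     self.basis.degree).derivative(deriv)
        new_order = self.basis.order - deriv
        interior = tuple(sp.t[new_order:-new_order].tolist())
        new_basis = BSplineBasis(self.basis.t_min, self.basis.t_max,
                                 new_order, interior)
        return FunctionalCurve(new_basis, sp.c[:new_basis.n_basis],
                               label=f"{self.label}'" if self.label else "")

    def to_dict(self) -> dict:
        return {"basis": self.basis.to_dict(),
                "coefficients": self.coefficients.tolist(),
                "label": self.label}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "FunctionalCurve":
        return cls(BSplineBasis.from_dict(d["basis"]),
                   np.asarray(d["coefficients"]), d.get("label", ""))

    @classmethod
    def from_json(cls, s: str) -> "FunctionalCurve":
        return cls.from_dict(json.loads(s))


class BSplineSmoother(BaseEstimator):
    """Penalized least-squares smoother producing a FunctionalCurve.

    Parameters
    ----------
    n_basis : int or None
        Number of basis functions; None means min(n_points, 20).
    order : int, default 4 (cubic)
    lam : float or None
        Roughness-penalty weight on the integrated squared second
        derivative.  None selects lambda by GCV over ``GCV_GRID``.
    basis : BSplineBasis or None
        Explicit basis; overrides n_basis/order.

    Attributes
    ----------
    curve_ : FunctionalCurve
    lambda_ : float
    gcv_ : float            (GCV score at the chosen lambda)
    dof_ : float            (trace of the smoothing hat matrix)
    residuals_ : ndarray
    """

    def __init__(self, n_basis=None, order: int = 4, lam=None, basis=None,
                 label: str = ""):
        self.n_basis = n_basis
        self.order = order
        self.lam = lam
        self.basis = basis
        self.label = label

    def fit(self, t, y):
        t = np.asarray(t, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValidationError("times and values must have equal length")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(t)):
            raise ValidationError("times and values must be finite")
        if np.unique(t).size < 2:
            raise ValidationError("need at least 2 distinct observation times")

        basis = self.basis
        if basis is None:
            nb = self.n_basis if self.n_basis is not None else min(t.size, 20)
            nb = max(nb, self.order)
            basis = make_bspline_basis(t.min(), t.max(), nb, self.order)
        B = basis.design_matrix(t)
        P = basis.penalty_matrix(2) if basis.order > 2 else np.zeros(
            (basis.n_basis, basis.n_basis))
        BtB = B.T @ B
        Bty = B.T @ y

        def solve(lam):
            M = BtB + lam * P
            try:
                return np.linalg.solve(M, Bty)
            except np.linalg.LinAlgError as exc:
                raise NumericalError(
                    f"singular smoothing system (lambda={lam}): {exc}") from exc

        if self.lam is not None:
            lam = float(self.lam)
            if lam == 0.0:
                # unpenalized: least squares, tolerant of exact interpolation
                c, *_ = np.linalg.lstsq(B, y, rcond=None)
                if np.linalg.matrix_rank(B) < min(B.shape):
                    pass  # minimum-norm solution; residuals still reported
            else:
                c = solve(lam)
            gcv = np.nan
        else:
            best = None
            n = t.size
            for lam_try in GCV_GRID:
                M = BtB + lam_try * P
                try:
                    Minv = np.linalg.inv(M)
                except np.linalg.LinAlgError:
                    continue
                c_try = Minv @ Bty
                fitted = B @ c_try
                df = float(np.trace(B @ Minv @ B.T))
                denom = (1.0 - df / n) ** 2
                if denom <= 0:
                    continue
                score = float(((y - fitted) ** 2).mean() / denom)
                if best is None or score < best[0]:
                    best = (score, lam_try, c_try)
            if best is None:
                raise NumericalError("GCV failed for every candidate lambda")
            gcv, lam, c = best

        fitted = B @ c
        self.basis_ = basis
        self.curve_ = FunctionalCurve(basis, c, label=self.label)
        self.lambda_ = float(lam)
        self.gcv_ = float(gcv) if gcv == gcv else float("nan")
        M = BtB + self.lambda_ * P
        try:
            self.dof_ = float(np.trace(B @ np.linalg.solve(M, B.T)))
        except np.linalg.LinAlgError:
            self.dof_ = float(basis.n_basis)
        self.residuals_ = y - fitted
        return self

    def predict(self, t, deriv: int = 0):
        return self.curve_(t, deriv=deriv)


def smooth_penalized(times, values, basis: BSplineBasis, lam) -> FunctionalCurve:
    """Penalized smooth of one series on an explicit basis (thin wrapper)."""
    sm = BSplineSmoother(basis=basis, lam=lam)
    sm.fit(times, values)
    return sm.curve_


def eval_curve(curve: FunctionalCurve, times, deriv: int = 0) -> np.ndarray:
    """Evaluate a curve or its derivative; errors outside the domain."""
    if deriv not in (0, 1, 2):
        raise ValidationError("deriv must be 0, 1 or 2")
    return curve(times, deriv=deriv)
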
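"""Fuzzy-measure (capacity) algebra and Choquet-integral regression.

A *capacity* (fuzzy measure) on a set of sensory attributes
``N = {1, ..., n}`` is a set function ``v`` with ``v(∅) = 0``,
``v(N) = 1`` and ``v(S) ≤ v(T)`` whenever ``S ⊆ T``.  It generalises
additive importance weights: the Choquet integral of an attribute
profile with respect to ``v`` reduces to a weighted mean when ``v`` is
additive, and otherwise captures complementarity / substitutivity
between attributes.  Relative importance is summarised by the Shapley
value of ``v`` (components sum to one) and pairwise dependence by the
Shapley interaction index (positive = complementary, negative =
substitutive).

Subsets are encoded as bitmasks over the attribute order, so a capacity
on ``n`` attributes is a vector of length ``2**n`` indexed by mask.

The identification problem — recover a capacity from observed attribute
profiles and overall-liking scores — is a convex quadratic programme
over Möbius coefficients with normalisation (equality) and monotonicity
(inequality) constraints; :class:`ChoquetRegression` solves it with an
exact KKT solve when no monotonicity constraint is active and an SLSQP
polish otherwise, optionally restricted to k-additive capacities and
ridge-regularised toward the uniform additive capacity (which makes the
heavily under-determined fits of small sensory designs well posed and
deterministic).
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import NumericalError, ValidationError

__all__ = [
    "Capacity",
    "MobiusCapacity",
    "PointwiseFit",
    "ChoquetRegression",
    "to_mobius",
    "from_mobius",
    "choquet",
    "choquet_mobius",
    "shapley",
    "interaction_matrix",
    "check_monotone",
    "scale_minmax",
    "unscale_minmax",
    "fit_capacity_ls",
]

DEFAULT_MONOTONE_TOL = 1e-9


# ---------------------------------------------------------------------------
# bitmask helpers

def subset_masks(n: int):
    """All subset bitmasks of an n-element ground set, 0 .. 2**n - 1."""
    return range(1 << n)


def mask_size(mask: int) -> int:
    return bin(mask).count("1")


def members(mask: int, n: int):
    """Indices of the attributes present in ``mask``."""
    return [i for i in range(n) if mask >> i & 1]


def mask_of(indices) -> int:
    m = 0
    for i in indices:
        m |= 1 << i
    return m


def subsets_of(mask: int):
    """Iterate over all submasks of ``mask`` (including 0 and ``mask``)."""
    sub = mask
    while True:
        yield sub
        if sub == 0:
            return
        sub = (sub - 1) & mask


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class Capacity:
    """Normalised monotone set function on an ordered attribute set.

    ``values[mask]`` is v(S) for the subset S encoded by ``mask`` over
    ``attributes``.  Construction validates normalisation and
    monotonicity (within ``DEFAULT_MONOTONE_TOL``).
    """

    attributes: tuple
    values: np.ndarray

    def __post_init__(self):
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        n = len(attrs)
        if n < 1:
            raise ValidationError("capacity needs at least one attribute")
        if len(set(attrs)) != n:
            raise ValidationError("attribute labels must be unique")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (1 << n,):
            raise ValidationError(
                f"expected {1 << n} subset values for {n} attributes, got {v.shape}"
            )
        object.__setattr__(self, "values", v)
        if abs(v[0]) > 1e-12:
            raise ValidationError(f"v(empty set) must be 0, got {v[0]!r}")
        full = (1 << n) - 1
        if abs(v[full] - 1.0) > 1e-9:
            raise ValidationError(f"v(full set) must be 1, got {v[full]!r}")
        bad = check_monotone_masks(v, n, DEFAULT_MONOTONE_TOL)
        if bad:
            s, t = bad[0]
            raise ValidationError(
                "capacity not monotone: v(%s)=%.6g > v(%s)=%.6g"
                % (self._label(s), v[s], self._label(t), v[t])
            )

    @property
    def n(self) -> int:
        return len(self.attributes)

    def _label(self, mask: int) -> str:
        names = sorted(self.attributes[i] for i in members(mask, self.n))
        return "{" + "+".join(names) + "}"

    def value(self, subset) -> float:
        """v(S) for S given as an iterable of attribute labels."""
        idx = {a: i for i, a in enumerate(self.attributes)}
        return float(self.values[mask_of(idx[a] for a in subset)])

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        out = {}
        for mask in subset_masks(self.n):
            if mask == 0:
                continue
            key = "+".join(sorted(self.attributes[i] for i in members(mask, self.n)))
            out[key] = float(self.values[mask])
        return {"attributes": list(self.attributes), "values": out}

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "Capacity":
        attrs = tuple(d["attributes"])
        idx = {a: i for i, a in enumerate(attrs)}
        v = np.zeros(1 << len(attrs))
        for key, val in d["values"].items():
            v[mask_of(idx[a] for a in key.split("+"))] = val
        return cls(attrs, v)

    @classmethod
    def from_json(cls, s: str) -> "Capacity":
        return cls.from_dict(json.loads(s))

    @classmethod
    def additive(cls, attributes, weights) -> "Capacity":
        """Additive capacity v(S) = sum of weights over S (weights sum to 1)."""
        w = np.asarray(weights, dtype=float)
        n = len(w)
        v = np.zeros(1 << n)
        for mask in subset_masks(n):
            v[mask] = w[members(mask, n)].sum()
        return cls(tuple(attributes), v)

    @classmethod
    def uniform(cls, attributes) -> "Capacity":
        n = len(tuple(attributes))
        return cls.additive(attributes, np.full(n, 1.0 / n))


@dataclass(frozen=True)
class MobiusCapacity:
    """Möbius representation of a capacity.

    ``coefficients[mask]`` is m(S); the zeta transform
    v(S) = Σ_{T ⊆ S} m(T) recovers the direct representation.
    ``k_additive`` records the interaction order: "full", or an integer
    k meaning m(S) = 0 for |S| > k.
    """

    attributes: tuple
    coefficients: np.ndarray
    k_additive: object = "full"

    def __post_init__(self):
        attrs = tuple(self.attributes)
        object.__setattr__(self, "attributes", attrs)
        n = len(attrs)
        m = np.asarray(self.coefficients, dtype=float)
        if m.shape != (1 << n,):
            raise ValidationError(
                f"expected {1 << n} Möbius coefficients for {n} attributes"
            )
        object.__setattr__(self, "coefficients", m)
        if abs(m[0]) > 1e-12:
            raise ValidationError("m(empty set) must be 0")
        if abs(m.sum() - 1.0) > 1e-8:
            raise ValidationError(
                f"Möbius coefficients must sum to 1, got {m.sum()!r}"
            )
        k = self.k_additive
        if k != "full":
            k = int(k)
            if k < 1:
                raise ValidationError("k_additive must be >= 1")
            for mask in subset_masks(n):
                if mask_size(mask) > k and m[mask] != 0.0:
                    raise ValidationError(
                        f"subset of size {mask_size(mask)} has nonzero coefficient "
                        f"but k_additive={k}"
                    )
            object.__setattr__(self, "k_additive", k)

    @property
    def n(self) -> int:
        return len(self.attributes)

    def shapley(self) -> np.ndarray:
        """Shapley value: phi_i = Σ_{S ∋ i} m(S) / |S|."""
        n = self.n
        phi = np.zeros(n)
        for mask in subset_masks(n):
            if mask == 0:
                continue
            share = self.coefficients[mask] / mask_size(mask)
            for i in members(mask, n):
                phi[i] += share
        return phi

    def interaction_matrix(self) -> np.ndarray:
        """Shapley interaction index: I_ij = Σ_{S ⊇ {i,j}} m(S) / (|S| - 1)."""
        n = self.n
        I = np.zeros((n, n))
        for mask in subset_masks(n):
            s = mask_size(mask)
            if s < 2:
                continue
            share = self.coefficients[mask] / (s - 1)
            for i, j in itertools.combinations(members(mask, n), 2):
                I[i, j] += share
                I[j, i] += share
        return I


@dataclass
class PointwiseFit:
    """Result of one pointwise capacity identification."""

    capacity: MobiusCapacity
    shapley: np.ndarray
    interactions: np.ndarray
    residual_sse: float
    n_samples: int
    n_parameters: int
    underdetermined: bool
    scaling: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# transforms and aggregation

def to_mobius(capacity: Capacity) -> MobiusCapacity:
    """Möbius transform m(S) = Σ_{T ⊆ S} (-1)^{|S\\T|} v(T)."""
    n = capacity.n
    v = capacity.values
    m = np.zeros_like(v)
    for mask in subset_masks(n):
        s = mask_size(mask)
        acc = 0.0
        for sub in subsets_of(mask):
            acc += (-1) ** (s - mask_size(sub)) * v[sub]
        m[mask] = acc
    return MobiusCapacity(capacity.attributes, m)


def from_mobius(mobius: MobiusCapacity) -> Capacity:
    """Zeta transform v(S) = Σ_{T ⊆ S} m(T); validates monotonicity."""
    n = mobius.n
    m = mobius.coefficients
    v = np.zeros_like(m)
    for mask in subset_masks(n):
        v[mask] = sum(m[sub] for sub in subsets_of(mask))
    v[0] = 0.0
    bad = check_monotone_masks(v, n, DEFAULT_MONOTONE_TOL)
    if bad:
        labels = []
        for s, t in bad[:5]:
            ls = "{" + "+".join(sorted(mobius.attributes[i] for i in members(s, n))) + "}"
            lt = "{" + "+".join(sorted(mobius.attributes[i] for i in members(t, n))) + "}"
            labels.append(f"v({ls})>v({lt})")
        raise ValidationError(
            "Möbius vector induces a non-monotone set function: " + ", ".join(labels)
        )
    return Capacity(mobius.attributes, v)


def choquet(capacity: Capacity, x) -> float:
    """Choquet integral of profile ``x`` (one value per attribute, in [0,1]).

    Sorted-increment form: Σ_i (x_(i) - x_(i-1)) · v(A_(i)) with the
    x_(i) ascending and A_(i) the attributes whose value is >= x_(i).
    """
    x = np.asarray(x, dtype=float)
    n = capacity.n
    if x.shape != (n,):
        raise ValidationError(f"profile must have {n} values, got shape {x.shape}")
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValidationError("profile values must lie in [0,1]; rescale first")
    order = np.argsort(x, kind="stable")
    total = 0.0
    prev = 0.0
    remaining = (1 << n) - 1
    for idx in order:
        total += (x[idx] - prev) * capacity.values[remaining]
        prev = x[idx]
        remaining &= ~(1 << idx)
    return float(total)


def choquet_mobius(mobius: MobiusCapacity, x) -> float:
    """Choquet integral in Möbius form: Σ_S m(S) · min_{i in S} x_i."""
    x = np.asarray(x, dtype=float)
    n = mobius.n
    total = 0.0
    for mask in subset_masks(n):
        if mask == 0:
            continue
        c = mobius.coefficients[mask]
        if c != 0.0:
            total += c * min(x[i] for i in members(mask, n))
    return float(total)


def shapley(capacity: Capacity) -> np.ndarray:
    """Shapley value of a capacity (direct form, average marginal gain).

    phi_i = Σ_{S ⊆ N\\{i}} |S|! (n-|S|-1)! / n! · (v(S ∪ i) - v(S)).
    """
    n = capacity.n
    v = capacity.values
    fact = [math.factorial(k) for k in range(n + 1)]
    phi = np.zeros(n)
    for i in range(n):
        bit = 1 << i
        for mask in subset_masks(n):
            if mask & bit:
                continue
            s = mask_size(mask)
            w = fact[s] * fact[n - s - 1] / fact[n]
            phi[i] += w * (v[mask | bit] - v[mask])
    return phi


def interaction_matrix(capacity: Capacity) -> np.ndarray:
    """Pairwise Shapley interaction index (direct second-difference form)."""
    n = capacity.n
    v = capacity.values
    fact = [math.factorial(k) for k in range(n + 1)]
    I = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        bi, bj = 1 << i, 1 << j
        acc = 0.0
        for mask in subset_masks(n):
            if mask & (bi | bj):
                continue
            s = mask_size(mask)
            w = fact[s] * fact[n - s - 2] / fact[n - 1]
            acc += w * (v[mask | bi | bj] - v[mask | bi] - v[mask | bj] + v[mask])
        I[i, j] = I[j, i] = acc
    return I


def check_monotone_masks(values: np.ndarray, n: int, tol: float):
    """Violated covering pairs (S, S ∪ {i}) with v(S) > v(S ∪ {i}) + tol."""
    bad = []
    for mask in subset_masks(n):
        for i in range(n):
            bit = 1 << i
            if mask & bit:
                continue
            if values[mask] > values[mask | bit] + tol:
                bad.append((mask, mask | bit))
    return bad


def check_monotone(capacity, tol: float = DEFAULT_MONOTONE_TOL):
    """List of violated (S, T) label pairs; empty iff monotone within tol.

    Accepts a :class:`Capacity` or a raw ``(attributes, values)`` pair so
    that candidate set functions can be checked before construction.
    """
    if isinstance(capacity, Capacity):
        attrs, v = capacity.attributes, capacity.values
    else:
        attrs, v = capacity
        v = np.asarray(v, dtype=float)
    n = len(attrs)
    out = []
    for s, t in check_monotone_masks(v, n, tol):
        ls = tuple(sorted(attrs[i] for i in members(s, n)))
        lt = tuple(sorted(attrs[i] for i in members(t, n)))
        out.append((ls, lt))
    return out


# ---------------------------------------------------------------------------
# scaling

@dataclass(frozen=True)
class ScaleRecord:
    lo: float
    hi: float
    constant: bool


def scale_minmax(table):
    """Column-wise affine map of a samples × variables table onto [0,1].

    Each column's observed min maps to 0 and max to 1.  A constant
    column carries no information for a Choquet fit; it is mapped to 0.5
    and flagged in its :class:`ScaleRecord`.  Returns ``(scaled,
    records)`` where records allow exact inversion via
    :func:`unscale_minmax`.
    """
    X = np.atleast_2d(np.asarray(table, dtype=float))
    if X.shape[0] < 1:
        raise ValidationError("need at least one sample to scale")
    out = np.empty_like(X)
    records = []
    for j in range(X.shape[1]):
        lo, hi = float(X[:, j].min()), float(X[:, j].max())
        if hi - lo <= 0.0:
            out[:, j] = 0.5
            records.append(ScaleRecord(lo, hi, True))
        else:
            out[:, j] = (X[:, j] - lo) / (hi - lo)
            records.append(ScaleRecord(lo, hi, False))
    return out, records


def unscale_minmax(scaled, records):
    """Invert :func:`scale_minmax` (constant columns return their value)."""
    X = np.atleast_2d(np.asarray(scaled, dtype=float)).copy()
    for j, rec in enumerate(records):
        if rec.constant:
            X[:, j] = rec.lo
        else:
            X[:, j] = X[:, j] * (rec.hi - rec.lo) + rec.lo
    return X


# ---------------------------------------------------------------------------
# identification

class ChoquetRegression(BaseEstimator, RegressorMixin):
    """Least-squares Choquet-integral regression over a k-additive capacity.

    Minimises ``Σ_i (C_m(x_i) - y_i)² + ridge·‖m - m_uniform‖²`` over
    Möbius coefficients ``m`` of subsets up to size ``k_additive``,
    subject to normalisation (Σ m = 1) and all monotonicity constraints,
    which are linear in ``m``.  ``m_uniform`` is the uniform additive
    capacity, so the ridge term shrinks toward "all attributes equally
    important, no interactions" — the natural neutral prior when the
    number of products is far below the number of coefficients, as in
    small sensory designs.

    Parameters
    ----------
    k_additive : int, default 2
        Maximal interaction order of the fitted capacity.
    ridge : float, default 1e-6
        Strength of the shrinkage toward the uniform additive capacity.
        Must be > 0 when the fit is under-determined unless
        ``allow_underdetermined`` is set.
    allow_underdetermined : bool, default False
        Permit ridge=0 with fewer samples than parameters (the optimum
        is then non-unique).

    Attributes
    ----------
    mobius_ : MobiusCapacity
    capacity_ : Capacity
    shapley_ : ndarray of shape (n_attributes,)
    interactions_ : ndarray of shape (n_attributes, n_attributes)
    residual_sse_ : float
    underdetermined_ : bool
    n_parameters_ : int
    """

    def __init__(self, k_additive: int = 2, ridge: float = 1e-6,
                 allow_underdetermined: bool = False):
        self.k_additive = k_additive
        self.ridge = ridge
        self.allow_underdetermined = allow_underdetermined

    # -- design matrix over active subsets ---------------------------------
    @staticmethod
    def _active_masks(n: int, k: int):
        return [m for m in subset_masks(n) if 1 <= mask_size(m) <= k]

    @staticmethod
    def _design(X: np.ndarray, masks) -> np.ndarray:
        n_samp = X.shape[0]
        A = np.empty((n_samp, len(masks)))
        for j, mask in enumerate(masks):
            idx = members(mask, X.shape[1])
            A[:, j] = X[:, idx].min(axis=1)
        return A

    @staticmethod
    def _monotonicity_matrix(n: int, masks) -> np.ndarray:
        """Rows G with G m >= 0 iff the induced capacity is monotone.

        One row per (attribute i, subset S ⊆ N\\{i}):
        v(S ∪ i) - v(S) = Σ_{T ⊆ S} m(T ∪ i) >= 0.
        """
        col = {mask: j for j, mask in enumerate(masks)}
        rows = []
        for i in range(n):
            bit = 1 << i
            for S in subset_masks(n):
                if S & bit:
                    continue
                g = np.zeros(len(masks))
                for T in subsets_of(S):
                    j = col.get(T | bit)
                    if j is not None:
                        g[j] += 1.0
                rows.append(g)
        return np.array(rows)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2:
            raise ValidationError("X must be 2-D (samples × attributes)")
        n_samp, n_attr = X.shape
        if y.shape[0] != n_samp:
            raise ValidationError("X and y must have the same number of samples")
        if n_attr < 2:
            raise ValidationError("need at least 2 attributes")
        if np.any(X < -1e-9) or np.any(X > 1 + 1e-9) or np.any(y < -1e-9) or np.any(y > 1 + 1e-9):
            raise ValidationError("X and y must lie in [0,1]; apply scale_minmax first")
        k = int(self.k_additive)
        if k < 1:
            raise ValidationError("k_additive must be >= 1")
        k = min(k, n_attr)

        masks = self._active_masks(n_attr, k)
        p = len(masks)
        underdetermined = n_samp < p
        if underdetermined and self.ridge <= 0 and not self.allow_underdetermined:
            raise ValidationError(
                f"{n_samp} samples < {p} coefficients with ridge=0: the optimum is "
                "non-unique; set ridge>0 or allow_underdetermined=True"
            )

        A = self._design(X, masks)
        G = self._monotonicity_matrix(n_attr, masks)
        # uniform additive capacity in the active parameterisation
        m_unif = np.zeros(p)
        for j, mask in enumerate(masks):
            if mask_size(mask) == 1:
                m_unif[j] = 1.0 / n_attr

        ridge = float(self.ridge)
        H = A.T @ A + ridge * np.eye(p)
        b = A.T @ y + ridge * m_unif

        # KKT solve with the normalisation constraint only; exact for the
        # common case where no monotonicity constraint is active.
        ones = np.ones(p)
        kkt = np.zeros((p + 1, p + 1))
        kkt[:p, :p] = 2.0 * H
        kkt[:p, p] = ones
        kkt[p, :p] = ones
        rhs = np.concatenate([2.0 * b, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"KKT system singular: {exc}") from exc
        m = sol[:p]

        if G.size and np.min(G @ m) < -1e-12:
            m = self._solve_qp(H, b, G, m_unif)

        m = m / m.sum()  # enforce normalisation exactly
        coeffs = np.zeros(1 << n_attr)
        for j, mask in enumerate(masks):
            coeffs[mask] = m[j]
        mobius = MobiusCapacity(tuple(f"x{i}" for i in range(n_attr)), coeffs,
                                k_additive=k)
        resid = A @ m - y

        self.masks_ = masks
        self.n_parameters_ = p
        self.underdetermined_ = bool(underdetermined)
        self.mobius_ = mobius
        self.capacity_ = from_mobius(mobius)
        self.shapley_ = mobius.shapley()
        self.interactions_ = mobius.interaction_matrix()
        self.residual_sse_ = float(resid @ resid)
        self.n_features_in_ = n_attr
        return self

    @staticmethod
    def _solve_qp(H, b, G, x0):
        """Minimise x'Hx - 2b'x s.t. sum(x)=1, Gx>=0 (SLSQP, warm start)."""
        p = H.shape[0]

        def fun(x):
            return float(x @ H @ x - 2.0 * b @ x)

        def jac(x):
            return 2.0 * (H @ x) - 2.0 * b

        cons = [
            {"type": "eq", "fun": lambda x: x.sum() - 1.0,
             "jac": lambda x: np.ones(p)},
            {"type": "ineq", "fun": lambda x: G @ x, "jac": lambda x: G},
        ]
        res = optimize.minimize(fun, x0, jac=jac, method="SLSQP",
                                constraints=cons,
                                options={"maxiter": 1000, "ftol": 1e-14})
        if not res.success:
            raise NumericalError(f"capacity QP failed: {res.message}")
        m = res.x
        viol = float(np.min(G @ m)) if G.size else 0.0
        if viol < -1e-7:
            raise NumericalError(
                f"capacity QP returned infeasible point (violation {viol:.2e})"
            )
        if viol < 0.0:
            # repair solver-tolerance slack by blending toward the strictly
            # feasible warm start (every monotonicity margin there is 1/n)
            margin = float(np.min(G @ x0))
            eps = -viol / (margin - viol)
            m = (1.0 - eps) * m + eps * x0
        return m

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        A = self._design(X, self.masks_)
        m = np.array([self.mobius_.coefficients[mask] for mask in self.masks_])
        return A @ m


def fit_capacity_ls(X, y, k_additive: int = 2, ridge: float = 1e-6,
                    attributes=None, allow_underdetermined: bool = False,
                    scale: bool = False) -> PointwiseFit:
    """Identify a capacity from samples by constrained least squares.

    Thin functional wrapper over :class:`ChoquetRegression`.  If
    ``scale`` is true, X and y are min–max scaled to [0,1] first and the
    scaling records are stored on the result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    records = []
    if scale:
        X, records = scale_minmax(X)
        y2, yrec = scale_minmax(y[:, None])
        y = y2[:, 0]
        records = records + yrec
    est = ChoquetRegression(k_additive=k_additive, ridge=ridge,
                            allow_underdetermined=allow_underdetermined)
    est.fit(X, y)
    mob = est.mobius_
    if attributes is not None:
        mob = MobiusCapacity(tuple(attributes), mob.coefficients,
                             k_additive=mob.k_additive)
    return PointwiseFit(
        capacity=mob,
        shapley=est.shapley_,
        interactions=est.interactions_,
        residual_sse=est.residual_sse_,
        n_samples=X.shape[0],
        n_parameters=est.n_parameters_,
        underdetermined=est.underdetermined_,
        scaling=records,
    )
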
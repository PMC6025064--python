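"""LMG relative importance for consumer liking models.

The LMG statistic attributes the R² of a linear regression to its
predictors by averaging, over all orderings in which predictors can
enter the model, the increase in R² each predictor contributes when it
enters after its predecessors.  It is exactly the Shapley value of the
cooperative game whose characteristic function maps a predictor subset
to the R² of the regression on that subset, which makes it robust to
multicollinearity among sensory attributes.

Predictors are handled in *groups*: a continuous attribute is a
one-column group, while a 3-level just-about-right (JAR) factor
(−1 = too weak, 0 = just about right, +1 = too strong) is expanded into
indicator columns that enter and leave the model together, so each JAR
attribute receives a single share.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .exceptions import ValidationError

__all__ = [
    "PredictorGroupDesign",
    "LMGResult",
    "LMGImportance",
    "expand_jar_design",
    "r2_of_subset",
    "lmg_shares",
]

JAR_LEVELS = (-1, 0, 1)
JAR_LEVEL_NAMES = {-1: "too_weak", 0: "just_right", 1: "too_strong"}


@dataclass
class PredictorGroupDesign:
    """Response plus named groups of design columns.

    ``groups`` maps group name -> 2-D array (n_obs × k_group).  Group
    order is meaningful only for presentation; LMG shares are invariant
    to it.
    """

    response: np.ndarray
    groups: dict
    n_obs: int = 0

    def __post_init__(self):
        self.response = np.asarray(self.response, dtype=float).ravel()
        self.n_obs = self.response.shape[0]
        clean = {}
        for name, cols in self.groups.items():
            cols = np.atleast_2d(np.asarray(cols, dtype=float))
            if cols.shape[0] != self.n_obs:
                if cols.shape[1] == self.n_obs:  # accept transposed 1-D input
                    cols = cols.T
                else:
                    raise ValidationError(
                        f"group {name!r} has {cols.shape[0]} rows, expected {self.n_obs}"
                    )
            clean[str(name)] = cols
        self.groups = clean

    @property
    def group_names(self):
        return list(self.groups)

    @property
    def n_columns(self) -> int:
        return sum(g.shape[1] for g in self.groups.values())

    def matrix(self, subset=None) -> np.ndarray:
        """Column-stack of the given groups (all groups when None)."""
        names = self.group_names if subset is None else list(subset)
        if not names:
            return np.empty((self.n_obs, 0))
        return np.hstack([self.groups[n] for n in names])


@dataclass
class LMGResult:
    shares: dict
    total_r2: float
    normalized: bool
    n_orderings_used: int
    exact: bool
    group_names: list = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.shares, name="lmg_share")


def expand_jar_design(raw, response=None, attribute_names=None) -> PredictorGroupDesign:
    """Expand a consumers × attributes JAR table into grouped indicators.

    Every attribute becomes one predictor group of indicator columns
    for its observed non-reference levels, with "just about right" (0)
    as the reference level.  An attribute with a single observed level
    carries no variance and is dropped with a warning.
    """
    if isinstance(raw, pd.DataFrame):
        names = list(raw.columns)
        values = raw.to_numpy()
    else:
        values = np.asarray(raw)
        names = (list(attribute_names) if attribute_names is not None
                 else [f"attr{j}" for j in range(values.shape[1])])
    values = np.atleast_2d(values)
    legal = set(JAR_LEVELS)
    observed = set(np.unique(values).tolist())
    if not observed <= legal:
        raise ValidationError(
            f"JAR values must be in {{-1, 0, +1}}; found {sorted(observed - legal)}"
        )
    groups = {}
    for j, name in enumerate(names):
        col = values[:, j].astype(int)
        levels = sorted(set(col.tolist()))
        non_ref = [lv for lv in levels if lv != 0]
        if len(levels) < 2:
            warnings.warn(
                f"JAR attribute {name!r} has a single observed level "
                f"({JAR_LEVEL_NAMES[levels[0]]}); dropped from the design"
            )
            continue
        cols = np.column_stack([(col == lv).astype(float) for lv in non_ref])
        groups[name] = cols
    y = np.zeros(values.shape[0]) if response is None else response
    return PredictorGroupDesign(response=y, groups=groups)


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of the least-squares fit of y on [1, X]; pseudoinverse path."""
    n = y.shape[0]
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    if X.shape[1] == 0:
        return 0.0
    Z = np.column_stack([np.ones(n), X])
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ beta
    return float(1.0 - (resid @ resid) / sst)


def r2_of_subset(design: PredictorGroupDesign, subset) -> float:
    """Coefficient of determination for a subset of predictor groups.

    Empty subset → 0.  Rank-deficient designs are handled by the
    minimum-norm least-squares solution (R² remains well defined).
    """
    subset = list(subset)
    unknown = set(subset) - set(design.group_names)
    if unknown:
        raise ValidationError(f"unknown groups: {sorted(unknown)}")
    return _r2(design.response, design.matrix(subset))


class LMGImportance(BaseEstimator):
    """Shapley/LMG decomposition of regression R² over predictor groups.

    Exact enumeration over group subsets when the number of groups is
    at most ``max_exact_groups``; otherwise a seeded Monte-Carlo average
    over ``n_sample_orderings`` random orderings.

    Parameters
    ----------
    groups : dict mapping name -> list of column indices, optional
        When None, every column of X is its own group.
    normalized : bool, default True
        Divide shares by the full-model R² so they sum to one.
    max_exact_groups : int, default 8
    n_sample_orderings : int, default 10000
    random_state : int, default 0

    Attributes
    ----------
    shares_ : dict  (group name -> share)
    total_r2_ : float
    exact_ : bool
    n_orderings_used_ : int
    """

    def __init__(self, groups=None, normalized: bool = True,
                 max_exact_groups: int = 8, n_sample_orderings: int = 10000,
                 random_state: int = 0):
        self.groups = groups
        self.normalized = normalized
        self.max_exact_groups = max_exact_groups
        self.n_sample_orderings = n_sample_orderings
        self.random_state = random_state

    def _design_from_xy(self, X, y) -> PredictorGroupDesign:
        if isinstance(X, PredictorGroupDesign):
            return X
        if isinstance(X, pd.DataFrame):
            if self.groups is None:
                cols = {str(c): X[[c]].to_numpy(dtype=float) for c in X.columns}
            else:  # groups map name -> list of column labels
                cols = {name: X[list(labels)].to_numpy(dtype=float)
                        for name, labels in self.groups.items()}
        else:
            X = np.atleast_2d(np.asarray(X, dtype=float))
            if self.groups is None:
                cols = {f"x{j}": X[:, j:j + 1] for j in range(X.shape[1])}
            else:  # groups map name -> list of column indices
                cols = {name: X[:, list(idx)] for name, idx in self.groups.items()}
        return PredictorGroupDesign(response=y, groups=cols)

    def fit(self, X, y=None):
        design = self._design_from_xy(X, y)
        names = design.group_names
        g = len(names)
        if g < 1:
            raise ValidationError("need at least one predictor group")
        if design.n_obs < 3:
            raise ValidationError("need at least 3 observations")
        if design.n_obs <= design.n_columns:
            warnings.warn(
                f"{design.n_obs} observations for {design.n_columns} design "
                "columns: rank-deficient fits use the pseudoinverse"
            )
        # R² of every group subset, keyed by frozenset
        r2 = {frozenset(): 0.0}
        exact = g <= self.max_exact_groups
        if exact:
            for r in range(1, g + 1):
                for comb in itertools.combinations(names, r):
                    r2[frozenset(comb)] = r2_of_subset(design, comb)
            shares = {}
            fact = [math.factorial(i) for i in range(g + 1)]
            for name in names:
                others = [n for n in names if n != name]
                acc = 0.0
                for r in range(0, g):
                    for comb in itertools.combinations(others, r):
                        s = frozenset(comb)
                        w = fact[r] * fact[g - r - 1] / fact[g]
                        acc += w * (r2[s | {name}] - r2[s])
                shares[name] = acc
            n_orderings = math.factorial(g)
        else:
            rng = np.random.default_rng(self.random_state)
            sums = dict.fromkeys(names, 0.0)
            cache = {frozenset(): 0.0}
            for _ in range(int(self.n_sample_orderings)):
                perm = [names[i] for i in rng.permutation(g)]
                prefix = []
                prev = 0.0
                for name in perm:
                    prefix.append(name)
                    key = frozenset(prefix)
                    if key not in cache:
                        cache[key] = r2_of_subset(design, prefix)
                    sums[name] += cache[key] - prev
                    prev = cache[key]
            shares = {n: s / self.n_sample_orderings for n, s in sums.items()}
            n_orderings = int(self.n_sample_orderings)

        total = r2_of_subset(design, names)
        if self.normalized:
            if total <= 0.0:
                raise ValidationError(
                    "total R² is zero: normalized shares are undefined"
                )
            shares = {n: s / total for n, s in shares.items()}
        self.shares_ = shares
        self.total_r2_ = total
        self.exact_ = exact
        self.n_orderings_used_ = n_orderings
        self.group_names_ = names
        return self

    def result_(self) -> LMGResult:
        return LMGResult(shares=self.shares_, total_r2=self.total_r2_,
                         normalized=self.normalized,
                         n_orderings_used=self.n_orderings_used_,
                         exact=self.exact_, group_names=self.group_names_)


def lmg_shares(design: PredictorGroupDesign, normalized: bool = True,
               max_exact_groups: int = 8, n_sample_orderings: int = 10000,
               seed: int = 0) -> LMGResult:
    """LMG shares of a grouped design (thin wrapper over LMGImportance)."""
    est = LMGImportance(normalized=normalized,
                        max_exact_groups=max_exact_groups,
                        n_sample_orderings=n_sample_orderings,
                        random_state=seed)
    est.fit(design)
    return est.result_()
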
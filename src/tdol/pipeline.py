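"""Temporal-drivers-of-liking orchestration.

The full analysis chain: smooth raw multi-attribute time-intensity
(MATI) series into functional curves, evaluate them on a common time
grid, fit a relative-importance model at every grid time (Choquet
capacity → Shapley values and pairwise interaction indices, or LMG
variance decomposition for consumer/just-about-right data), smooth the
resulting importance trajectories into curves, and differentiate those
curves to describe when the importance of each attribute peaks, dips or
stays stable.

Default grids follow the conventions of panel line-scale MATI work:
3–90 s in steps of 3 for panel attributes, 1–25 s for first-bite
check-all-that-apply proportions, and 14–90 s in steps of 4 for
just-about-right consumer data; all are overridable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import capacity as cap
from .exceptions import ValidationError
from .funcdata import BSplineSmoother, FunctionalCurve
from .relimp import expand_jar_design, lmg_shares

__all__ = [
    "ImportanceTrajectory",
    "InteractionTrajectory",
    "DynamicsReport",
    "GRID_PANEL",
    "GRID_CATA",
    "GRID_JAR",
    "pointwise_importance_choquet",
    "pointwise_importance_lmg",
    "importance_curves",
    "derivative_report",
    "dominant_driver",
]

GRID_PANEL = np.arange(3.0, 91.0, 3.0)   # 30 points
GRID_CATA = np.arange(1.0, 26.0, 1.0)    # 25 points
GRID_JAR = np.arange(14.0, 91.0, 4.0)    # 20 points


# ---------------------------------------------------------------------------
# trajectory containers

@dataclass
class ImportanceTrajectory:
    """Time grid × attribute matrix of relative-importance values."""

    times: np.ndarray
    attributes: list
    values: np.ndarray
    method: str = ""
    diagnostics: list = field(default_factory=list)
    validate: bool = True

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.attributes = [str(a) for a in self.attributes]
        if self.values.shape != (self.times.size, len(self.attributes)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{self.times.size} times × {len(self.attributes)} attributes"
            )
        if self.validate:
            finite = np.isfinite(self.values).all(axis=1)
            vals = self.values[finite]
            if vals.size:
                if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
                    raise ValidationError("importance values must lie in [0,1]")
                sums = vals.sum(axis=1)
                if np.any(np.abs(sums - 1.0) > 1e-6):
                    worst = float(np.abs(sums - 1.0).max())
                    raise ValidationError(
                        f"importance rows must sum to 1 (worst deviation {worst:.2e})"
                    )

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.attributes)
        df.insert(0, "second", self.times)
        return df


@dataclass
class InteractionTrajectory:
    """Time grid × attribute-pair matrix of pairwise interaction indices."""

    times: np.ndarray
    pairs: list
    values: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.pairs = [tuple(p) for p in self.pairs]
        if self.values.shape != (self.times.size, len(self.pairs)):
            raise ValidationError("values shape does not match times × pairs")
        if np.any(self.values < -1 - 1e-9) or np.any(self.values > 1 + 1e-9):
            raise ValidationError("interaction indices must lie in [-1, 1]")

    def as_frame(self) -> pd.DataFrame:
        cols = [f"{a}v{b}" for a, b in self.pairs]
        df = pd.DataFrame(self.values, columns=cols)
        df.insert(0, "second", self.times)
        return df


@dataclass
class DynamicsReport:
    """Per-curve dynamics: extrema of importance and stability windows.

    ``crossings`` maps label -> list of (time, kind) with kind in
    {"maximum", "minimum", "inflection"}; ``stable_intervals`` maps
    label -> list of (t_start, t_end) where both |f'| and |f''| stay
    below their thresholds.
    """

    crossings: dict
    stable_intervals: dict
    eps1: dict
    eps2: dict

    def as_dict(self) -> dict:
        return {
            "crossings": {k: [[float(t), kind] for t, kind in v]
                          for k, v in self.crossings.items()},
            "stable_intervals": {k: [[float(a), float(b)] for a, b in v]
                                 for k, v in self.stable_intervals.items()},
            "eps1": {k: float(v) for k, v in self.eps1.items()},
            "eps2": {k: float(v) for k, v in self.eps2.items()},
        }


# ---------------------------------------------------------------------------
# smoothing helpers

def _smooth_dataset_curves(dataset, lam=None, n_basis=None) -> dict:
    """One smoothed curve per (product, attribute) of the observer-mean."""
    curves = {}
    for product in dataset.products:
        for attribute in dataset.attributes:
            t, v = dataset.series(product, attribute)
            sm = BSplineSmoother(n_basis=n_basis, lam=lam,
                                 label=f"{product}:{attribute}")
            sm.fit(t, v)
            curves[(product, attribute)] = sm.curve_
    return curves


# ---------------------------------------------------------------------------
# pointwise fitting

def pointwise_importance_choquet(panel, liking, times=None, k_additive: int = 2,
                                 ridge: float = 1e-6, lam=None, n_basis=None):
    """Pointwise Choquet-capacity importance along a time grid.

    At each grid time the per-product smoothed attribute curves and
    liking curves are evaluated, min–max scaled across products, and a
    k-additive capacity is identified by constrained least squares;
    the Shapley row and interaction row are recorded.

    Parameters
    ----------
    panel : MATIDataset
        Panel attribute intensities (several products, >= 2 attributes).
        Averaged across observers before smoothing.
    liking : MATIDataset
        Overall-liking series for the same products (consumer means or
        raw; averaged across observers before smoothing).
    times : grid, default GRID_PANEL (3–90 s step 3)

    Returns
    -------
    (ImportanceTrajectory, InteractionTrajectory)
    """
    times = GRID_PANEL if times is None else np.asarray(times, dtype=float)
    products = panel.products
    attributes = panel.attributes
    if len(products) < 2 or len(attributes) < 2:
        raise ValidationError("need >= 2 products and >= 2 attributes")
    missing = [p for p in products if p not in liking.products]
    if missing:
        raise ValidationError(f"liking data missing for product(s) {missing}")
    for p in products:
        have = set(panel.data.loc[panel.data["product"] == p, "attribute"])
        lost = [a for a in attributes if a not in have]
        if lost:
            raise ValidationError(
                f"product {p!r} has no series for attribute(s) {lost}")

    attr_curves = _smooth_dataset_curves(panel, lam=lam, n_basis=n_basis)
    liking_attr = liking.attributes
    lik_curves = {}
    for p in products:
        t, v = liking.series(p, liking_attr[0])
        sm = BSplineSmoother(n_basis=n_basis, lam=lam, label=f"{p}:liking")
        sm.fit(t, v)
        lik_curves[p] = sm.curve_

    n_attr = len(attributes)
    pairs = list(itertools.combinations(attributes, 2))
    shap_rows = np.empty((times.size, n_attr))
    int_rows = np.empty((times.size, len(pairs)))
    diags = []
    pair_idx = list(itertools.combinations(range(n_attr), 2))
    for r, t in enumerate(times):
        X = np.array([[attr_curves[(p, a)]([t])[0] for a in attributes]
                      for p in products])
        y = np.array([lik_curves[p]([t])[0] for p in products])
        Xs, recs = cap.scale_minmax(X)
        ys2, yrec = cap.scale_minmax(y[:, None])
        fit = cap.fit_capacity_ls(Xs, ys2[:, 0], k_additive=k_additive,
                                  ridge=ridge, attributes=attributes)
        fit.scaling = recs + yrec
        shap_rows[r] = fit.shapley
        int_rows[r] = [fit.interactions[i, j] for i, j in pair_idx]
        diags.append(fit)

    traj = ImportanceTrajectory(times=times, attributes=attributes,
                                values=shap_rows, method="shapley",
                                diagnostics=diags)
    inter = InteractionTrajectory(times=times, pairs=pairs, values=int_rows)
    return traj, inter


def pointwise_importance_lmg(consumer, liking, times=None, jar: bool = True,
                             normalized: bool = True, seed: int = 0):
    """Pointwise LMG importance of consumer attributes along a time grid.

    Parameters
    ----------
    consumer : MATIDataset
        Per-consumer attribute responses over time (``observer`` is the
        consumer id).  With ``jar=True`` values must be in {-1, 0, +1}
        and each attribute is expanded to a grouped 3-level factor with
        "just about right" as reference.
    liking : MATIDataset
        Per-consumer overall-liking ratings on the same times/consumers.
    times : grid, default GRID_JAR (14–90 s step 4)

    Returns
    -------
    ImportanceTrajectory with one (normalized) LMG row per grid time;
    a time point with zero liking variance yields a row of NaN and a
    warning rather than a failure.
    """
    times = GRID_JAR if times is None else np.asarray(times, dtype=float)
    attributes = consumer.attributes
    lik_attr = liking.attributes[0]
    rows = np.full((times.size, len(attributes)), np.nan)
    diags = []
    for r, t in enumerate(times):
        sub = consumer.data[consumer.data["time_s"] == t]
        lik = liking.data[(liking.data["time_s"] == t)
                          & (liking.data["attribute"] == lik_attr)]
        if sub.empty or lik.empty:
            raise ValidationError(f"no consumer records at time {t}")
        wide = sub.pivot(index="observer", columns="attribute", values="value")
        wide = wide.loc[:, attributes]
        y = lik.set_index("observer")["value"]
        common = wide.index.intersection(y.index)
        wide, y = wide.loc[common], y.loc[common].to_numpy(dtype=float)
        if wide.isna().any().any():
            raise ValidationError(f"incomplete consumer table at time {t}")
        if np.var(y) == 0.0:
            warnings.warn(f"zero liking variance at time {t}; row set to NaN")
            diags.append(None)
            continue
        if jar:
            design = expand_jar_design(wide.astype(int), response=y)
        else:
            from .relimp import PredictorGroupDesign
            design = PredictorGroupDesign(
                response=y,
                groups={a: wide[a].to_numpy(dtype=float)[:, None]
                        for a in attributes})
        res = lmg_shares(design, normalized=normalized, seed=seed)
        for j, a in enumerate(attributes):
            if a in res.shares:
                rows[r, j] = res.shares[a]
        diags.append(res)
    # LMG shares can be minutely negative only through round-off; rows of
    # NaN mark degenerate time points
    traj = ImportanceTrajectory(times=times, attributes=attributes,
                                values=rows, method="lmg", diagnostics=diags,
                                validate=normalized)
    return traj


# ---------------------------------------------------------------------------
# curves and dynamics

def importance_curves(trajectory, lam=None, n_basis=None) -> dict:
    """Smooth each trajectory column into a FunctionalCurve.

    Works for both importance (attribute columns) and interaction
    (pair columns) trajectories; requires >= 4 time points.
    """
    times = trajectory.times
    if times.size < 4:
        raise ValidationError("need at least 4 time points to smooth")
    if hasattr(trajectory, "attributes"):
        labels = list(trajectory.attributes)
    else:
        labels = [f"{a}v{b}" for a, b in trajectory.pairs]
    curves = {}
    for j, label in enumerate(labels):
        col = trajectory.values[:, j]
        ok = np.isfinite(col)
        if ok.sum() < 4:
            raise ValidationError(f"fewer than 4 finite values for {label!r}")
        sm = BSplineSmoother(n_basis=n_basis, lam=lam, label=label)
        sm.fit(times[ok], col[ok])
        curves[label] = sm.curve_
    return curves


def _refine_crossing(curve: FunctionalCurve, lo: float, hi: float) -> float:
    """Bisection on the first derivative between two grid times."""
    f = lambda t: float(curve([t], deriv=1)[0])
    a, b = lo, hi
    fa = f(a)
    for _ in range(80):
        m = 0.5 * (a + b)
        fm = f(m)
        if fa * fm <= 0:
            b = m
        else:
            a, fa = m, fm
        if b - a < 1e-10 * max(1.0, abs(hi)):
            break
    return 0.5 * (a + b)


def derivative_report(curves: dict, eval_grid=None, eps1=None, eps2=None) -> DynamicsReport:
    """Locate extrema and stability windows of importance curves.

    Zero crossings of the first derivative are found by sign change on
    ``eval_grid`` and refined by bisection; each is classified as a
    maximum (f'' < 0), minimum (f'' > 0) or inflection (f'' ~ 0).
    Stable intervals are maximal grid runs with |f'| < eps1 and
    |f''| < eps2; the thresholds default per curve to 10% of the
    maximum absolute first and second derivative.
    """
    crossings, stables, e1map, e2map = {}, {}, {}, {}
    for label, curve in curves.items():
        lo, hi = curve.domain
        grid = (np.linspace(lo, hi, 201) if eval_grid is None
                else np.asarray(eval_grid, dtype=float))
        d1 = curve(grid, deriv=1)
        d2 = curve(grid, deriv=2)
        value_scale = max(1.0, float(np.abs(curve(grid)).max()))
        if np.abs(d1).max() <= 1e-9 * value_scale:
            # numerically constant curve: no extrema, stable throughout
            crossings[label] = []
            stables[label] = [(float(grid[0]), float(grid[-1]))]
            e1map[label] = e2map[label] = 0.0
            continue
        e1 = eps1 if eps1 is not None else 0.1 * np.abs(d1).max()
        e2 = eps2 if eps2 is not None else 0.1 * np.abs(d2).max()
        e1map[label], e2map[label] = float(e1), float(e2)

        found = []
        for i in range(grid.size - 1):
            a, b = d1[i], d1[i + 1]
            if a == 0.0 and i > 0:
                t0 = float(grid[i])
            elif a * b < 0:
                t0 = _refine_crossing(curve, float(grid[i]), float(grid[i + 1]))
            else:
                continue
            c2 = float(curve([t0], deriv=2)[0])
            scale2 = np.abs(d2).max()
            if c2 < -1e-10 * max(scale2, 1e-12):
                kind = "maximum"
            elif c2 > 1e-10 * max(scale2, 1e-12):
                kind = "minimum"
            else:
                kind = "inflection"
            found.append((t0, kind))
        crossings[label] = found

        mask = (np.abs(d1) < e1) & (np.abs(d2) < e2)
        intervals = []
        start = None
        for i, ok in enumerate(mask):
            if ok and start is None:
                start = grid[i]
            elif not ok and start is not None:
                intervals.append((float(start), float(grid[i - 1])))
                start = None
        if start is not None:
            intervals.append((float(start), float(grid[-1])))
        stables[label] = intervals
    return DynamicsReport(crossings=crossings, stable_intervals=stables,
                          eps1=e1map, eps2=e2map)


def dominant_driver(trajectory: ImportanceTrajectory) -> pd.DataFrame:
    """Per-time winning attribute (argmax importance) with tie flags.

    Exact ties are broken toward the lexicographically first label and
    flagged.
    """
    if trajectory.times.size == 0:
        raise ValidationError("empty trajectory")
    order = np.argsort(trajectory.attributes)  # lexicographic preference
    labels_sorted = [trajectory.attributes[i] for i in order]
    rows = []
    for r, t in enumerate(trajectory.times):
        vals = trajectory.values[r]
        if not np.all(np.isfinite(vals)):
            rows.append((t, "", False))
            continue
        best = max(vals)
        winners = [lab for lab, v in zip(labels_sorted, vals[order]) if v == best]
        rows.append((t, winners[0], len(winners) > 1))
    return pd.DataFrame(rows, columns=["second", "driver", "tie"])
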
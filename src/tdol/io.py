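"""Readers, writers and validation for MATI tables and trajectories.

The canonical on-disk format is long-format CSV (UTF-8, comma
separator, ``.`` decimal, mandatory header) with columns

    observer,product,attribute,time_s,value

``observer`` may be empty for product-level series such as panel means.
Every dataset declares a measurement scale, and reads are validating:
out-of-range values, duplicate keys and missing columns are errors with
row numbers, never silent coercions.

Relative-importance trajectories are written one row per time point
("second" column plus one column per attribute or attribute pair),
the layout in which such results are conventionally tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "ScaleSpec",
    "MATIDataset",
    "SCALES",
    "read_mati_csv",
    "write_mati_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "load_reference_tables",
]

REQUIRED_COLUMNS = ("observer", "product", "attribute", "time_s", "value")


@dataclass(frozen=True)
class ScaleSpec:
    """Declared measurement scale of a dataset's values."""

    name: str
    lo: float
    hi: float
    levels: tuple = ()  # non-empty => discrete scale, exact membership

    def check(self, values: np.ndarray) -> np.ndarray:
        """Boolean mask of out-of-scale values."""
        v = np.asarray(values, dtype=float)
        if self.levels:
            return ~np.isin(v, np.asarray(self.levels, dtype=float))
        return (v < self.lo) | (v > self.hi) | ~np.isfinite(v)


SCALES = {
    "line150": ScaleSpec("line150", 0.0, 150.0),
    "proportion": ScaleSpec("proportion", 0.0, 1.0),
    "jar": ScaleSpec("jar", -1.0, 1.0, levels=(-1.0, 0.0, 1.0)),
    "liking100": ScaleSpec("liking100", 0.0, 100.0),
    "hedonic9": ScaleSpec("hedonic9", 1.0, 9.0),
    "unit": ScaleSpec("unit", 0.0, 1.0),
}


def _resolve_scale(scale) -> ScaleSpec:
    if isinstance(scale, ScaleSpec):
        return scale
    try:
        return SCALES[scale]
    except KeyError:
        raise ValidationError(
            f"unknown scale {scale!r}; known: {sorted(SCALES)}") from None


@dataclass
class MATIDataset:
    """Long-format time-intensity records with a declared scale.

    ``data`` columns: observer (str, may be ""), product (str),
    attribute (str), time_s (float, >= 0), value (float).
    """

    data: pd.DataFrame
    scale: ScaleSpec

    def __post_init__(self):
        self.scale = _resolve_scale(self.scale)
        df = self.data.copy()
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"missing required column(s): {missing}")
        df = df.loc[:, list(REQUIRED_COLUMNS)]
        df["observer"] = df["observer"].fillna("").astype(str)
        df["product"] = df["product"].astype(str)
        df["attribute"] = df["attribute"].astype(str)
        df["time_s"] = pd.to_numeric(df["time_s"], errors="raise")
        df["value"] = pd.to_numeric(df["value"], errors="raise")
        if (df["time_s"] < 0).any():
            rows = df.index[df["time_s"] < 0].tolist()[:5]
            raise ValidationError(f"negative time_s at rows {rows}")
        bad = self.scale.check(df["value"].to_numpy())
        if bad.any():
            rows = df.index[bad].tolist()
            raise ValidationError(
                f"{bad.sum()} value(s) outside scale {self.scale.name!r} "
                f"at rows {rows[:5]}"
            )
        dup = df.duplicated(subset=["observer", "product", "attribute", "time_s"])
        if dup.any():
            rows = df.index[dup].tolist()
            raise ValidationError(
                f"duplicate (observer, product, attribute, time_s) keys at "
                f"rows {rows[:5]}"
            )
        self.data = df.reset_index(drop=True)

    # -- convenience views -------------------------------------------------
    @property
    def products(self):
        return sorted(self.data["product"].unique())

    @property
    def attributes(self):
        return sorted(self.data["attribute"].unique())

    @property
    def times(self):
        return np.sort(self.data["time_s"].unique())

    def observer_mean(self) -> "MATIDataset":
        """Average across observers at each (product, attribute, time)."""
        g = (self.data.groupby(["product", "attribute", "time_s"], sort=True)
             ["value"].mean().reset_index())
        g.insert(0, "observer", "")
        return MATIDataset(g, self.scale)

    def series(self, product: str, attribute: str):
        """(times, values) of the observer-mean series for one cell."""
        sub = self.data[(self.data["product"] == product)
                        & (self.data["attribute"] == attribute)]
        if sub.empty:
            raise ValidationError(
                f"no records for product {product!r}, attribute {attribute!r}"
            )
        g = sub.groupby("time_s", sort=True)["value"].mean()
        return g.index.to_numpy(dtype=float), g.to_numpy(dtype=float)


def read_mati_csv(path, scale) -> MATIDataset:
    """Read and validate a long-format MATI CSV.

    Rows with an empty ``value`` field are dropped with a warning (raw
    recordings may have gaps); all other problems raise.
    """
    scale = _resolve_scale(scale)
    df = pd.read_csv(path, dtype={"observer": str, "product": str,
                                  "attribute": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s): {missing}")
    blank = df["value"].isna()
    if blank.any():
        warnings.warn(
            f"{path}: dropped {int(blank.sum())} row(s) with missing value "
            f"(rows {df.index[blank].tolist()[:5]})"
        )
        df = df[~blank]
    try:
        return MATIDataset(df, scale)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_mati_csv(dataset: MATIDataset, path) -> None:
    dataset.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# trajectory tables


def pair_label(a: str, b: str) -> str:
    return f"{a}v{b}"


def write_trajectory_csv(trajectory, path) -> None:
    """Write a trajectory as "second" + one column per attribute/pair.

    Values are emitted with 12 significant digits so read-back agrees
    to 1e-12.
    """
    labels = getattr(trajectory, "attributes", None)
    if labels is None:
        labels = [pair_label(a, b) for a, b in trajectory.pairs]
    df = pd.DataFrame(trajectory.values, columns=list(labels))
    df.insert(0, "second", trajectory.times)
    df.to_csv(path, index=False, float_format="%.12g")


def read_trajectory_csv(path, kind: str = "importance", method: str = ""):
    """Read a trajectory table written by :func:`write_trajectory_csv`.

    kind: "importance" (attribute columns) or "interaction"
    (pair columns labelled "AvB").
    """
    from .pipeline import ImportanceTrajectory, InteractionTrajectory

    df = pd.read_csv(path)
    if "second" not in df.columns:
        raise ValidationError(f"{path}: missing 'second' column")
    times = df["second"].to_numpy(dtype=float)
    values = df.drop(columns="second").to_numpy(dtype=float)
    labels = [str(c) for c in df.columns if c != "second"]
    if kind == "interaction":
        pairs = []
        for lab in labels:
            if "v" not in lab:
                raise ValidationError(f"{path}: {lab!r} is not an 'AvB' pair label")
            a, _, b = lab.partition("v")
            pairs.append((a, b))
        return InteractionTrajectory(times=times, pairs=pairs, values=values)
    return ImportanceTrajectory(times=times, attributes=labels, values=values,
                                method=method, validate=False)


# ---------------------------------------------------------------------------
# packaged reference tables

_REFERENCE_FILES = {
    "shapley_line": ("table_shapley_line.csv", "importance", "shapley"),
    "interactions_line": ("table_interactions_line.csv", "interaction", ""),
    "shapley_cata": ("table_shapley_cata.csv", "importance", "shapley"),
    "lmg_jar": ("table_lmg_jar.csv", "importance", "lmg"),
}


def load_reference_tables() -> dict:
    """Packaged relative-importance tables from a published fruit-chews
    MATI study, transcribed at printed (2-decimal) precision.

    Returned trajectories are consistency fixtures only: their rows
    reflect rounding, so importance rows sum to 1 only within a couple
    of percent, and they are never used as fitting targets (the raw
    panel and consumer data behind them were not published).

    Keys: ``shapley_line`` (4 texture attributes, 3–90 s step 3),
    ``interactions_line`` (their 6 pairs), ``shapley_cata`` (5
    check-all-that-apply items, 1–25 s), ``lmg_jar`` (3 just-about-right
    flavour attributes, 14–90 s step 4).
    """
    out = {}
    base = resources.files("tdol") / "data"
    for key, (fname, kind, method) in _REFERENCE_FILES.items():
        with resources.as_file(base / fname) as p:
            out[key] = read_trajectory_csv(p, kind=kind, method=method)
    return out
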
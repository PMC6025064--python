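"""Synthetic MATI panel and consumer data with known importance structure.

Every stage of the analysis chain is testable without external data:
this module generates multi-attribute time-intensity panel curves,
consumer liking driven by a known capacity (so Shapley recovery can be
checked against ground truth), just-about-right consumer tables with
known penalty structure, and check-all-that-apply proportion series.

Shapes emulate a small industrial fruit-chews study: 3 products rated
by 9 panelists on 4 texture attributes on a 0–150 line scale, with
time-intensity curves rising to a peak near 10 s and then decaying;
40 consumers; 3 just-about-right flavour attributes; 5 first-bite
check-all-that-apply items over 1–25 s.  The time-intensity shape is a
scaled gamma-density rise–decay  a · (t/p)^k · exp(k (1 − t/p)), which
peaks at exactly t = p with unit height.

All randomness flows through one seeded generator per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import capacity as cap
from .exceptions import ValidationError
from .io import MATIDataset, SCALES

__all__ = [
    "SimConfig",
    "gen_mati_curves",
    "gen_liking_from_capacity",
    "gen_jar_consumer_table",
    "gen_cata_proportions",
    "default_panel_capacity",
    "PANEL_ATTRIBUTES",
    "JAR_ATTRIBUTES",
    "CATA_ITEMS",
]

PANEL_ATTRIBUTES = ("Hardness", "Cohesiveness", "MoistnessOfMass",
                    "AwarenessOfParticles")
JAR_ATTRIBUTES = ("FruitFlavor", "Sweetness", "Sourness")
CATA_ITEMS = ("UniformBite", "Deformable", "Dense", "Springy", "Toothpull")

# liking penalty (0–100 scale points) for a non-just-right response, per
# JAR attribute; the dominant attribute gets ~3.5x the runner-up so that
# dominance is statistically identifiable from 40 consumers per time point
JAR_PENALTIES = {"FruitFlavor": 18.0, "Sweetness": 5.0, "Sourness": 3.0}
JAR_BASELINE = 70.0


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation settings.

    Defaults mirror the emulated study: 3 products, 4 panel attributes,
    9 panelists, 40 consumers, panel sampling every 3 s over 3–90 s,
    time-intensity peak near 10 s, rating noise 5 points on the 0–150
    line scale.
    """

    n_products: int = 3
    n_attributes: int = 4
    n_panelists: int = 9
    n_consumers: int = 40
    t_min: float = 3.0
    t_max: float = 90.0
    t_step: float = 3.0
    peak_time: float = 10.0
    shape_k: float = 2.5       # gamma-shape steepness (higher = narrower peak)
    noise_sd: float = 5.0      # rating units on the 0-150 line scale
    liking_noise_sd: float = 8.0  # 0-100 liking scale
    seed: int = 0
    anchor_products: bool = True  # include low/high reference products

    def __post_init__(self):
        if min(self.n_products, self.n_attributes, self.n_panelists,
               self.n_consumers) < 1:
            raise ValidationError("all counts must be positive")
        if self.noise_sd < 0 or self.liking_noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.t_max <= self.t_min or self.t_step <= 0:
            raise ValidationError("need t_max > t_min and t_step > 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.t_min, self.t_max + 1e-9, self.t_step)

    def attribute_names(self):
        if self.n_attributes == len(PANEL_ATTRIBUTES):
            return list(PANEL_ATTRIBUTES)
        return [f"Attr{i+1}" for i in range(self.n_attributes)]

    def product_names(self):
        return [f"P{chr(65+i)}" if i < 26 else f"P{i}" for i in range(self.n_products)]


def _ti_shape(t: np.ndarray, peak: float, k: float) -> np.ndarray:
    """Unit-height gamma rise-decay curve peaking at ``peak``."""
    r = np.maximum(t, 1e-9) / peak
    return r ** k * np.exp(k * (1.0 - r))


def gen_mati_curves(cfg: SimConfig) -> MATIDataset:
    """Panel time-intensity dataset on the 0–150 line scale.

    Each (product, attribute) has a gamma-shaped rise-decay base curve
    with product-specific amplitude; each panelist observes it with
    Gaussian noise truncated to [0, 150].  When ``anchor_products`` is
    set, the first and last products take the smallest and largest
    amplitude of every attribute, giving the min–max scaling of the
    pipeline fixed, invertible anchors.
    """
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times
    attrs = cfg.attribute_names()
    prods = cfg.product_names()
    rows = []
    for a_i, a in enumerate(attrs):
        peak = cfg.peak_time + rng.uniform(-1.0, 1.0)
        amps = rng.uniform(60.0, 140.0, size=cfg.n_products)
        if cfg.anchor_products and cfg.n_products >= 2:
            order = np.argsort(amps)
            lo, hi = amps[order[0]], amps[order[-1]]
            mid = np.sort(amps)[1:-1]
            amps = np.concatenate([[lo], rng.permutation(mid), [hi]])
        base = _ti_shape(t, peak, cfg.shape_k)
        for p_i, p in enumerate(prods):
            clean = amps[p_i] * base
            for panelist in range(cfg.n_panelists):
                noisy = clean + rng.normal(0.0, cfg.noise_sd, size=t.size) \
                    if cfg.noise_sd > 0 else clean.copy()
                noisy = np.clip(noisy, 0.0, 150.0)
                for ti, v in zip(t, noisy):
                    rows.append((f"panelist{panelist+1}", p, a, ti, v))
    df = pd.DataFrame(rows, columns=["observer", "product", "attribute",
                                     "time_s", "value"])
    return MATIDataset(df, SCALES["line150"])


def default_panel_capacity(attributes=PANEL_ATTRIBUTES) -> cap.MobiusCapacity:
    """A mildly non-uniform 2-additive ground-truth capacity.

    Shapley values (0.32, 0.28, 0.21, 0.19) with complementary and
    substitutive pairs — the size of departure from equal importance
    typical of texture attributes.
    """
    n = len(attributes)
    if n != 4:
        raise ValidationError("default capacity is defined for 4 attributes")
    m = np.zeros(1 << n)
    m[0b0001] = 0.26   # attr 1 alone
    m[0b0010] = 0.24
    m[0b0100] = 0.21
    m[0b1000] = 0.21
    m[0b0011] = 0.08   # attrs 1,2 complementary
    m[0b1100] = -0.04  # attrs 3,4 substitutive (redundant)
    m[0b0101] = 0.04
    return cap.MobiusCapacity(tuple(attributes), m, k_additive=2)


@dataclass
class LikingGroundTruth:
    """Liking dataset plus the generating capacity's importance values."""

    liking: MATIDataset
    capacity: cap.MobiusCapacity
    shapley: np.ndarray
    interactions: np.ndarray


def gen_liking_from_capacity(panel: MATIDataset, capacity: cap.MobiusCapacity,
                             noise_sd: float = 0.0, seed: int = 0) -> LikingGroundTruth:
    """Consumer-mean liking driven by a known capacity, on a 0–100 scale.

    At every sampled time the observer-mean attribute values are min–max
    scaled across products, aggregated with the Choquet integral of
    ``capacity``, mapped to 0–100 and perturbed with truncated Gaussian
    noise.  The generating Shapley values and interaction matrix are
    returned so recovery tests never re-derive them.
    """
    attrs = list(capacity.attributes)
    if sorted(attrs) != panel.attributes:
        raise ValidationError(
            f"capacity attributes {sorted(attrs)} do not match panel "
            f"attributes {panel.attributes}")
    rng = np.random.default_rng(seed)
    mean = panel.observer_mean()
    times = mean.times
    prods = mean.products
    v_cap = cap.from_mobius(capacity)
    wide = mean.data.pivot_table(index="time_s", columns=["product", "attribute"],
                                 values="value")
    rows = []
    for t in times:
        X = np.array([[wide.loc[t, (p, a)] for a in attrs] for p in prods])
        Xs, _ = cap.scale_minmax(X)
        for p_i, p in enumerate(prods):
            c = cap.choquet(v_cap, np.clip(Xs[p_i], 0.0, 1.0))
            lik = 100.0 * c
            if noise_sd > 0:
                lik = float(np.clip(lik + rng.normal(0.0, noise_sd), 0.0, 100.0))
            rows.append(("", p, "OverallLiking", t, lik))
    df = pd.DataFrame(rows, columns=["observer", "product", "attribute",
                                     "time_s", "value"])
    return LikingGroundTruth(
        liking=MATIDataset(df, SCALES["liking100"]),
        capacity=capacity,
        shapley=capacity.shapley(),
        interactions=capacity.interaction_matrix(),
    )


@dataclass
class JarGroundTruth:
    """Consumer JAR tables, liking and the generating penalty structure."""

    jar: MATIDataset
    liking: MATIDataset
    penalties: dict
    dominant: pd.DataFrame  # per-time ground-truth dominant attribute


def jar_level_probabilities(t: np.ndarray, attribute: str) -> np.ndarray:
    """Per-time probabilities of (-1, 0, +1) for one JAR attribute.

    "Too strong" stays rare; "too weak" and "just right" mirror each
    other and cross over mid-consumption, the pattern typical of
    flavour fade during chew-down.
    """
    cross = {"FruitFlavor": 35.0, "Sweetness": 25.0, "Sourness": 50.0}.get(
        attribute, 40.0)
    p_weak = 0.15 + 0.55 / (1.0 + np.exp(-(t - cross) / 12.0))
    p_strong = np.full_like(p_weak, 0.05)
    p_jr = 1.0 - p_weak - p_strong
    return np.column_stack([p_weak, p_jr, p_strong])


def gen_jar_consumer_table(cfg: SimConfig, times=None,
                           penalties=None) -> JarGroundTruth:
    """Per-time consumer just-about-right responses and liking.

    Levels are drawn independently per consumer/time from
    :func:`jar_level_probabilities`; liking is a 0–100 baseline minus a
    fixed penalty for every non-just-right response plus truncated
    Gaussian noise.  The attribute with the largest penalty is the
    ground-truth dominant driver at every time.
    """
    rng = np.random.default_rng(cfg.seed)
    times = (np.arange(14.0, 91.0, 4.0) if times is None
             else np.asarray(times, dtype=float))
    penalties = dict(JAR_PENALTIES if penalties is None else penalties)
    attrs = list(penalties)
    jar_rows, lik_rows = [], []
    dominant = max(attrs, key=lambda a: penalties[a])
    for t in times:
        for c_i in range(cfg.n_consumers):
            consumer = f"consumer{c_i+1}"
            lik = JAR_BASELINE
            for a in attrs:
                probs = jar_level_probabilities(np.array([t]), a)[0]
                level = int(rng.choice((-1, 0, 1), p=probs))
                jar_rows.append((consumer, "PB", a, t, level))
                if level != 0:
                    lik -= penalties[a]
            if cfg.liking_noise_sd > 0:
                lik += rng.normal(0.0, cfg.liking_noise_sd)
            lik_rows.append((consumer, "PB", "OverallLiking", t,
                             float(np.clip(lik, 0.0, 100.0))))
    jar_df = pd.DataFrame(jar_rows, columns=["observer", "product",
                                             "attribute", "time_s", "value"])
    lik_df = pd.DataFrame(lik_rows, columns=["observer", "product",
                                             "attribute", "time_s", "value"])
    dom = pd.DataFrame({"second": times, "driver": dominant})
    return JarGroundTruth(
        jar=MATIDataset(jar_df, SCALES["jar"]),
        liking=MATIDataset(lik_df, SCALES["liking100"]),
        penalties=penalties,
        dominant=dom,
    )


def gen_cata_proportions(cfg: SimConfig, times=None) -> MATIDataset:
    """Per-time check-all-that-apply item proportions (first bite, 1–25 s).

    Each (product, item) proportion follows a smooth logistic
    rise-and-fall trajectory with randomised onset, offset and plateau,
    kept strictly within [0, 1].
    """
    rng = np.random.default_rng(cfg.seed)
    times = (np.arange(1.0, 26.0, 1.0) if times is None
             else np.asarray(times, dtype=float))
    rows = []
    for p in cfg.product_names():
        for item in CATA_ITEMS:
            plateau = rng.uniform(0.3, 0.95)
            onset = rng.uniform(1.0, 8.0)
            offset = rng.uniform(12.0, 30.0)
            rise = rng.uniform(1.0, 3.0)
            fall = rng.uniform(2.0, 6.0)
            prop = plateau / (1.0 + np.exp(-(times - onset) / rise)) \
                / (1.0 + np.exp((times - offset) / fall))
            prop = np.clip(prop, 0.0, 1.0)
            for t, v in zip(times, prop):
                rows.append(("", p, item, float(t), float(v)))
    df = pd.DataFrame(rows, columns=["observer", "product", "attribute",
                                     "time_s", "value"])
    return MATIDataset(df, SCALES["proportion"])
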
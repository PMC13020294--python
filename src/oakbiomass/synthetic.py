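"""Synthetic Q. mongolica populations emulating the calibration study design.

The published 175-tree dataset was never deposited, so this module
generates populations with the same structure: 160 trees spread over
the diameter classes 2-32 cm (16 per class) plus 15 random extras,
heights from a saturating height-diameter curve bounded by the study's
20.5 m applicability limit, 17 climate indicators drawn uniformly from
Northeast-China-plausible ranges, component biomasses from the published
allometric mean structure with multiplicative heteroscedastic noise
(lognormal, mean 1, variance proportional to mean^variance_power), root
biomass from the published root:shoot ratio form, and a root-excavated
subsample allocated across diameter classes as in the study (53 of 175
by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from . import reference
from .allocation import DIAMETER_CLASS_CENTERS, _nearest_class
from .allometric import CARModel
from .data import CLIMATE_KEYS, TreeRecord
from .systems import ClimateCARModel


class ConfigError(ValueError):
    """Invalid generator configuration."""


#: Uniform sampling ranges for the 17 indicators; plausible for the
#: study region (temperate monsoon Northeast China).  Units follow the
#: ClimateAP convention (deg C, mm, degree-days, days, %, unitless).
DEFAULT_CLIMATE_RANGES: dict[str, tuple[float, float]] = {
    "MAT": (-2.0, 8.0), "MWMT": (18.0, 24.0), "MCMT": (-28.0, -8.0),
    "TD": (32.0, 48.0), "MAP": (400.0, 900.0), "AHM": (30.0, 90.0),
    "DD_lt0": (900.0, 3200.0), "DD_gt5": (1500.0, 2900.0),
    "DD_lt18": (3500.0, 6000.0), "DD_gt18": (50.0, 400.0),
    "NFFD": (90.0, 170.0), "PAS": (40.0, 220.0), "EMT": (-45.0, -25.0),
    "EXT": (30.0, 40.0), "EREF": (500.0, 900.0), "CMD": (50.0, 350.0),
    "RH": (50.0, 75.0),
}


@dataclass(frozen=True)
class HeightCurve:
    """Saturating height-diameter relation H = 1.3 + a (1 - exp(-k D)),
    with multiplicative lognormal scatter, truncated at the study's
    height bound.  Defaults calibrated so the design mean is ~9.75 m."""
    asymptote: float = 27.0     # m above breast height
    rate: float = 0.027         # per cm of DBH
    cv: float = 0.20            # site-to-site scatter across the study area
    max_height: float = reference.MAX_HEIGHT_M
    min_height: float = 1.4

    def mean(self, dbh):
        return 1.3 + self.asymptote * (1.0 - np.exp(-self.rate * np.asarray(dbh)))


def _default_true_models() -> dict:
    return {c: CARModel(*reference.INDEPENDENT_BIOMASS[(c, "univariate")],
                        response=c)
            for c in ("stem", "branch", "leaf")}


@dataclass(frozen=True)
class GeneratorConfig:
    n_trees: int = reference.N_TREES
    root_subsample: int = reference.N_ROOT_SUBSAMPLE
    seed: int = 0
    dbh_range: tuple[float, float] = reference.DBH_RANGE_CM
    height_model: HeightCurve = field(default_factory=HeightCurve)
    noise_cv_per_component: Mapping[str, float] = field(
        default_factory=lambda: dict(reference.RESIDUAL_CV))
    variance_power: float = 2.0     # Var(noise) proportional to mean^power
    true_models: Mapping[str, CARModel | ClimateCARModel] = field(
        default_factory=_default_true_models)
    root_ratio: tuple[float, float] = reference.ROOT_SHOOT_BIOMASS["univariate"]
    climate_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLIMATE_RANGES))
    root_scheme: str = "stratified_by_diameter_class"
    age_coefficient: float = 3.5    # yr per cm, mean age ~ coeff * DBH
    age_cv: float = 0.25

    def __post_init__(self) -> None:
        if self.n_trees <= 0:
            raise ConfigError("n_trees must be positive")
        if not 0 <= self.root_subsample <= self.n_trees:
            raise ConfigError("root_subsample must lie in [0, n_trees]")
        lo, hi = self.dbh_range
        if not (0 < lo < hi):
            raise ConfigError("dbh_range must satisfy 0 < min < max")
        for comp, cv in self.noise_cv_per_component.items():
            if cv < 0:
                raise ConfigError(f"noise CV for {comp} must be >= 0")
        if self.root_scheme not in ("stratified_by_diameter_class", "random"):
            raise ConfigError(f"unknown root subsampling scheme {self.root_scheme!r}")
        missing = [k for k in CLIMATE_KEYS if k not in self.climate_ranges]
        if missing:
            raise ConfigError(f"climate_ranges missing {missing}")


def _sample_dbh(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Diameter-class design: equal class counts plus random extras,
    scaled from the study's 160 + 15 split when n_trees differs."""
    lo, hi = cfg.dbh_range
    centers = np.asarray(DIAMETER_CLASS_CENTERS, dtype=float)
    n_random = int(round(cfg.n_trees * 15 / 175))
    per_class, extra = divmod(cfg.n_trees - n_random, len(centers))
    n_random += extra
    # half-width: half the gap to the nearest neighbouring class
    gaps = np.diff(centers)
    half = np.minimum(np.append(gaps, gaps[-1]),
                      np.insert(gaps, 0, gaps[0])) / 2.0
    vals = []
    for c, h in zip(centers, half):
        vals.append(rng.uniform(c - h, c + h, size=per_class))
    vals.append(rng.uniform(lo, hi, size=n_random))
    dbh = np.clip(np.concatenate(vals), lo, hi)
    rng.shuffle(dbh)
    return dbh


def _lognormal_multiplier(rng, cv: np.ndarray | float, size: int) -> np.ndarray:
    """Positive multiplicative noise, E = 1, CV as given."""
    cv = np.broadcast_to(np.asarray(cv, dtype=float), (size,))
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.standard_normal(size) * sigma - sigma ** 2 / 2.0)


def _component_mean(model, dbh, height, climate_col):
    if isinstance(model, ClimateCARModel):
        return model.predict(dbh, height if model.form == "bivariate" else None,
                             climate_col)
    return model.predict(dbh, height if model.form == "bivariate" else None)


def generate_trees(config: GeneratorConfig | None = None) -> list[TreeRecord]:
    """Generate a synthetic tree population; deterministic per seed."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_trees
    dbh = _sample_dbh(cfg, rng)
    hm = cfg.height_model
    height = np.clip(hm.mean(dbh) * _lognormal_multiplier(rng, hm.cv, n),
                     hm.min_height, hm.max_height)
    age = np.clip(cfg.age_coefficient * dbh
                  * _lognormal_multiplier(rng, cfg.age_cv, n), 5.0, 130.0)
    climate = {k: rng.uniform(*cfg.climate_ranges[k], size=n)
               for k in CLIMATE_KEYS}

    mean_ref = {}
    comps = {}
    for label in ("stem", "branch", "leaf"):
        model = cfg.true_models[label]
        ckey = getattr(model, "climate_variable", None)
        mu = _component_mean(model, dbh, height,
                             climate[ckey] if ckey else None)
        mean_ref[label] = mu
        comps[label] = mu * _noise(rng, cfg, label, mu)
    agb_mean = mean_ref["stem"] + mean_ref["branch"] + mean_ref["leaf"]
    b0, b1 = cfg.root_ratio
    root_mean = b0 * dbh ** b1 * agb_mean
    root = root_mean * _noise(rng, cfg, "root", root_mean)

    records = []
    for i in range(n):
        records.append(TreeRecord(
            tree_id=f"T{i + 1:04d}", dbh=float(dbh[i]), height=float(height[i]),
            age=float(age[i]), stem=float(comps["stem"][i]),
            branch=float(comps["branch"][i]), leaf=float(comps["leaf"][i]),
            root=float(root[i]),
            climate={k: float(climate[k][i]) for k in CLIMATE_KEYS}))
    return subsample_root_set(records, cfg.root_subsample,
                              scheme=cfg.root_scheme,
                              seed=int(rng.integers(0, 2 ** 31 - 1)))


def _noise(rng, cfg: GeneratorConfig, label: str, mu: np.ndarray) -> np.ndarray:
    cv = cfg.noise_cv_per_component.get(label, 0.0)
    if cv == 0:
        return np.ones_like(mu)
    # variance proportional to mean^power: per-tree CV scaled around the
    # population-mean prediction (power 2 gives a constant CV).
    mu_ref = float(np.mean(mu))
    cv_tree = cv * (np.maximum(mu, 1e-12) / mu_ref) ** ((cfg.variance_power - 2) / 2)
    return _lognormal_multiplier(rng, cv_tree, mu.size)


def subsample_root_set(records: list[TreeRecord], k: int, *,
                       scheme: str = "stratified_by_diameter_class",
                       seed: int = 0) -> list[TreeRecord]:
    """Keep root biomass on exactly ``k`` records, drop it elsewhere.

    All input records must carry root biomass (full-knowledge synthetic
    population).  The stratified scheme allocates the k slots across the
    diameter classes near-proportionally (largest-remainder rounding),
    mirroring the study's class-wise excavation design.
    """
    n = len(records)
    if k > n:
        raise ValueError(f"cannot flag {k} of {n} records")
    if any(not r.has_root for r in records):
        raise ValueError("all records must have root biomass before subsampling")
    rng = np.random.default_rng(seed)
    if k == n:
        return list(records)
    if scheme == "random":
        keep = set(rng.choice(n, size=k, replace=False).tolist())
    elif scheme == "stratified_by_diameter_class":
        dbh = np.array([r.dbh for r in records])
        cls = _nearest_class(dbh, DIAMETER_CLASS_CENTERS)
        keep = set()
        occupied = [c for c in range(len(DIAMETER_CLASS_CENTERS))
                    if np.any(cls == c)]
        quota = {c: k * int(np.sum(cls == c)) / n for c in occupied}
        alloc = {c: int(np.floor(q)) for c, q in quota.items()}
        short = k - sum(alloc.values())
        # largest remainders get the leftover slots; every non-empty
        # class keeps at least one when k >= number of classes
        if k >= len(occupied):
            for c in occupied:
                if alloc[c] == 0:
                    alloc[c] = 1
            short = k - sum(alloc.values())
        order = sorted(occupied, key=lambda c: quota[c] - np.floor(quota[c]),
                       reverse=True)
        for c in order:
            if short == 0:
                break
            step = 1 if short > 0 else -1
            if step < 0 and alloc[c] <= 1:
                continue
            alloc[c] += step
            short -= step
        for c in occupied:
            members = np.flatnonzero(cls == c)
            take = min(alloc[c], members.size)
            keep.update(rng.choice(members, size=take, replace=False).tolist())
        # rounding safety: top up / trim at random
        pool = [i for i in range(n) if i not in keep]
        while len(keep) < k:
            keep.add(pool.pop(int(rng.integers(len(pool)))))
        while len(keep) > k:
            keep.remove(sorted(keep)[int(rng.integers(len(keep)))])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return [r if i in keep else r.without_root()
            for i, r in enumerate(records)]


def climate_screening_population(seed: int, n_trees: int = 175,
                                 modulation: float = 0.6,
                                 noise_cv: float = 0.3) -> list[TreeRecord]:
    """Population with a planted single-indicator climate dependence per
    component, for validating correlation-based climate screening.

    Each component's mean is its published univariate power law times
    ``1 + modulation * u``, where u is the assigned indicator (stem:
    DD_lt0, branch: PAS, leaf: TD) rescaled to [-1, 1]; all other
    indicators are pure noise.  DBH is uniform on 10-20 cm so the size
    signal does not drown the planted climate signal.
    """
    rng = np.random.default_rng(seed)
    dbh = rng.uniform(10.0, 20.0, size=n_trees)
    hm = HeightCurve()
    height = np.clip(hm.mean(dbh) * _lognormal_multiplier(rng, hm.cv, n_trees),
                     hm.min_height, hm.max_height)
    climate = {k: rng.uniform(*DEFAULT_CLIMATE_RANGES[k], size=n_trees)
               for k in CLIMATE_KEYS}
    assignment = dict(reference.CLIMATE_ASSIGNMENT)
    comps = {}
    for label in ("stem", "branch", "leaf"):
        key = assignment[label]
        lo, hi = DEFAULT_CLIMATE_RANGES[key]
        u = 2.0 * (climate[key] - lo) / (hi - lo) - 1.0
        base = CARModel(*reference.INDEPENDENT_BIOMASS[(label, "univariate")],
                        response=label)
        mu = base.predict(dbh) * (1.0 + modulation * u)
        comps[label] = mu * _lognormal_multiplier(rng, noise_cv, n_trees)
    return [TreeRecord(tree_id=f"S{i + 1:04d}", dbh=float(dbh[i]),
                       height=float(height[i]), age=float(3.5 * dbh[i]),
                       stem=float(comps["stem"][i]),
                       branch=float(comps["branch"][i]),
                       leaf=float(comps["leaf"][i]),
                       climate={k: float(climate[k][i]) for k in CLIMATE_KEYS})
            for i in range(n_trees)]


def zero_noise_config(**overrides) -> GeneratorConfig:
    """Config with all component noise switched off (height scatter kept
    so bivariate forms stay identifiable)."""
    cvs = {c: 0.0 for c in ("stem", "branch", "leaf", "root")}
    return replace(GeneratorConfig(**overrides), noise_cv_per_component=cvs)
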
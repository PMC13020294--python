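"""Biomass allocation patterns: component proportions of whole-tree
biomass, class-binned summaries, and proportion-climate correlations.

Allocation is defined on whole-tree biomass (stem + branch + leaf +
root), so it is computed on the root-excavated subsample only.  Class
summaries follow the study design: diameter classes centered at
{2,4,6,8,12,16,20,24,28,32} cm, height classes centered at {2,...,20} m
(membership by nearest center, half-open at midpoints), and age groups
5-15, 15-25, ..., 90-105, 105-130 yr ([lo, hi), final bin closed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .data import CLIMATE_KEYS, TreeRecord, climate_array

PROPORTION_COMPONENTS = ("stem", "branch", "leaf", "root")
DIAMETER_CLASS_CENTERS = (2, 4, 6, 8, 12, 16, 20, 24, 28, 32)      # cm
HEIGHT_CLASS_CENTERS = (2, 4, 6, 8, 10, 12, 14, 16, 18, 20)        # m
AGE_BIN_EDGES = (5, 15, 25, 35, 45, 55, 65, 75, 90, 105, 130)      # yr


@dataclass(frozen=True)
class AllocationSummary:
    scheme: str                      # diameter | age | height
    bins: tuple                      # class labels (centers or (lo, hi))
    counts: np.ndarray               # trees per bin
    mean_proportions: pd.DataFrame   # rows = bins, cols = components; NaN if empty


def proportions(record: TreeRecord) -> dict[str, float]:
    """Per-tree component fractions of whole-tree biomass; sum to 1."""
    total = record.total            # raises if the root was not excavated
    if total <= 0:
        raise ValueError(f"tree {record.tree_id}: non-positive total biomass")
    return {"stem": record.stem / total, "branch": record.branch / total,
            "leaf": record.leaf / total, "root": record.root / total}


def _nearest_class(values: np.ndarray, centers) -> np.ndarray:
    """Index of the nearest class center (half-open split at midpoints)."""
    centers = np.asarray(centers, dtype=float)
    mids = (centers[:-1] + centers[1:]) / 2.0
    return np.searchsorted(mids, values, side="right")


def _age_bins(ages: np.ndarray) -> np.ndarray:
    edges = np.asarray(AGE_BIN_EDGES, dtype=float)
    idx = np.searchsorted(edges, ages, side="right") - 1
    out_of_range = (ages < edges[0]) | (ages > edges[-1])
    if np.any(out_of_range):
        warnings.warn(f"{int(out_of_range.sum())} tree(s) outside the age "
                      "groups; assigned to the nearest group", stacklevel=3)
    idx = np.clip(idx, 0, len(edges) - 2)
    idx[ages == edges[-1]] = len(edges) - 2      # final bin closed
    return idx


def summarize_by_class(records: list[TreeRecord], scheme: str) -> AllocationSummary:
    """Per-class arithmetic means of per-tree proportions (root subsample)."""
    sub = [r for r in records if r.has_root]
    if not sub:
        raise ValueError("no root-excavated records; allocation undefined")
    props = pd.DataFrame([proportions(r) for r in sub])
    if scheme == "diameter":
        x = np.array([r.dbh for r in sub])
        idx = _nearest_class(x, DIAMETER_CLASS_CENTERS)
        bins = DIAMETER_CLASS_CENTERS
    elif scheme == "height":
        x = np.array([r.height for r in sub])
        idx = _nearest_class(x, HEIGHT_CLASS_CENTERS)
        bins = HEIGHT_CLASS_CENTERS
    elif scheme == "age":
        x = np.array([r.age for r in sub])
        idx = _age_bins(x)
        bins = tuple(zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:]))
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    n_bins = len(bins)
    counts = np.bincount(idx, minlength=n_bins)
    means = pd.DataFrame(np.nan, index=range(n_bins),
                         columns=list(PROPORTION_COMPONENTS))
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            means.iloc[b] = props[sel].mean()
    if (counts == 0).any():
        empty = [bins[i] for i in np.flatnonzero(counts == 0)]
        warnings.warn(f"empty {scheme} class(es): {empty}", stacklevel=2)
    return AllocationSummary(scheme=scheme, bins=tuple(bins), counts=counts,
                             mean_proportions=means)


def correlate_proportions_climate(records: list[TreeRecord],
                                  alpha: float = 0.05,
                                  holm: bool = False) -> pd.DataFrame:
    """Pearson r and two-sided p for each (climate indicator, component
    proportion) pair; rows = 17 indicators x 4 components.

    Significance is flagged at raw ``alpha`` by default; ``holm=True``
    applies a Holm step-down adjustment across all pairs instead.
    """
    sub = [r for r in records if r.has_root and r.climate]
    if len(sub) < 3:
        raise ValueError("need >= 3 root-excavated records with climate data")
    props = pd.DataFrame([proportions(r) for r in sub])
    rows = []
    for key in CLIMATE_KEYS:
        cv = climate_array(sub, key)
        for comp in PROPORTION_COMPONENTS:
            pv = props[comp].to_numpy()
            if np.ptp(cv) == 0 or np.ptp(pv) == 0:
                rows.append({"climate": key, "component": comp,
                             "r": np.nan, "p": np.nan, "significant": False})
                continue
            r, p = pearsonr(cv, pv)
            rows.append({"climate": key, "component": comp,
                         "r": float(r), "p": float(p), "significant": False})
    table = pd.DataFrame(rows)
    valid = table["p"].notna()
    if holm:
        pvals = table.loc[valid, "p"].to_numpy()
        order = np.argsort(pvals)
        m = pvals.size
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * pvals[i])
            adj[i] = min(1.0, running)
        table.loc[valid, "significant"] = adj < alpha
    else:
        table.loc[valid, "significant"] = table.loc[valid, "p"] < alpha
    if table["p"].isna().any():
        warnings.warn("some pairs had zero variance; r reported as missing",
                      stacklevel=2)
    return table
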
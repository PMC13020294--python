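"""Tree-level records and the CSV tree-table dialect.

A :class:`TreeRecord` holds one destructively sampled tree: size
variables (DBH in cm, height in m, age in yr), oven-dry component
biomasses (kg), the 17 ClimateAP-style climate indicators, and whether
the root system was excavated.  Aboveground biomass is always the sum
stem + branch + leaf and is never stored independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: The 17 climate indicators, in canonical column order.  Degree-day
#: names are sanitized ("DD_lt0" for degree-days below 0 C, etc.)
#: because '<' and '>' are hostile in CSV headers.
CLIMATE_KEYS = (
    "MAT", "MWMT", "MCMT", "TD", "MAP", "AHM",
    "DD_lt0", "DD_gt5", "DD_lt18", "DD_gt18",
    "NFFD", "PAS", "EMT", "EXT", "EREF", "CMD", "RH",
)

#: Indicators that are physically non-negative (precipitation, snow,
#: degree-day sums).
_NONNEGATIVE_KEYS = ("MAP", "PAS", "DD_lt0", "DD_gt5", "DD_lt18", "DD_gt18")

TREE_TABLE_COLUMNS = (
    "tree_id", "dbh_cm", "height_m", "age_yr",
    "stem_kg", "branch_kg", "leaf_kg", "root_kg",
) + CLIMATE_KEYS


class TreeTableError(ValueError):
    """Malformed tree-table file (bad header or dialect)."""


@dataclass(frozen=True)
class TreeRecord:
    tree_id: str
    dbh: float          # cm, > 0
    height: float       # m, > 0
    age: float          # yr, > 0
    stem: float         # kg dry mass
    branch: float       # kg
    leaf: float         # kg
    root: float | None = None   # kg; None if the root was not excavated
    climate: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("dbh", "height", "age"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        for name in ("stem", "branch", "leaf"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.root is not None and (not np.isfinite(self.root) or self.root < 0):
            raise ValueError(f"root must be finite and >= 0, got {self.root!r}")
        if self.climate:
            missing = [k for k in CLIMATE_KEYS if k not in self.climate]
            if missing:
                raise ValueError(f"climate vector missing keys: {missing}")
            for k in _NONNEGATIVE_KEYS:
                if self.climate[k] < 0:
                    raise ValueError(f"climate {k} must be >= 0")
            if not 0.0 <= self.climate["RH"] <= 100.0:
                raise ValueError("climate RH must lie in [0, 100]")

    @property
    def aboveground(self) -> float:
        """Aboveground biomass, defined as stem + branch + leaf (kg)."""
        return self.stem + self.branch + self.leaf

    @property
    def has_root(self) -> bool:
        return self.root is not None

    @property
    def total(self) -> float:
        """Whole-tree biomass (kg); requires an excavated root."""
        if self.root is None:
            raise ValueError(f"tree {self.tree_id}: no root biomass recorded")
        return self.aboveground + self.root

    def without_root(self) -> "TreeRecord":
        return replace(self, root=None)


# ----------------------------------------------------------------- accessors

def component_array(records: list[TreeRecord], component: str) -> np.ndarray:
    """Response vector for one component label.

    ``aboveground`` is computed as the component sum; ``root`` raises if
    any record lacks an excavated root.
    """
    if component == "aboveground":
        return np.array([r.aboveground for r in records], dtype=float)
    if component == "root":
        vals = [r.root for r in records]
        if any(v is None for v in vals):
            raise ValueError("root requested but some records have no root biomass")
        return np.array(vals, dtype=float)
    if component not in ("stem", "branch", "leaf"):
        raise KeyError(f"unknown component {component!r}")
    return np.array([getattr(r, component) for r in records], dtype=float)


def size_arrays(records: list[TreeRecord]) -> tuple[np.ndarray, np.ndarray]:
    """(dbh, height) arrays in cm and m."""
    return (np.array([r.dbh for r in records], dtype=float),
            np.array([r.height for r in records], dtype=float))


def climate_array(records: list[TreeRecord], key: str) -> np.ndarray:
    if key not in CLIMATE_KEYS:
        raise KeyError(f"unknown climate indicator {key!r}")
    return np.array([r.climate[key] for r in records], dtype=float)


# ------------------------------------------------------------------ CSV I/O

def records_to_frame(records: list[TreeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "tree_id": r.tree_id, "dbh_cm": r.dbh, "height_m": r.height,
            "age_yr": r.age, "stem_kg": r.stem, "branch_kg": r.branch,
            "leaf_kg": r.leaf, "root_kg": np.nan if r.root is None else r.root,
        }
        for k in CLIMATE_KEYS:
            row[k] = r.climate.get(k, np.nan) if r.climate else np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=list(TREE_TABLE_COLUMNS))


def frame_to_records(frame: pd.DataFrame, *, source: str = "<frame>") -> list[TreeRecord]:
    """Validate rows into records; invalid rows are rejected with a warning
    citing their line numbers (header = line 1)."""
    missing = [c for c in TREE_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise TreeTableError(f"{source}: missing columns {missing}")
    records, bad = [], []
    has_climate = not frame[list(CLIMATE_KEYS)].isna().all().all()
    for pos, (_, row) in enumerate(frame.iterrows()):
        line = pos + 2
        try:
            root = None if pd.isna(row["root_kg"]) else float(row["root_kg"])
            climate = ({k: float(row[k]) for k in CLIMATE_KEYS}
                       if has_climate else {})
            records.append(TreeRecord(
                tree_id=str(row["tree_id"]), dbh=float(row["dbh_cm"]),
                height=float(row["height_m"]), age=float(row["age_yr"]),
                stem=float(row["stem_kg"]), branch=float(row["branch_kg"]),
                leaf=float(row["leaf_kg"]), root=root, climate=climate))
        except (ValueError, TypeError) as exc:
            bad.append((line, str(exc)))
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad)
        warnings.warn(f"{source}: rejected {len(bad)} row(s): {detail}",
                      stacklevel=2)
    return records


def read_tree_table(path) -> list[TreeRecord]:
    """Read the tree-table CSV dialect; see :data:`TREE_TABLE_COLUMNS`."""
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error passthrough
        raise TreeTableError(f"{path}: unreadable ({exc})") from exc
    return frame_to_records(frame, source=str(path))


def write_tree_table(records: list[TreeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)
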
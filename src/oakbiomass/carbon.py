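"""Biomass-to-carbon conversion by component carbon content factors.

Carbon stock per component is dry biomass times a component-specific
carbon content fraction (stem 0.4820 — the wood/bark arithmetic mean,
branch 0.4805, leaf 0.4923, national standard GB/T 43648-2024).
Aboveground carbon is the sum of the component carbons.

Because the CAR mean function is multiplicative in its coefficient,
a carbon-stock model is obtained from a biomass model by scaling the
coefficient by the factor, exponents unchanged; equivalently one can
refit on converted responses (the package supports both routes, which
agree up to fit tolerance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from . import reference
from .allometric import CARModel
from .data import TreeRecord


@dataclass(frozen=True)
class CarbonFactors:
    """Component carbon content fractions (kg C per kg dry mass)."""
    stem: float = reference.CARBON_FACTORS["stem"]
    branch: float = reference.CARBON_FACTORS["branch"]
    leaf: float = reference.CARBON_FACTORS["leaf"]
    root: float | None = None

    def __post_init__(self) -> None:
        for name in ("stem", "branch", "leaf", "root"):
            v = getattr(self, name)
            if v is not None and not 0.0 < v < 1.0:
                raise ValueError(f"carbon factor {name} must lie in (0, 1)")

    def __getitem__(self, component: str) -> float:
        if component == "aboveground":
            raise KeyError("aboveground carbon is the sum of component carbons, "
                           "not a single factor")
        v = getattr(self, component, None)
        if v is None:
            raise KeyError(f"no carbon factor configured for {component!r}")
        return v

    @classmethod
    def with_default_root(cls) -> "CarbonFactors":
        """Factors including the root fraction implied by the published
        belowground coefficient pair.  The root value is a reconstruction,
        not a published factor, and a warning is always issued."""
        warnings.warn(
            "root carbon factor 0.4685 is reconstructed from published "
            "coefficient ratios, not a published value", stacklevel=2)
        return cls(root=reference.ROOT_CARBON_FACTOR_IMPLIED)


def biomass_to_carbon(masses: dict[str, float] | TreeRecord,
                      factors: CarbonFactors | None = None,
                      components=("stem", "branch", "leaf")) -> dict[str, float]:
    """Per-component carbon masses (kg C) plus their aboveground sum.

    ``masses`` is a component->kg mapping or a :class:`TreeRecord`.
    Requesting a component without a configured factor raises (never a
    silent default).
    """
    factors = factors or CarbonFactors()
    if isinstance(masses, TreeRecord):
        masses = {c: (masses.root if c == "root" else getattr(masses, c))
                  for c in components}
    out = {}
    for comp in components:
        m = masses[comp]
        if m is None or m < 0:
            raise ValueError(f"{comp} biomass must be present and >= 0")
        out[comp] = m * factors[comp]
    out["aboveground"] = sum(out[c] for c in ("stem", "branch", "leaf")
                             if c in out)
    return out


def scale_model_to_carbon(model: CARModel, factor: float) -> CARModel:
    """Carbon-stock CAR model: coefficient scaled by the carbon factor,
    exponents unchanged (exact consequence of the multiplicative form)."""
    if not 0.0 < factor < 1.0:
        raise ValueError("carbon factor must lie in (0, 1)")
    return model.scaled(factor, response=f"{model.response}_carbon"
                        if model.response else "carbon")


def carbon_response(component: str, factors: CarbonFactors | None = None):
    """Callable record -> kg C, usable as a fitting response (route 1:
    fit carbon-stock models directly on converted data)."""
    factors = factors or CarbonFactors()

    def response(record: TreeRecord) -> float:
        if component == "aboveground":
            return (record.stem * factors["stem"]
                    + record.branch * factors["branch"]
                    + record.leaf * factors["leaf"])
        mass = record.root if component == "root" else getattr(record, component)
        if mass is None:
            raise ValueError(f"tree {record.tree_id}: no {component} biomass")
        return mass * factors[component]

    response.__name__ = f"{component}_carbon"
    return response
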
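"""JSON model bundles: lossless round-tripping of fitted objects.

A bundle is ``{"kind": ..., "version": ..., "payload": {...}}`` where
``kind`` tags the object type.  Serialization is canonical (sorted keys,
fixed separators) so serialize -> parse -> serialize is byte-identical.
"""

from __future__ import annotations

import json

import numpy as np

from . import __version__
from .allometric import CARModel, FitDiagnostics, WeightSpec
from .belowground import RootShootModel
from .carbon import CarbonFactors
from .systems import ClimateCARModel, CompatibleSystemFit


def _diag_dict(d: FitDiagnostics | None):
    if d is None:
        return None
    return {"converged": d.converged, "n_iter": d.n_iter,
            "sse": d.sse, "message": d.message}


def _diag_from(d):
    return None if d is None else FitDiagnostics(**d)


def _weight_dict(w: WeightSpec):
    return {"mode": w.mode, "power": w.power, "source": w.source}


def to_payload(obj) -> tuple[str, dict]:
    if isinstance(obj, CARModel):
        return "car_model", {
            "a0": obj.a0, "a1": obj.a1, "a2": obj.a2,
            "response": obj.response, "weighting": _weight_dict(obj.weighting),
            "diagnostics": _diag_dict(obj.diagnostics)}
    if isinstance(obj, ClimateCARModel):
        return "climate_car_model", {
            "c0": obj.c0, "c01": obj.c01, "e1": obj.e1, "e11": obj.e11,
            "e2": obj.e2, "e21": obj.e21,
            "climate_variable": obj.climate_variable, "response": obj.response}
    if isinstance(obj, CompatibleSystemFit):
        return "compatible_system", {
            "structure": obj.structure,
            "models": {k: dict(zip(("kind", "payload"), to_payload(m)))
                       for k, m in obj.models.items()},
            "total_model": None if obj.total_model is None
            else to_payload(obj.total_model)[1],
            "proportion_models": None if obj.proportion_models is None
            else {k: to_payload(m)[1] for k, m in obj.proportion_models.items()},
            "sigma": np.asarray(obj.sigma).tolist(),
            "diagnostics": _diag_dict(obj.diagnostics)}
    if isinstance(obj, RootShootModel):
        return "root_shoot_model", {
            "b0": obj.b0, "b1": obj.b1, "b2": obj.b2,
            "aboveground": None if obj.aboveground is None
            else to_payload(obj.aboveground)[1],
            "diagnostics": _diag_dict(obj.diagnostics)}
    if isinstance(obj, CarbonFactors):
        return "carbon_factors", {"stem": obj.stem, "branch": obj.branch,
                                  "leaf": obj.leaf, "root": obj.root}
    raise TypeError(f"cannot serialize {type(obj).__name__}")


def _car_from(p) -> CARModel:
    return CARModel(a0=p["a0"], a1=p["a1"], a2=p["a2"], response=p["response"],
                    weighting=WeightSpec(**p["weighting"]),
                    diagnostics=_diag_from(p["diagnostics"]))


def from_payload(kind: str, p: dict):
    if kind == "car_model":
        return _car_from(p)
    if kind == "climate_car_model":
        return ClimateCARModel(c0=p["c0"], c01=p["c01"], e1=p["e1"],
                               e11=p["e11"], e2=p["e2"], e21=p["e21"],
                               climate_variable=p["climate_variable"],
                               response=p["response"])
    if kind == "compatible_system":
        return CompatibleSystemFit(
            structure=p["structure"],
            models={k: from_payload(m["kind"], m["payload"])
                    for k, m in p["models"].items()},
            sigma=np.asarray(p["sigma"], dtype=float),
            diagnostics=_diag_from(p["diagnostics"]),
            total_model=None if p["total_model"] is None
            else _car_from(p["total_model"]),
            proportion_models=None if p["proportion_models"] is None
            else {k: _car_from(v) for k, v in p["proportion_models"].items()})
    if kind == "root_shoot_model":
        return RootShootModel(b0=p["b0"], b1=p["b1"], b2=p["b2"],
                              aboveground=None if p["aboveground"] is None
                              else _car_from(p["aboveground"]),
                              diagnostics=_diag_from(p["diagnostics"]))
    if kind == "carbon_factors":
        return CarbonFactors(stem=p["stem"], branch=p["branch"],
                             leaf=p["leaf"], root=p["root"])
    raise ValueError(f"unknown bundle kind {kind!r}")


def dumps(obj) -> str:
    kind, payload = to_payload(obj)
    return json.dumps({"kind": kind, "version": __version__,
                       "payload": payload},
                      sort_keys=True, separators=(",", ":"))


def loads(text: str):
    doc = json.loads(text)
    return from_payload(doc["kind"], doc["payload"])


def save_bundle(obj, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps(obj))


def load_bundle(path):
    with open(path, encoding="utf-8") as fh:
        return loads(fh.read())
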
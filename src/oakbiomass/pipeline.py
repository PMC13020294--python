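"""End-to-end orchestration: simulate/load -> independent fits ->
compatible systems -> climate system -> root-shoot -> carbon ->
evaluation -> allocation.

``run_pipeline`` takes a plain-dict config and returns a report dict of
fitted objects, evaluation tables and allocation summaries; with
``out_dir`` set it also writes model bundles (JSON), an evaluation table
and allocation summaries (CSV).  One seed in the config makes the whole
run reproducible.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd

from . import serialize
from .allocation import correlate_proportions_climate, summarize_by_class
from .allometric import fit_car
from .belowground import fit_root_shoot, mpe_adjustment
from .carbon import CarbonFactors, carbon_response
from .data import component_array, read_tree_table, size_arrays, write_tree_table
from .evaluation import evaluate
from .synthetic import GeneratorConfig, generate_trees
from .systems import fit_aggregation, fit_climate_aggregation, fit_decomposition

ALL_STAGES = ("independent", "decomposition", "aggregation", "climate",
              "rootshoot", "carbon", "evaluate", "allocation")


class PipelineError(RuntimeError):
    """Stage ordering / dependency problem."""


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Run the requested stages; see module docstring.

    Config keys: ``simulate`` (GeneratorConfig kwargs) or ``input``
    (tree-table CSV path); optional ``stages`` (subset of
    :data:`ALL_STAGES`, order-insensitive), ``seed``.
    """
    stages = tuple(config.get("stages", ALL_STAGES))
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise PipelineError(f"unknown stages {sorted(unknown)}")
    if "evaluate" in stages and "independent" not in stages:
        raise PipelineError("evaluate stage needs fitted models "
                            "(include the independent stage)")
    if "simulate" in config:
        gen_kwargs = dict(config["simulate"])
        gen_kwargs.setdefault("seed", config.get("seed", 0))
        gen_cfg = GeneratorConfig(**gen_kwargs)
        records = generate_trees(gen_cfg)
    elif "input" in config:
        records = read_tree_table(config["input"])
    else:
        raise PipelineError("config needs a 'simulate' block or an 'input' path")

    report: dict = {"n_trees": len(records),
                    "n_root": sum(r.has_root for r in records)}
    bundles: dict = {}
    dbh, height = size_arrays(records)
    eval_rows = []

    def record_eval(name, obs, pred, p):
        stats = evaluate(obs, pred, p)
        row = {"item": name}
        row.update(stats.as_dict())
        eval_rows.append(row)

    if "independent" in stages:
        indep = {}
        for comp in ("stem", "branch", "leaf", "aboveground"):
            for form in ("univariate", "bivariate"):
                m = fit_car(records, comp, form=form)
                indep[(comp, form)] = m
                pred = m.predict(dbh, height if form == "bivariate" else None)
                record_eval(f"independent:{comp}:{form}",
                            component_array(records, comp), pred, m.n_params)
        report["independent"] = indep
        bundles.update({f"independent_{c}_{f}": m
                        for (c, f), m in indep.items()})

    if "decomposition" in stages:
        if "independent" not in stages:
            raise PipelineError("decomposition needs the independent stage "
                                "(frozen aboveground total)")
        dec = fit_decomposition(records,
                                total_spec=report["independent"][("aboveground",
                                                                  "bivariate")])
        report["decomposition"] = dec
        bundles["decomposition_system"] = dec
        comps = dec.predict_components(dbh, height)
        for c in ("stem", "branch", "leaf"):
            record_eval(f"decomposition:{c}", component_array(records, c),
                        comps[c], 2)

    if "aggregation" in stages:
        agg = fit_aggregation(records)
        report["aggregation"] = agg
        bundles["aggregation_system"] = agg
        comps = agg.predict_components(dbh, height)
        for c in ("stem", "branch", "leaf"):
            record_eval(f"aggregation:{c}", component_array(records, c),
                        comps[c], agg.models[c].n_params)
        record_eval("aggregation:aboveground",
                    component_array(records, "aboveground"),
                    agg.predict_total(dbh, height), 7)

    if "climate" in stages:
        if any(not r.climate for r in records):
            raise PipelineError("climate stage requires climate data on "
                                "every record")
        clim_fit = fit_climate_aggregation(records,
                                           config.get("climate_assignment"))
        report["climate"] = clim_fit
        bundles["climate_system"] = clim_fit
        cvals = {m.climate_variable:
                 pd.Series([r.climate[m.climate_variable] for r in records]).to_numpy()
                 for m in clim_fit.models.values()}
        comps = clim_fit.predict_components(dbh, height, cvals)
        for c in ("stem", "branch", "leaf"):
            record_eval(f"climate:{c}", component_array(records, c), comps[c],
                        clim_fit.models[c].n_params)

    if "rootshoot" in stages:
        rs = fit_root_shoot(records, form=config.get("rootshoot_form",
                                                     "univariate"))
        report["rootshoot"] = rs
        bundles["rootshoot_model"] = rs
        sub = [r for r in records if r.has_root]
        d_s, h_s = size_arrays(sub)
        pred_root = rs.ratio(d_s) * rs.aboveground.predict(d_s)
        stats = evaluate(component_array(sub, "root"), pred_root,
                         rs.n_params + rs.aboveground.n_params)
        row = {"item": "rootshoot:root"}
        row.update(stats.as_dict())
        eval_rows.append(row)
        report["mpe_adjustment"] = mpe_adjustment(records, stats.mpe)

    if "carbon" in stages:
        if "independent" not in stages:
            raise PipelineError("carbon stage needs fitted biomass models")
        factors = CarbonFactors()
        scaled = {key: m.scaled(factors[key[0]])
                  for key, m in report["independent"].items()
                  if key[0] != "aboveground"}
        direct = {}
        for comp in ("stem", "branch", "leaf"):
            resp = carbon_response(comp, factors)
            direct[comp] = fit_car(records, resp)
        report["carbon"] = {"scaled": scaled, "direct": direct,
                            "factors": factors}
        bundles["carbon_factors"] = factors

    if "allocation" in stages:
        summaries = {scheme: summarize_by_class(records, scheme)
                     for scheme in ("diameter", "age", "height")}
        report["allocation"] = summaries
        if all(r.climate for r in records if r.has_root):
            report["allocation_climate"] = correlate_proportions_climate(records)

    eval_table = pd.DataFrame(eval_rows)
    report["evaluation_table"] = eval_table

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_tree_table(records, out / "trees.csv")
        for name, obj in bundles.items():
            serialize.save_bundle(obj, out / f"{name}.json")
        if not eval_table.empty:
            eval_table.to_csv(out / "evaluation.csv", index=False)
        if "allocation" in report:
            for scheme, summ in report["allocation"].items():
                tab = summ.mean_proportions.copy()
                tab.insert(0, "bin", [str(b) for b in summ.bins])
                tab.insert(1, "count", summ.counts)
                tab.to_csv(out / f"allocation_{scheme}.csv", index=False)
        if "allocation_climate" in report:
            report["allocation_climate"].to_csv(
                out / "allocation_climate_correlations.csv", index=False)
    return report
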
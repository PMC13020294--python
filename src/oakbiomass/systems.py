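"""Additivity-constrained simultaneous biomass systems fitted by nonlinear
seemingly-unrelated regression (NSUR).

Three structures are supported:

* **aggregation** — stem, branch and leaf each get their own CAR (or
  climate-parameterized CAR) equation and the total is their algebraic
  sum, so additivity holds by construction.  The three component
  equations are estimated jointly with a 3x3 cross-equation error
  covariance (the total equation is an exact linear combination of the
  components and would make a 4x4 covariance singular).
* **decomposition** — an independently fitted aboveground total f1 is
  split into component shares {1, g_branch, g_leaf}/(1 + g_branch +
  g_leaf), where the g's are CAR-form proportion functions; shares sum
  to one identically.
* **climate aggregation** — the aggregation structure with coefficient
  and exponents linear in one climate indicator per component
  (stem: degree-days below 0 C, branch: precipitation as snow,
  leaf: continentality by default).

Estimation is iterated feasible GLS: per-equation weighted fits seed the
parameters, the error covariance is estimated from heteroscedasticity-
standardized cross-equation residuals, and the joint covariance-weighted
objective is minimized; the loop repeats until the parameters stabilize.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular, LinAlgError
from scipy.optimize import least_squares
from scipy.stats import pearsonr

from . import reference
from .allometric import (CARModel, FitDiagnostics, FitError, WeightSpec,
                         WEIGHT_FLOOR, fit_car)
from .data import (CLIMATE_KEYS, TreeRecord, climate_array, component_array,
                   size_arrays)

COMPONENTS = ("stem", "branch", "leaf")
MAX_OUTER_ITER = 100
OUTER_TOL = 1e-8


# --------------------------------------------------------------------- types

@dataclass(frozen=True)
class ClimateCARModel:
    """CAR power law whose coefficient and exponents are linear in one
    climate indicator c:  (c0 + c01*c) * DBH^(e1 + e11*c) [* H^(e2 + e21*c)].
    """
    c0: float
    c01: float
    e1: float
    e11: float
    e2: float | None = None
    e21: float | None = None
    climate_variable: str = "DD_lt0"
    response: str = ""

    def __post_init__(self) -> None:
        if self.climate_variable not in CLIMATE_KEYS:
            raise ValueError(f"unknown climate indicator {self.climate_variable!r}")
        if (self.e2 is None) != (self.e21 is None):
            raise ValueError("height exponent base and slope must come together")

    @property
    def form(self) -> str:
        return "univariate" if self.e2 is None else "bivariate"

    @property
    def n_params(self) -> int:
        return 4 if self.e2 is None else 6

    def effective(self, climate_value: float) -> tuple:
        """(coefficient, dbh exponent[, height exponent]) at one climate value."""
        coeff = self.c0 + self.c01 * climate_value
        e_d = self.e1 + self.e11 * climate_value
        if self.e2 is None:
            return coeff, e_d
        return coeff, e_d, self.e2 + self.e21 * climate_value

    def predict(self, dbh, height=None, climate_value=None):
        if climate_value is None:
            raise ValueError("climate-parameterized model requires its climate value")
        c = np.asarray(climate_value, dtype=float)
        dbh = np.asarray(dbh, dtype=float)
        coeff = self.c0 + self.c01 * c
        out = coeff * dbh ** (self.e1 + self.e11 * c)
        if self.e2 is not None:
            if height is None:
                raise ValueError("bivariate model requires height")
            out = out * np.asarray(height, dtype=float) ** (self.e2 + self.e21 * c)
        return out


@dataclass(frozen=True)
class CompatibleSystemSpec:
    """Which structure to fit and the per-equation mean-function forms."""
    structure: str                                   # aggregation | decomposition | climate_aggregation
    component_forms: dict = field(default_factory=lambda: {
        "stem": "bivariate", "branch": "univariate", "leaf": "univariate"})
    total_form: str = "bivariate"                    # decomposition f1
    proportion_forms: dict = field(default_factory=lambda: {
        "branch": "univariate", "leaf": "univariate"})
    climate_assignment: dict = field(
        default_factory=lambda: dict(reference.CLIMATE_ASSIGNMENT))

    def __post_init__(self) -> None:
        if self.structure not in ("aggregation", "decomposition",
                                  "climate_aggregation"):
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.structure != "decomposition":
            if set(self.component_forms) != set(COMPONENTS):
                raise ValueError("need forms for exactly stem, branch, leaf")
        else:
            if set(self.proportion_forms) != {"branch", "leaf"}:
                raise ValueError("decomposition needs branch and leaf proportion functions")


@dataclass(frozen=True)
class CompatibleSystemFit:
    """A fitted simultaneous system."""
    structure: str
    models: dict                    # aggregation/climate: label -> CAR/ClimateCAR
    sigma: np.ndarray               # cross-equation error covariance (standardized scale)
    diagnostics: FitDiagnostics
    total_model: CARModel | None = None          # decomposition f1
    proportion_models: dict | None = None        # decomposition g functions

    def shares(self, dbh, height=None):
        """Decomposition component shares; sum to 1 identically."""
        if self.structure != "decomposition":
            raise ValueError("shares are defined for the decomposition structure")
        g = {}
        for label, m in self.proportion_models.items():
            val = m.predict(dbh, height if m.form == "bivariate" else None)
            if np.any(val < 0):
                raise ValueError(f"proportion function for {label} is negative")
            g[label] = val
        denom = 1.0 + g["branch"] + g["leaf"]
        return {"stem": 1.0 / denom, "branch": g["branch"] / denom,
                "leaf": g["leaf"] / denom}

    def predict_components(self, dbh, height=None, climate=None):
        """Per-component predictions (kg); climate maps indicator -> values."""
        dbh = np.asarray(dbh, dtype=float)
        if self.structure == "decomposition":
            f1 = self.total_model.predict(
                dbh, height if self.total_model.form == "bivariate" else None)
            return {k: s * f1 for k, s in self.shares(dbh, height).items()}
        out = {}
        for label, m in self.models.items():
            h = height if m.form == "bivariate" else None
            if isinstance(m, ClimateCARModel):
                if climate is None:
                    raise ValueError("climate values required for this system")
                out[label] = m.predict(dbh, h, climate[m.climate_variable])
            else:
                out[label] = m.predict(dbh, h)
        return out

    def predict_total(self, dbh, height=None, climate=None):
        """Total aboveground prediction; identically the component sum."""
        comps = self.predict_components(dbh, height, climate)
        return comps["stem"] + comps["branch"] + comps["leaf"]


# ------------------------------------------------------------------ NSUR core

def _standardize(resid: np.ndarray, means: np.ndarray, power: float) -> np.ndarray:
    return resid / np.maximum(np.abs(means), WEIGHT_FLOOR) ** (power / 2.0)


def _safe_cholesky(sigma: np.ndarray):
    try:
        return cholesky(sigma, lower=True)
    except LinAlgError:
        ridge = 1e-8 * np.trace(sigma) / sigma.shape[0] + 1e-12
        warnings.warn("singular cross-equation covariance; ridge-regularized",
                      stacklevel=2)
        return cholesky(sigma + ridge * np.eye(sigma.shape[0]), lower=True)


def nsur_core(y_mat: np.ndarray, predict, theta0: np.ndarray, *,
              weight_power: float = 1.0, sigma=None,
              bounds=(-np.inf, np.inf), tol: float = OUTER_TOL,
              max_outer: int = MAX_OUTER_ITER):
    """Iterated feasible GLS over a stack of nonlinear equations.

    ``y_mat`` is (n, m); ``predict(theta)`` returns the (n, m) mean
    matrix (equations may share parameters).  Residuals are standardized
    per equation by mean^(power/2) before the cross-equation covariance
    is estimated (``sigma`` fixes it instead of re-estimating).  Returns
    (theta, sigma, diagnostics).
    """
    n, m = y_mat.shape
    theta = np.asarray(theta0, dtype=float)
    bounded = not (np.all(np.isneginf(np.atleast_1d(bounds[0])))
                   and np.all(np.isposinf(np.atleast_1d(bounds[1]))))
    converged, outer = False, 0
    for outer in range(1, max_outer + 1):
        means = predict(theta)
        scale = np.maximum(np.abs(means), WEIGHT_FLOOR) ** (weight_power / 2.0)
        if sigma is None:
            u = (y_mat - means) / scale
            s_mat = (u.T @ u) / n
        else:
            s_mat = np.asarray(sigma, dtype=float)
        chol_l = _safe_cholesky(s_mat)

        def joint_resid(p, scale=scale, chol_l=chol_l):
            u = (y_mat - predict(p)) / scale
            return solve_triangular(chol_l, u.T, lower=True).T.ravel()

        sol = least_squares(joint_resid, theta,
                            method="trf" if bounded else "lm",
                            bounds=bounds if bounded else (-np.inf, np.inf),
                            x_scale="jac", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        step = np.max(np.abs(sol.x - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = sol.x
        if step < tol:
            converged = True
            break
    means = predict(theta)
    scale = np.maximum(np.abs(means), WEIGHT_FLOOR) ** (weight_power / 2.0)
    u = (y_mat - means) / scale
    s_final = (u.T @ u) / n if sigma is None else np.asarray(sigma, dtype=float)
    diag = FitDiagnostics(converged=converged, n_iter=outer,
                          sse=float(np.sum((y_mat - means) ** 2)),
                          message="" if converged else
                          "NSUR outer loop did not converge")
    return theta, s_final, diag


# ----------------------------------------------------- structure-specific fits

def _pack_car(models_forms, records, init_models):
    """Parameter packing helpers shared by aggregation-style fits."""
    slices, theta0, lo = {}, [], 0
    for label in COMPONENTS:
        m = init_models[label]
        p = [m.a0, m.a1] + ([m.a2] if m.a2 is not None else [])
        slices[label] = slice(lo, lo + len(p))
        theta0.extend(p)
        lo += len(p)
    return slices, np.array(theta0, dtype=float)


def fit_aggregation(records: list[TreeRecord], component_forms=None, *,
                    weights: WeightSpec | None = None, sigma=None,
                    tol: float = OUTER_TOL) -> CompatibleSystemFit:
    """Additive aggregation system: per-component CAR equations whose sum is
    the total by construction.  Default forms follow the published system
    (stem bivariate, branch and leaf univariate)."""
    spec = CompatibleSystemSpec("aggregation",
                                component_forms=component_forms or
                                {"stem": "bivariate", "branch": "univariate",
                                 "leaf": "univariate"})
    weights = weights or WeightSpec()
    dbh, height = size_arrays(records)
    y_mat = np.column_stack([component_array(records, c) for c in COMPONENTS])
    init_models = {c: fit_car(records, c, form=spec.component_forms[c],
                              weights=weights) for c in COMPONENTS}
    slices, theta0 = _pack_car(spec.component_forms, records, init_models)
    forms = {c: spec.component_forms[c] for c in COMPONENTS}

    def predict(theta):
        cols = []
        for c in COMPONENTS:
            p = theta[slices[c]]
            col = p[0] * dbh ** p[1]
            if forms[c] == "bivariate":
                col = col * height ** p[2]
            cols.append(col)
        return np.column_stack(cols)

    theta, s_mat, diag = nsur_core(y_mat, predict, theta0,
                                   weight_power=weights.power, sigma=sigma,
                                   tol=tol)
    models = {}
    for c in COMPONENTS:
        p = theta[slices[c]]
        models[c] = CARModel(a0=float(p[0]), a1=float(p[1]),
                             a2=float(p[2]) if forms[c] == "bivariate" else None,
                             response=c, weighting=weights)
    return CompatibleSystemFit(structure="aggregation", models=models,
                               sigma=s_mat, diagnostics=diag)


def fit_decomposition(records: list[TreeRecord], total_spec=None,
                      proportion_forms=None, *, weights: WeightSpec | None = None,
                      refit_total: bool = False, sigma=None,
                      tol: float = OUTER_TOL) -> CompatibleSystemFit:
    """Decomposition system: components as shares of an aboveground total.

    ``total_spec`` is a fitted aboveground :class:`CARModel` or a form
    string (default bivariate, fitted independently and then frozen;
    ``refit_total=True`` re-estimates it jointly with the shares).
    """
    weights = weights or WeightSpec()
    if isinstance(total_spec, CARModel):
        total_model = total_spec
    else:
        total_model = fit_car(records, "aboveground",
                              form=total_spec or "bivariate", weights=weights)
    pforms = proportion_forms or {"branch": "univariate", "leaf": "univariate"}
    CompatibleSystemSpec("decomposition", proportion_forms=pforms)
    dbh, height = size_arrays(records)
    y_mat = np.column_stack([component_array(records, c) for c in COMPONENTS])
    f1 = total_model.predict(dbh,
                             height if total_model.form == "bivariate" else None)

    # share parameters: g_label = c0 * D^c1 [* H^c2], c0 > 0
    labels = ("branch", "leaf")
    slices, theta0, lo_bounds, hi_bounds, lo = {}, [], [], [], 0
    ybar = y_mat.mean(axis=0)
    for i, label in enumerate(labels):
        npar = 2 if pforms[label] == "univariate" else 3
        slices[label] = slice(lo, lo + npar)
        # crude share-ratio start: mean component / mean stem, flat in D
        theta0.extend([ybar[i + 1] / max(ybar[0], 1e-9), 0.0] + [0.0] * (npar - 2))
        lo_bounds.extend([1e-9] + [-np.inf] * (npar - 1))
        hi_bounds.extend([np.inf] * npar)
        lo += npar
    n_share = lo
    refit = bool(refit_total)
    if refit:
        p_tot = [total_model.a0, total_model.a1] + (
            [total_model.a2] if total_model.a2 is not None else [])
        theta0.extend(p_tot)
        lo_bounds.extend([1e-9] + [-np.inf] * (len(p_tot) - 1))
        hi_bounds.extend([np.inf] * len(p_tot))
    theta0 = np.array(theta0, dtype=float)

    def g_vals(theta):
        out = {}
        for label in labels:
            p = theta[slices[label]]
            v = p[0] * dbh ** p[1]
            if pforms[label] == "bivariate":
                v = v * height ** p[2]
            out[label] = v
        return out

    def predict(theta):
        g = g_vals(theta)
        denom = 1.0 + g["branch"] + g["leaf"]
        if refit:
            p = theta[n_share:]
            tot = p[0] * dbh ** p[1]
            if total_model.form == "bivariate":
                tot = tot * height ** p[2]
        else:
            tot = f1
        return np.column_stack([tot / denom, tot * g["branch"] / denom,
                                tot * g["leaf"] / denom])

    theta, s_mat, diag = nsur_core(y_mat, predict, theta0,
                                   weight_power=weights.power, sigma=sigma,
                                   bounds=(np.array(lo_bounds), np.array(hi_bounds)),
                                   tol=tol)
    prop_models = {}
    for label in labels:
        p = theta[slices[label]]
        prop_models[label] = CARModel(
            a0=float(p[0]), a1=float(p[1]),
            a2=float(p[2]) if pforms[label] == "bivariate" else None,
            response=f"{label}_share", weighting=weights)
    if refit:
        p = theta[n_share:]
        total_model = CARModel(a0=float(p[0]), a1=float(p[1]),
                               a2=float(p[2]) if total_model.form == "bivariate"
                               else None,
                               response="aboveground", weighting=weights)
    return CompatibleSystemFit(structure="decomposition", models={},
                               sigma=s_mat, diagnostics=diag,
                               total_model=total_model,
                               proportion_models=prop_models)


def _climate_loglog_init(dbh, height, y, clim, *, bivariate: bool) -> list:
    """Starting values for one climate-parameterized equation.

    Log-linearization: ln y ~ [1, c, ln D, c ln D (, ln H, c ln H)] gives
    the exponent base/slope directly; the log-scale coefficient
    exp(alpha + beta c) is linearized around the mean climate value to
    seed (c0, c01).
    """
    ylog = np.log(np.maximum(np.asarray(y, dtype=float), 1e-9))
    ld = np.log(dbh)
    cols = [np.ones_like(ld), clim, ld, clim * ld]
    if bivariate:
        lh = np.log(height)
        cols += [lh, clim * lh]
    beta, *_ = np.linalg.lstsq(np.column_stack(cols), ylog, rcond=None)
    cbar = float(np.mean(clim))
    scale = np.exp(beta[0] + beta[1] * cbar)
    c0 = scale * (1.0 - beta[1] * cbar)
    c01 = scale * beta[1]
    out = [c0, c01, beta[2], beta[3]]
    if bivariate:
        out += [beta[4], beta[5]]
    return out


def fit_climate_aggregation(records: list[TreeRecord], climate_assignment=None,
                            component_forms=None, *,
                            weights: WeightSpec | None = None, sigma=None,
                            tol: float = OUTER_TOL) -> CompatibleSystemFit:
    """Aggregation system with climate-parameterized coefficients/exponents.

    Each component's coefficient and exponents are linear in one assigned
    climate indicator (defaults: stem -> DD_lt0, branch -> PAS,
    leaf -> TD).  Initialized from the plain aggregation fit with zero
    climate slopes.
    """
    assignment = dict(reference.CLIMATE_ASSIGNMENT)
    if climate_assignment:
        assignment.update(climate_assignment)
    for label, key in assignment.items():
        if key not in CLIMATE_KEYS:
            raise ValueError(f"unknown climate indicator {key!r} for {label}")
    forms = component_forms or {"stem": "bivariate", "branch": "univariate",
                                "leaf": "univariate"}
    weights = weights or WeightSpec()
    dbh, height = size_arrays(records)
    y_mat = np.column_stack([component_array(records, c) for c in COMPONENTS])
    clim = {c: climate_array(records, assignment[c]) for c in COMPONENTS}

    slices, theta0, lo = {}, [], 0
    for c, yc in zip(COMPONENTS, y_mat.T):
        p = _climate_loglog_init(dbh, height, yc, clim[c],
                                 bivariate=forms[c] == "bivariate")
        slices[c] = slice(lo, lo + len(p))
        theta0.extend(p)
        lo += len(p)
    theta0 = np.array(theta0, dtype=float)

    def predict(theta):
        cols = []
        for c in COMPONENTS:
            p = theta[slices[c]]
            cv = clim[c]
            col = (p[0] + p[1] * cv) * dbh ** (p[2] + p[3] * cv)
            if forms[c] == "bivariate":
                col = col * height ** (p[4] + p[5] * cv)
            cols.append(col)
        return np.column_stack(cols)

    theta, s_mat, diag = nsur_core(y_mat, predict, theta0,
                                   weight_power=weights.power, sigma=sigma,
                                   tol=tol)
    models = {}
    for c in COMPONENTS:
        p = theta[slices[c]]
        biv = forms[c] == "bivariate"
        models[c] = ClimateCARModel(
            c0=float(p[0]), c01=float(p[1]), e1=float(p[2]), e11=float(p[3]),
            e2=float(p[4]) if biv else None, e21=float(p[5]) if biv else None,
            climate_variable=assignment[c], response=c)
        coeff = p[0] + p[1] * clim[c]
        if np.any(coeff <= 0):
            raise FitError(
                f"{c}: effective coefficient non-positive for "
                f"{int(np.sum(coeff <= 0))} training record(s); fit rejected")
    return CompatibleSystemFit(structure="climate_aggregation", models=models,
                               sigma=s_mat, diagnostics=diag)


# ------------------------------------------------------- climate screening

def select_climate_factors(records: list[TreeRecord], *,
                           collinearity_threshold: float = 0.7):
    """Pick one climate indicator per component by Pearson correlation.

    For each component (processed stem, branch, leaf) the candidate is
    the indicator with the largest absolute correlation to the component
    biomass; a candidate is demoted (next-best taken) when its absolute
    correlation with an indicator already chosen for another component
    exceeds ``collinearity_threshold``.  Ties break on lexicographic
    indicator order.  Returns (assignment dict, correlation report dict
    component -> {indicator: r}).
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records for correlation screening")
    cols = {}
    for key in CLIMATE_KEYS:
        v = climate_array(records, key)
        if np.ptp(v) == 0:
            warnings.warn(f"climate indicator {key} has zero variance; excluded",
                          stacklevel=2)
            continue
        cols[key] = v
    report, assignment, chosen = {}, {}, []
    for comp in COMPONENTS:
        y = component_array(records, comp)
        rs = {k: float(pearsonr(v, y)[0]) for k, v in cols.items()}
        report[comp] = rs
        if not rs:
            continue
        ranked = sorted(rs, key=lambda k: (-abs(rs[k]), k))
        for cand in ranked:
            clash = any(
                cand == prev or
                abs(pearsonr(cols[cand], cols[prev])[0]) > collinearity_threshold
                for prev in chosen)
            if not clash:
                assignment[comp] = cand
                chosen.append(cand)
                break
    if not assignment:
        warnings.warn("no usable climate indicators; empty selection",
                      stacklevel=2)
    return assignment, report
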
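"""Constant-allometric-ratio (CAR) power-law models with heteroscedasticity
weighting.

The mean function is the classic allometric form

    Y = a0 * DBH^a1            (univariate)
    Y = a0 * DBH^a1 * H^a2     (bivariate)

with an additive arithmetic-scale error whose variance grows with tree
size.  Fitting is weighted nonlinear least squares: squared residuals
are weighted by ``1 / f(x)^power`` (residuals standardized by
``1/sqrt(f(x))`` when power = 1), with weights refreshed from the
current fitted means until the parameters stabilize (iteratively
reweighted NLS).  Initialization is ordinary least squares on
log-transformed data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .data import TreeRecord, component_array, size_arrays

WEIGHT_FLOOR = 1e-12        # floor on fitted means before inversion
MAX_IRLS_ITER = 50
PARAM_TOL = 1e-8


class FitError(RuntimeError):
    """Fitting could not produce a usable model (degenerate input)."""


@dataclass(frozen=True)
class WeightSpec:
    """Heteroscedasticity weighting for squared residuals.

    ``power=1`` weights squared residuals by 1/f(x) (the usual
    residual/sqrt(f) standardization); ``power=2`` corresponds to a
    variance proportional to the squared mean.  ``source`` selects
    whether f(x) is the current fitted mean or the observed response.
    """
    mode: str = "inverse_mean_power"     # or "none"
    power: float = 1.0
    source: str = "fitted_mean"          # or "observed_response"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "inverse_mean_power"):
            raise ValueError(f"unknown weighting mode {self.mode!r}")
        if self.power < 0:
            raise ValueError("weight power must be >= 0")
        if self.source not in ("fitted_mean", "observed_response"):
            raise ValueError(f"unknown weight source {self.source!r}")


@dataclass(frozen=True)
class FitDiagnostics:
    converged: bool
    n_iter: int
    sse: float = float("nan")
    message: str = ""


@dataclass(frozen=True)
class CARModel:
    """A fitted or specified CAR power law."""
    a0: float
    a1: float
    a2: float | None = None              # present iff bivariate
    response: str = ""
    weighting: WeightSpec = field(default_factory=WeightSpec)
    diagnostics: FitDiagnostics | None = None

    @property
    def form(self) -> str:
        return "univariate" if self.a2 is None else "bivariate"

    @property
    def n_params(self) -> int:
        return 2 if self.a2 is None else 3

    def predict(self, dbh, height=None):
        return predict_car(self, dbh, height)

    def scaled(self, factor: float, response: str | None = None) -> "CARModel":
        """Coefficient scaled by ``factor``; exponents unchanged."""
        return replace(self, a0=self.a0 * factor,
                       response=self.response if response is None else response)


def predict_car(model: CARModel, dbh, height=None):
    """Evaluate the CAR mean function (kg for biomass responses)."""
    dbh = np.asarray(dbh, dtype=float)
    if np.any(dbh <= 0):
        raise ValueError("dbh must be > 0")
    if model.a2 is None:
        if height is not None:
            raise ValueError("height given for a univariate model")
        return model.a0 * dbh ** model.a1
    if height is None:
        raise ValueError("bivariate model requires height")
    height = np.asarray(height, dtype=float)
    if np.any(height <= 0):
        raise ValueError("height must be > 0")
    return model.a0 * dbh ** model.a1 * height ** model.a2


def compute_weights(fitted_means, spec: WeightSpec) -> np.ndarray:
    """Per-observation weights on squared residuals, w = f(x)^(-power)."""
    f = np.asarray(fitted_means, dtype=float)
    if spec.mode == "none":
        return np.ones_like(f)
    if np.any(f <= 0):
        raise ValueError("weights require strictly positive means")
    return np.maximum(f, WEIGHT_FLOOR) ** (-spec.power)


def _loglog_init(dbh, height, y, bivariate: bool) -> np.ndarray:
    y = np.maximum(np.asarray(y, dtype=float), 1e-9)
    cols = [np.ones_like(dbh), np.log(dbh)]
    if bivariate:
        cols.append(np.log(height))
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, np.log(y), rcond=None)
    beta[0] = np.exp(beta[0])
    return beta


def fit_car_xy(dbh, height, y, *, form: str = "univariate",
               weights: WeightSpec | None = None,
               init=None, response: str = "") -> CARModel:
    """Core IRLS fit on plain arrays (records wrapper: :func:`fit_car`)."""
    weights = weights or WeightSpec()
    dbh = np.asarray(dbh, dtype=float)
    y = np.asarray(y, dtype=float)
    bivariate = form == "bivariate"
    if form not in ("univariate", "bivariate"):
        raise ValueError(f"unknown form {form!r}")
    h = None if not bivariate else np.asarray(height, dtype=float)
    n_min = 4 if bivariate else 3
    if y.size < n_min:
        raise FitError(f"need >= {n_min} observations for a {form} fit")
    if np.any(dbh <= 0) or (bivariate and np.any(h <= 0)):
        raise ValueError("predictors must be strictly positive")
    if np.ptp(y) == 0:
        raise FitError("degenerate response: all observations equal")

    def mean_fn(p):
        out = p[0] * dbh ** p[1]
        if bivariate:
            out = out * h ** p[2]
        return out

    theta = np.asarray(init, dtype=float) if init is not None \
        else _loglog_init(dbh, h, y, bivariate)
    converged, it = False, 0
    for it in range(1, MAX_IRLS_ITER + 1):
        if weights.mode == "none":
            w = np.ones_like(y)
        else:
            base = y if weights.source == "observed_response" else mean_fn(theta)
            w = np.maximum(np.abs(base), WEIGHT_FLOOR) ** (-weights.power)
        sw = np.sqrt(w)
        sol = least_squares(lambda p: sw * (y - mean_fn(p)), theta,
                            method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        step = np.max(np.abs(sol.x - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = sol.x
        if weights.mode == "none" or weights.source == "observed_response":
            converged = True
            break
        if step < PARAM_TOL:
            converged = True
            break
    resid = y - mean_fn(theta)
    diag = FitDiagnostics(converged=converged, n_iter=it,
                          sse=float(resid @ resid),
                          message="" if converged else
                          "IRLS did not converge within iteration limit")
    return CARModel(a0=float(theta[0]), a1=float(theta[1]),
                    a2=float(theta[2]) if bivariate else None,
                    response=response, weighting=weights, diagnostics=diag)


def fit_car(records: list[TreeRecord], response, *, form: str = "univariate",
            weights: WeightSpec | None = None, init=None) -> CARModel:
    """Fit a CAR model to tree records.

    ``response`` is a component label (stem/branch/leaf/root/aboveground)
    or a callable record -> float (e.g. a carbon response).
    """
    if callable(response):
        y = np.array([response(r) for r in records], dtype=float)
        label = getattr(response, "__name__", "custom")
    else:
        y = component_array(records, response)
        label = response
    dbh, height = size_arrays(records)
    return fit_car_xy(dbh, height, y, form=form, weights=weights,
                      init=init, response=label)
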
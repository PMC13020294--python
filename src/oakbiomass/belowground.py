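"""Root-shoot ratio models and error propagation for belowground biomass.

Belowground biomass is expensive to measure, so only a subsample of
trees is excavated.  The belowground model is therefore expressed as a
DBH-dependent ratio applied to the aboveground model,

    M_root = (b0 * DBH^b1 [* H^b2]) * M_aboveground,

and both equations (aboveground CAR + root ratio) are estimated jointly
by SUR on the root subsample, sharing the aboveground parameters.  The
ratio form makes the belowground prediction compatible with *any*
aboveground source (independent fit or aggregation-system total).

Because the ratio model is calibrated on a small subsample while the
aboveground model uses the full sample, the mean prediction error of the
combined estimate shrinks with the root/shoot correlation:

    MPE_adjusted = sqrt(1 - (1 - 1/K) * r^2) * MPE_subsample

where K is the aboveground-to-belowground sample-size ratio and r the
correlation between observed belowground and aboveground biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .allometric import CARModel, FitDiagnostics, WeightSpec
from .data import TreeRecord, component_array, size_arrays
from .systems import nsur_core


@dataclass(frozen=True)
class RootShootModel:
    """Ratio-form belowground model tied to an aboveground CAR model."""
    b0: float
    b1: float
    b2: float | None = None          # present iff bivariate
    aboveground: CARModel | None = None
    diagnostics: FitDiagnostics | None = None

    @property
    def form(self) -> str:
        return "univariate" if self.b2 is None else "bivariate"

    @property
    def n_params(self) -> int:
        return 2 if self.b2 is None else 3

    def ratio(self, dbh, height=None):
        """The root:shoot ratio R = b0 * DBH^b1 [* H^b2]."""
        dbh = np.asarray(dbh, dtype=float)
        out = self.b0 * dbh ** self.b1
        if self.b2 is not None:
            if height is None:
                raise ValueError("bivariate ratio model requires height")
            out = out * np.asarray(height, dtype=float) ** self.b2
        return out


@dataclass(frozen=True)
class MpeAdjustment:
    """Inputs and result of the subsample error-propagation adjustment."""
    K: float
    r: float
    mpe_small: float
    mpe_adjusted: float


def fit_root_shoot(records: list[TreeRecord], *, form: str = "univariate",
                   agb_form: str = "univariate",
                   response=None, agb_response=None,
                   weights: WeightSpec | None = None,
                   sigma=None) -> RootShootModel:
    """Joint SUR fit of the aboveground CAR model and the root ratio model
    on the root-excavated subsample.

    ``response``/``agb_response`` optionally replace the default
    root/aboveground biomass responses (e.g. carbon-converted masses),
    as callables record -> float.
    """
    weights = weights or WeightSpec()
    sub = [r for r in records if r.has_root]
    if len(sub) < 5:
        raise ValueError(f"need >= 5 root-excavated records, got {len(sub)}")
    dbh, height = size_arrays(sub)
    y_root = (np.array([response(r) for r in sub], dtype=float)
              if response else component_array(sub, "root"))
    y_agb = (np.array([agb_response(r) for r in sub], dtype=float)
             if agb_response else component_array(sub, "aboveground"))
    agb_biv = agb_form == "bivariate"
    ratio_biv = form == "bivariate"
    n_agb = 3 if agb_biv else 2
    n_ratio = 3 if ratio_biv else 2

    # log-scale starts: aboveground from log-log OLS, ratio from the
    # observed root/aboveground ratios.
    Xa = [np.ones_like(dbh), np.log(dbh)] + ([np.log(height)] if agb_biv else [])
    ba, *_ = np.linalg.lstsq(np.column_stack(Xa),
                             np.log(np.maximum(y_agb, 1e-9)), rcond=None)
    obs_ratio = np.maximum(y_root, 1e-9) / np.maximum(y_agb, 1e-9)
    Xr = [np.ones_like(dbh), np.log(dbh)] + ([np.log(height)] if ratio_biv else [])
    br, *_ = np.linalg.lstsq(np.column_stack(Xr), np.log(obs_ratio), rcond=None)
    theta0 = np.concatenate([[np.exp(ba[0])], ba[1:], [np.exp(br[0])], br[1:]])

    def predict(theta):
        pa, pr = theta[:n_agb], theta[n_agb:]
        agb = pa[0] * dbh ** pa[1]
        if agb_biv:
            agb = agb * height ** pa[2]
        ratio = pr[0] * dbh ** pr[1]
        if ratio_biv:
            ratio = ratio * height ** pr[2]
        return np.column_stack([agb, ratio * agb])

    y_mat = np.column_stack([y_agb, y_root])
    theta, s_mat, diag = nsur_core(y_mat, predict, theta0,
                                   weight_power=weights.power, sigma=sigma)
    pa, pr = theta[:n_agb], theta[n_agb:]
    agb_model = CARModel(a0=float(pa[0]), a1=float(pa[1]),
                         a2=float(pa[2]) if agb_biv else None,
                         response="aboveground", weighting=weights,
                         diagnostics=diag)
    model = RootShootModel(b0=float(pr[0]), b1=float(pr[1]),
                           b2=float(pr[2]) if ratio_biv else None,
                           aboveground=agb_model, diagnostics=diag)
    if np.any(model.ratio(dbh, height if ratio_biv else None) < 0):
        import warnings
        warnings.warn("fitted root:shoot ratio is negative on part of the "
                      "training support", stacklevel=2)
    return model


def predict_root(model: RootShootModel, dbh, height=None,
                 aboveground_prediction=None):
    """Belowground biomass = ratio(dbh[, height]) x aboveground prediction.

    ``aboveground_prediction`` may come from any aboveground source
    (independent model or aggregation-system total); if omitted, the
    model's own paired aboveground fit is used.
    """
    if aboveground_prediction is None:
        if model.aboveground is None:
            raise ValueError("no aboveground prediction supplied or paired")
        aboveground_prediction = model.aboveground.predict(
            dbh, height if model.aboveground.form == "bivariate" else None)
    agb = np.asarray(aboveground_prediction, dtype=float)
    if np.any(agb < 0):
        raise ValueError("aboveground prediction must be >= 0")
    return model.ratio(dbh, height if model.b2 is not None else None) * agb


def adjust_mpe(K: float, r: float, mpe_small: float) -> float:
    """Propagate the subsample MPE through the large-sample aboveground
    model: sqrt(1 - (1 - 1/K) * r^2) * MPE."""
    if K < 1:
        raise ValueError("K must be >= 1 (aboveground sample is the larger)")
    if abs(r) > 1:
        raise ValueError("|r| must be <= 1")
    if mpe_small < 0:
        raise ValueError("MPE must be >= 0")
    return math.sqrt(1.0 - (1.0 - 1.0 / K) * r * r) * mpe_small


def mpe_adjustment(records: list[TreeRecord], mpe_small: float) -> MpeAdjustment:
    """Compute K and r from the data and apply :func:`adjust_mpe`.

    K = n_trees / n_root-excavated; r = Pearson correlation between
    observed root and aboveground biomass on the root subsample.
    """
    sub = [r for r in records if r.has_root]
    if len(sub) < 3:
        raise ValueError("need >= 3 root-excavated records")
    K = len(records) / len(sub)
    root = component_array(sub, "root")
    agb = component_array(sub, "aboveground")
    r = float(np.corrcoef(root, agb)[0, 1])
    return MpeAdjustment(K=K, r=r, mpe_small=mpe_small,
                         mpe_adjusted=adjust_mpe(K, r, mpe_small))
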
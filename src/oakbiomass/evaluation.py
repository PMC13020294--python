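"""Model evaluation statistics and jackknife (leave-one-out) validation.

Four statistics summarize fit quality of a biomass or carbon model:

* adjusted coefficient of determination
  ``R2_adj = 1 - (1 - R2) (N - 1) / (N - P - 1)``
* standard error of estimate ``SEE = sqrt(SSE / (N - P))`` (response units)
* total relative error ``TRE = 100 * sum(y - yhat) / sum(yhat)`` (%)
* mean prediction error ``MPE = 100 * t_alpha * (SEE / ybar) / sqrt(N)`` (%),
  with ``t_alpha`` the two-sided Student-t quantile at N - P degrees of
  freedom (95% by default).

The jackknife variant refits the model N times leaving one tree out,
predicts the held-out tree, and computes the same statistics on the
vector of out-of-sample predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats


@dataclass(frozen=True)
class EvaluationStats:
    r2: float
    r2_adj: float
    see: float          # response units
    tre: float          # %
    mpe: float          # %
    n: int
    p: int
    y_bar: float
    t_alpha: float
    alpha: float = 0.05

    def as_dict(self) -> dict:
        return {"r2": self.r2, "r2_adj": self.r2_adj, "see": self.see,
                "tre": self.tre, "mpe": self.mpe, "n": self.n, "p": self.p,
                "y_bar": self.y_bar, "t_alpha": self.t_alpha,
                "alpha": self.alpha}


def mpe_from_summary(see: float, y_bar: float, n: int, p: int,
                     alpha: float = 0.05) -> float:
    """MPE (%) from summary quantities alone; t at n - p df, two-sided."""
    if n <= p:
        raise ValueError("need n > p degrees of freedom")
    t = float(sstats.t.ppf(1.0 - alpha / 2.0, n - p))
    return 100.0 * t * (see / y_bar) / np.sqrt(n)


def evaluate(observed, predicted, p: int, alpha: float = 0.05) -> EvaluationStats:
    """Compute the four statistics for one response vector."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted must have equal length")
    n = y.size
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    sum_yhat = float(np.sum(yhat))
    if sum_yhat == 0:
        raise ValueError("sum of predictions is zero; TRE undefined")
    resid = y - yhat
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else float("-inf"))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    see = float(np.sqrt(sse / (n - p)))
    tre = 100.0 * float(np.sum(resid)) / sum_yhat
    y_bar = float(y.mean())
    t = float(sstats.t.ppf(1.0 - alpha / 2.0, n - p))
    mpe = 100.0 * t * (see / y_bar) / np.sqrt(n)
    return EvaluationStats(r2=r2, r2_adj=r2_adj, see=see, tre=tre, mpe=mpe,
                           n=n, p=p, y_bar=y_bar, t_alpha=t, alpha=alpha)


def jackknife_evaluate(records: list, fit_fn, predict_fn, response_fn,
                       p: int, alpha: float = 0.05) -> EvaluationStats:
    """Leave-one-out evaluation.

    ``fit_fn(subset) -> model`` refits on each delete-one subset;
    ``predict_fn(model, record) -> float`` predicts the held-out tree;
    ``response_fn(record) -> float`` extracts the observed value.
    Deterministic given a deterministic fitter.  A refit failure is
    re-raised citing the offending index.
    """
    y, yhat = [], []
    for i, rec in enumerate(records):
        subset = records[:i] + records[i + 1:]
        try:
            model = fit_fn(subset)
        except Exception as exc:
            raise RuntimeError(
                f"jackknife refit failed leaving out record {i} "
                f"(tree {getattr(rec, 'tree_id', i)}): {exc}") from exc
        y.append(response_fn(rec))
        yhat.append(float(predict_fn(model, rec)))
    return evaluate(np.array(y), np.array(yhat), p=p, alpha=alpha)


def jackknife_car(records: list, response: str, *, form: str = "univariate",
                  weights=None, alpha: float = 0.05) -> EvaluationStats:
    """Convenience jackknife for a single CAR model on tree records."""
    from .allometric import fit_car

    def fit_fn(subset):
        return fit_car(subset, response, form=form, weights=weights)

    def predict_fn(model, rec):
        return model.predict(rec.dbh, rec.height if form == "bivariate" else None)

    def response_fn(rec):
        from .data import component_array
        return float(component_array([rec], response)[0])

    p = 3 if form == "bivariate" else 2
    return jackknife_evaluate(records, fit_fn, predict_fn, response_fn,
                              p=p, alpha=alpha)
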
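"""Holdout prediction and skill scoring for fitted admission models.

Predictions are expected daily counts ``P_i = exp(X_i . beta_hat)`` on a
holdout period whose design columns match the training design.  Skill is
reported two ways:

* ``mse`` — mean squared error ``(1/n) sum (P_i - O_i)^2`` in squared
  counts; for a correctly specified Poisson model this converges to the
  mean of the daily variance, i.e. the mean expected count;
* ``mape`` — mean absolute percentage error
  ``(100/n) sum |P_i - O_i| / max(O_i, 1)``, the percentage-scale skill
  figure (the denominator floor keeps zero-count days finite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import PoissonFit

__all__ = ["ForecastResult", "predict", "score"]


@dataclass
class ForecastResult:
    """Holdout predictions with skill summaries."""

    predicted: np.ndarray
    observed: np.ndarray
    mse: float
    mape: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"predicted": self.predicted, "observed": self.observed})

    def summary(self) -> dict:
        return {"mse": self.mse, "mape": self.mape, "n": self.n}


def predict(fit: PoissonFit, X: pd.DataFrame) -> np.ndarray:
    """Expected admissions exp(X . beta) on a holdout design.

    ``X`` must carry exactly the training design's columns (order is
    reconciled by name); a mismatch raises listing the missing and extra
    columns.
    """
    missing = [c for c in fit.columns if c not in X.columns]
    extra = [c for c in X.columns if c not in fit.columns]
    if missing or extra:
        raise ValueError(
            f"holdout design mismatch: missing columns {missing}, extra {extra}"
        )
    mat = X[fit.columns].to_numpy(dtype=float)
    return np.exp(mat @ fit.beta)


def score(predicted, observed) -> ForecastResult:
    """Score a holdout forecast against observed counts."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: predicted {p.shape}, observed {o.shape}")
    if p.size < 1:
        raise ValueError("need at least one holdout day")
    mse = float(np.mean((p - o) ** 2))
    mape = float(100.0 * np.mean(np.abs(p - o) / np.maximum(o, 1.0)))
    return ForecastResult(predicted=p, observed=o, mse=mse, mape=mape, n=p.size)
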
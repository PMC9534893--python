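"""Model performance metrics and trait correlations.

R-squared is the squared Pearson product-moment correlation between the
observed and predicted series (so it is invariant to affine transforms
of the predictions, unlike the 1 - SSE/SST form, which is available as
``method="residual"``).  RMSE and MBE are reported on the original cm
scale; MBE = mean(observed - predicted), so a positive value means the
model under-predicts on average.  Mathematically RMSE >= |MBE| always
holds for a single series (Cauchy-Schwarz), so reported metric tables
can be screened for inconsistent entries.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import MetricError
from .preprocessing import DataSplit
from .synthetic import TRAITS


def _as_series(observed, predicted):
    y = np.asarray(observed, dtype=float).ravel()
    yhat = np.asarray(predicted, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise MetricError("observed and predicted lengths differ")
    return y, yhat


def r_squared(observed, predicted, method: str = "pearson") -> float:
    """Coefficient of determination.

    ``method="pearson"`` (default) returns the squared Pearson
    correlation; ``method="residual"`` returns 1 - SSE/SST.
    """
    y, yhat = _as_series(observed, predicted)
    if y.size < 2:
        raise MetricError("need at least 2 points")
    if np.ptp(y) == 0 or (method == "pearson" and np.ptp(yhat) == 0):
        raise MetricError("R^2 is undefined for a constant series")
    if method == "pearson":
        r = np.corrcoef(y, yhat)[0, 1]
        return float(r * r)
    if method == "residual":
        sse = float(np.sum((y - yhat) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - sse / sst
    raise MetricError(f"unknown R^2 method: {method}")


def rmse(observed, predicted) -> float:
    """Root mean square error, sqrt(mean((y - yhat)^2))."""
    y, yhat = _as_series(observed, predicted)
    if y.size < 1:
        raise MetricError("need at least 1 point")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def mbe(observed, predicted) -> float:
    """Mean bias error, mean(y - yhat)."""
    y, yhat = _as_series(observed, predicted)
    if y.size < 1:
        raise MetricError("need at least 1 point")
    return float(np.mean(y - yhat))


def evaluate_models(
    surrogates: Mapping[str, object],
    X: np.ndarray,
    Y: np.ndarray,
    split: DataSplit,
    trait_names: tuple[str, ...] = TRAITS,
    r2_method: str = "pearson",
) -> pd.DataFrame:
    """Metric report: model x subset (train/test) x trait.

    ``surrogates`` maps a model name to an object with
    ``predict_encoded``; metrics are computed on the original cm scale.
    """
    rows = []
    subsets = {"train": split.train_idx, "test": split.test_idx}
    for name, model in surrogates.items():
        for subset, idx in subsets.items():
            pred = model.predict_encoded(X[idx])
            for j, trait in enumerate(trait_names):
                rows.append(
                    {
                        "model": name,
                        "subset": subset,
                        "trait": trait,
                        "R2": r_squared(Y[idx, j], pred[:, j], method=r2_method),
                        "RMSE": rmse(Y[idx, j], pred[:, j]),
                        "MBE": mbe(Y[idx, j], pred[:, j]),
                        "n": int(len(idx)),
                    }
                )
    return pd.DataFrame(rows)


def select_best_model(report: pd.DataFrame) -> str:
    """Model with the lowest test RMSE averaged over traits."""
    test = report[report["subset"] == "test"]
    return test.groupby("model")["RMSE"].mean().idxmin()


def flag_inconsistent_metrics(report: pd.DataFrame, atol: float = 1e-9) -> pd.DataFrame:
    """Rows violating the necessary inequality RMSE >= |MBE|; any such
    row in an external table cannot describe a single prediction series."""
    return report[report["RMSE"] + atol < report["MBE"].abs()]


def trait_correlations(
    records: pd.DataFrame,
    cultivar: str | None = None,
    trait_names: tuple[str, ...] = TRAITS,
) -> pd.DataFrame:
    """Pearson correlation matrix of the traits, optionally restricted
    to one cultivar (symmetric, unit diagonal, entries in [-1, 1])."""
    frame = records if cultivar is None else records[records["cultivar"] == cultivar]
    if len(frame) < 3:
        raise MetricError("need at least 3 records for a correlation matrix")
    return frame.loc[:, list(trait_names)].corr(method="pearson")
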
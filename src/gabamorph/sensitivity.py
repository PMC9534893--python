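"""Variable importance via the variable sensitivity error (VSE) and ratio (VSR).

VSE is the model error (RMSE here) when one input variable is made
unavailable; VSR = VSE / full-model error.  A variable whose removal
hurts the model most gets the highest VSR and rank 1.  Errors are
assessed over *all* rows (training and testing pooled), per output
trait.

Two modes are provided:

* ``retrain_without`` (default): refit the model with the variable's
  column removed, same configuration and seed — the literal reading of
  "if that input variable is unavailable";
* ``mean_substitute``: keep the full model but replace the column by
  its training mean, a fast approximation.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .exceptions import MetricError, ParameterError
from .models import MLPConfig
from .surrogate import fit_surrogate
from .synthetic import INPUT_COLUMNS, TRAITS

MODES = ("retrain_without", "mean_substitute")


def surrogate_fitter(kind: str = "mlp", mlp_config: MLPConfig | None = None,
                     rbf_params: dict | None = None) -> Callable:
    """A fitter closure ``fit(X, Y, train_idx) -> surrogate`` with fixed
    model configuration, for use with :func:`sensitivity_analysis`."""

    def fit(X, Y, train_idx=None):
        return fit_surrogate(
            X, Y, train_idx=train_idx, kind=kind,
            mlp_config=mlp_config, rbf_params=rbf_params,
            input_names=tuple(f"x{i}" for i in range(np.asarray(X).shape[1])),
        )

    return fit


def _per_trait_rmse(pred: np.ndarray, Y: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((Y - pred) ** 2, axis=0))


def compute_vse(
    fitter: Callable,
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    variable: int,
    mode: str = "retrain_without",
    full_model=None,
) -> np.ndarray:
    """Per-trait RMSE over all rows with ``variable`` unavailable."""
    if mode not in MODES:
        raise ParameterError(f"mode must be one of {MODES}")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if not 0 <= variable < X.shape[1]:
        raise ParameterError(f"variable index {variable} out of range")
    if mode == "retrain_without":
        keep = [j for j in range(X.shape[1]) if j != variable]
        model = fitter(X[:, keep], Y, train_idx)
        pred = model.predict_encoded(X[:, keep])
    else:
        if full_model is None:
            full_model = fitter(X, Y, train_idx)
        Xs = X.copy()
        Xs[:, variable] = X[train_idx, variable].mean()
        pred = full_model.predict_encoded(Xs)
    return _per_trait_rmse(pred, Y)


def compute_vsr(vse: np.ndarray, full_error: np.ndarray) -> np.ndarray:
    """VSR = VSE / full-model error (elementwise)."""
    full_error = np.asarray(full_error, dtype=float)
    if np.any(full_error <= 0):
        raise MetricError("full-model error is zero; VSR is undefined")
    return np.asarray(vse, dtype=float) / full_error


def rank_inputs(vsr_by_variable: np.ndarray) -> np.ndarray:
    """Ranks 1..p by descending VSR; ties keep input-column order."""
    order = np.argsort(-np.asarray(vsr_by_variable, dtype=float), kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    return ranks


def sensitivity_analysis(
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray,
    fitter: Callable,
    var_names: Sequence[str] = INPUT_COLUMNS,
    trait_names: Sequence[str] = TRAITS,
    mode: str = "retrain_without",
) -> pd.DataFrame:
    """Full VSE/VSR/rank table, tidy: one row per (trait, variable).

    The full model is fitted on the training rows; errors are assessed
    over all rows.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if len(var_names) != X.shape[1] or len(trait_names) != Y.shape[1]:
        raise ParameterError("var_names / trait_names do not match the matrices")
    full_model = fitter(X, Y, train_idx)
    full_error = _per_trait_rmse(full_model.predict_encoded(X), Y)
    if np.any(full_error <= 0):
        raise MetricError("degenerate fit: full-model error is zero")

    vse = np.empty((X.shape[1], Y.shape[1]))
    for j in range(X.shape[1]):
        vse[j] = compute_vse(fitter, X, Y, train_idx, j, mode=mode, full_model=full_model)
    vsr = vse / full_error[None, :]

    rows = []
    for t, trait in enumerate(trait_names):
        ranks = rank_inputs(vsr[:, t])
        for j, var in enumerate(var_names):
            rows.append(
                {
                    "trait": trait,
                    "variable": var,
                    "VSE": vse[j, t],
                    "VSR": vsr[j, t],
                    "rank": int(ranks[j]),
                    "full_RMSE": full_error[t],
                    "mode": mode,
                    "n": int(X.shape[0]),
                }
            )
    return pd.DataFrame(rows)


def sensitivity_wide(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy table into the conventional layout: one block row
    per trait with VSR and rank sub-rows, variables as columns."""
    blocks = []
    for trait, grp in table.groupby("trait", sort=False):
        for item in ("VSR", "rank"):
            row = {"trait": trait, "item": item}
            row.update(dict(zip(grp["variable"], grp[item])))
            blocks.append(row)
    return pd.DataFrame(blocks)
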
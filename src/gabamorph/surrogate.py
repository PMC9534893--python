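"""The trait surrogate: encoding + standardization + network, bundled.

A :class:`TraitSurrogate` owns everything needed to map a raw factor
tuple (cultivar, stress regime, GABA dose, day) to the five predicted
traits on the original cm scale, and can be serialized to JSON so the
sensitivity and optimization stages reload it bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ParameterError
from .models import MLPConfig, MLPNetwork, RBFNetwork, train_mlp, train_rbf
from .preprocessing import (
    DataSplit,
    FeatureEncoding,
    StandardizationParams,
    zscore_apply,
    zscore_fit,
    zscore_invert,
)
from .synthetic import INPUT_COLUMNS, TRAITS


@dataclass
class TraitSurrogate:
    """A trained regressor with its preprocessing attached."""

    kind: str  # "mlp" or "rbf"
    net: object
    x_params: StandardizationParams
    y_params: StandardizationParams
    input_names: tuple[str, ...] = INPUT_COLUMNS
    trait_names: tuple[str, ...] = TRAITS
    encoding: FeatureEncoding | None = None
    y_train_max: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    # -- prediction -------------------------------------------------------
    def predict_encoded(self, X: np.ndarray) -> np.ndarray:
        """Predict traits (original scale) from raw encoded inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = zscore_apply(X, self.x_params)
        return zscore_invert(self.net.forward(z), self.y_params)

    def predict_traits(self, cultivar, stress, gaba_mM, day) -> dict:
        """Predict the five traits for one raw factor tuple."""
        if self.encoding is None:
            raise ParameterError("surrogate has no factor encoding attached")
        row = self.encoding.encode_row(cultivar, stress, gaba_mM, day)
        pred = self.predict_encoded(row[None, :])[0]
        return dict(zip(self.trait_names, pred.tolist()))

    # -- serialization ----------------------------------------------------
    def to_jsonable(self) -> dict:
        if self.kind == "mlp":
            net_payload = {
                "weights": [w.tolist() for w in self.net.weights],
                "biases": [b.tolist() for b in self.net.biases],
            }
        elif self.kind == "rbf":
            net_payload = {
                "centers": self.net.centers.tolist(),
                "widths": self.net.widths.tolist(),
                "weights": self.net.weights.tolist(),
            }
        else:
            raise ParameterError(f"unknown surrogate kind: {self.kind}")
        return {
            "kind": self.kind,
            "net": net_payload,
            "x_params": self.x_params.to_jsonable(),
            "y_params": self.y_params.to_jsonable(),
            "input_names": list(self.input_names),
            "trait_names": list(self.trait_names),
            "encoding": None
            if self.encoding is None
            else {
                "cultivar_codes": self.encoding.cultivar_codes,
                "stress_codes": self.encoding.stress_codes,
                "one_hot": self.encoding.one_hot,
            },
            "y_train_max": None if self.y_train_max is None else self.y_train_max.tolist(),
            "meta": self.meta,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "TraitSurrogate":
        if obj["kind"] == "mlp":
            net = MLPNetwork(
                [np.asarray(w, float) for w in obj["net"]["weights"]],
                [np.asarray(b, float) for b in obj["net"]["biases"]],
            )
        elif obj["kind"] == "rbf":
            net = RBFNetwork(
                np.asarray(obj["net"]["centers"], float),
                np.asarray(obj["net"]["widths"], float),
                np.asarray(obj["net"]["weights"], float),
            )
        else:
            raise ParameterError(f"unknown surrogate kind: {obj['kind']}")
        enc = obj.get("encoding")
        return cls(
            kind=obj["kind"],
            net=net,
            x_params=StandardizationParams.from_jsonable(obj["x_params"]),
            y_params=StandardizationParams.from_jsonable(obj["y_params"]),
            input_names=tuple(obj["input_names"]),
            trait_names=tuple(obj["trait_names"]),
            encoding=None
            if enc is None
            else FeatureEncoding(
                cultivar_codes=enc["cultivar_codes"],
                stress_codes=enc["stress_codes"],
                one_hot=enc["one_hot"],
            ),
            y_train_max=None
            if obj.get("y_train_max") is None
            else np.asarray(obj["y_train_max"], float),
            meta=obj.get("meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_jsonable()))

    @classmethod
    def load(cls, path: str | Path) -> "TraitSurrogate":
        return cls.from_jsonable(json.loads(Path(path).read_text()))


def fit_surrogate(
    X: np.ndarray,
    Y: np.ndarray,
    train_idx: np.ndarray | None = None,
    kind: str = "mlp",
    mlp_config: MLPConfig | None = None,
    rbf_params: dict | None = None,
    encoding: FeatureEncoding | None = None,
    input_names: tuple[str, ...] | None = None,
    trait_names: tuple[str, ...] = TRAITS,
) -> TraitSurrogate:
    """Standardize on the training rows, train the requested network,
    and return the bundled surrogate.

    ``train_idx`` defaults to all rows.  Standardization parameters are
    fitted on the training rows only, so there is no leakage from the
    test subset.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if train_idx is None:
        train_idx = np.arange(X.shape[0])
    if input_names is None:
        input_names = (
            encoding.input_names if encoding is not None else INPUT_COLUMNS[: X.shape[1]]
        )
    x_params = zscore_fit(X[train_idx], column_names=list(input_names))
    y_params = zscore_fit(Y[train_idx], column_names=list(trait_names))
    Xz = zscore_apply(X[train_idx], x_params)
    Yz = zscore_apply(Y[train_idx], y_params)
    if kind == "mlp":
        net = train_mlp(Xz, Yz, mlp_config)
        meta = {
            "final_objective": net.history[-1] if net.history else None,
            "iterations": len(net.history),
            "l2": getattr(net, "final_l2", None),
        }
    elif kind == "rbf":
        net = train_rbf(Xz, Yz, **(rbf_params or {}))
        meta = {"k": net.k}
    else:
        raise ParameterError(f"unknown surrogate kind: {kind}")
    meta["n_train"] = int(len(train_idx))
    return TraitSurrogate(
        kind=kind,
        net=net,
        x_params=x_params,
        y_params=y_params,
        input_names=tuple(input_names),
        trait_names=tuple(trait_names),
        encoding=encoding,
        y_train_max=Y[train_idx].max(axis=0),
        meta=meta,
    )
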
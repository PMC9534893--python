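"""Factor encoding, z-score standardization, and the train/test split.

The four inputs are encoded as a fixed-order numeric matrix
(cultivar, stress, gaba_mM, day); the five traits form the target
matrix.  Both are z-scored with parameters fitted on the training rows
only, and the data are split 80/20 at random.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DegenerateColumnError, EncodingError, ParameterError
from .synthetic import INPUT_COLUMNS, TRAITS

DEFAULT_CULTIVAR_CODES = {"Atabaki": 1, "Rabab": 2}
DEFAULT_STRESS_CODES = {"control": 0, "drought": 1, "salt": 2, "combined": 3}


@dataclass(frozen=True)
class FeatureEncoding:
    """Injective categorical-to-code maps; GABA dose and day pass through.

    With ``one_hot=True`` each categorical expands to indicator columns
    (ordered by code) instead of a single ordinal column.
    """

    cultivar_codes: dict = field(default_factory=lambda: dict(DEFAULT_CULTIVAR_CODES))
    stress_codes: dict = field(default_factory=lambda: dict(DEFAULT_STRESS_CODES))
    one_hot: bool = False

    def __post_init__(self) -> None:
        for name, codes in (("cultivar", self.cultivar_codes), ("stress", self.stress_codes)):
            if len(set(codes.values())) != len(codes):
                raise ParameterError(f"{name} codes are not injective: {codes}")

    @property
    def input_names(self) -> tuple[str, ...]:
        if not self.one_hot:
            return INPUT_COLUMNS
        return tuple(
            [f"cultivar={c}" for c in sorted(self.cultivar_codes, key=self.cultivar_codes.get)]
            + [f"stress={s}" for s in sorted(self.stress_codes, key=self.stress_codes.get)]
            + ["gaba_mM", "day"]
        )

    def _code(self, table: dict, kind: str, level) -> float:
        try:
            return float(table[level])
        except KeyError:
            raise EncodingError(f"unknown {kind} level: {level!r}") from None

    def encode_row(self, cultivar, stress, gaba_mM, day) -> np.ndarray:
        if not self.one_hot:
            return np.array(
                [
                    self._code(self.cultivar_codes, "cultivar", cultivar),
                    self._code(self.stress_codes, "stress", stress),
                    float(gaba_mM),
                    float(day),
                ]
            )
        self._code(self.cultivar_codes, "cultivar", cultivar)
        self._code(self.stress_codes, "stress", stress)
        cult = [float(cultivar == c) for c in sorted(self.cultivar_codes, key=self.cultivar_codes.get)]
        stre = [float(stress == s) for s in sorted(self.stress_codes, key=self.stress_codes.get)]
        return np.array(cult + stre + [float(gaba_mM), float(day)])

    def decode_row(self, row) -> tuple:
        row = np.asarray(row, dtype=float)
        if not self.one_hot:
            inv_c = {v: k for k, v in self.cultivar_codes.items()}
            inv_s = {v: k for k, v in self.stress_codes.items()}
            try:
                return (inv_c[row[0]], inv_s[row[1]], float(row[2]), float(row[3]))
            except KeyError as exc:
                raise EncodingError(f"unknown code: {exc}") from None
        nc = len(self.cultivar_codes)
        ns = len(self.stress_codes)
        cultivars = sorted(self.cultivar_codes, key=self.cultivar_codes.get)
        stresses = sorted(self.stress_codes, key=self.stress_codes.get)
        return (
            cultivars[int(np.argmax(row[:nc]))],
            stresses[int(np.argmax(row[nc:nc + ns]))],
            float(row[nc + ns]),
            float(row[nc + ns + 1]),
        )


def encode_records(
    records: pd.DataFrame,
    encoding: FeatureEncoding | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode a morphology data frame into (X, Y) matrices.

    X columns follow ``encoding.input_names``; Y columns follow
    :data:`TRAITS` and stay on the original cm scale.
    """
    encoding = encoding or FeatureEncoding()
    X = np.vstack(
        [
            encoding.encode_row(r.cultivar, r.stress, r.gaba_mM, r.day)
            for r in records.itertuples()
        ]
    )
    Y = records.loc[:, list(TRAITS)].to_numpy(dtype=float)
    return X, Y


# ---------------------------------------------------------------------------
# z-score standardization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationParams:
    """Per-column mean and standard deviation (sample sd, n-1)."""

    mean: np.ndarray
    sd: np.ndarray

    def to_jsonable(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_jsonable(cls, obj: dict) -> "StandardizationParams":
        return cls(mean=np.asarray(obj["mean"], float), sd=np.asarray(obj["sd"], float))


def zscore_fit(matrix: np.ndarray, column_names=None) -> StandardizationParams:
    """Fit per-column mean and sample standard deviation.

    Raises :class:`DegenerateColumnError` naming any zero-variance
    column.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with at least 2 rows")
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        names = (
            [column_names[i] for i in bad] if column_names is not None else bad.tolist()
        )
        raise DegenerateColumnError(f"zero-variance column(s): {names}")
    return StandardizationParams(mean=mean, sd=sd)


def zscore_apply(matrix: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return (np.asarray(matrix, dtype=float) - params.mean) / params.sd


def zscore_invert(matrix: np.ndarray, params: StandardizationParams) -> np.ndarray:
    return np.asarray(matrix, dtype=float) * params.sd + params.mean


# ---------------------------------------------------------------------------
# train/test split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DataSplit:
    """Disjoint, exhaustive train/test row indices."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    train_frac: float
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "train_idx": self.train_idx.tolist(),
            "test_idx": self.test_idx.tolist(),
            "train_frac": self.train_frac,
            "seed": self.seed,
        }

    @classmethod
    def from_jsonable(cls, obj: dict) -> "DataSplit":
        return cls(
            train_idx=np.asarray(obj["train_idx"], int),
            test_idx=np.asarray(obj["test_idx"], int),
            train_frac=float(obj["train_frac"]),
            seed=int(obj["seed"]),
        )


def split_data(n: int, train_frac: float = 0.8, seed: int = 0) -> DataSplit:
    """Random shuffle split; train size = round(train_frac * n)
    (ties round half to even, so 80% of 512 gives 410 training rows)."""
    if not 0.0 < train_frac < 1.0:
        raise ParameterError("train_frac must be in (0, 1)")
    if n < 5:
        raise ParameterError("need at least 5 rows to split")
    n_train = int(round(train_frac * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    return DataSplit(
        train_idx=np.sort(perm[:n_train]),
        test_idx=np.sort(perm[n_train:]),
        train_frac=train_frac,
        seed=seed,
    )
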
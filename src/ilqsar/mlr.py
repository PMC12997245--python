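"""Multiple linear regression core: the QSAR model is

    Log 1/EC50 = a1*(CatDes)1 + ... + an*(CatDes)n
               + b1*(AniDes)1 + ... + bm*(AniDes)m + c

with named sigma-profile descriptors.  Fitting is ordinary least squares via
a numerically stable (SVD) solver; the published 11-descriptor model ships
as a packaged resource.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable, DescriptorVector


@dataclass
class MLRModel:
    descriptor_names: list[str]
    coefficients: dict[str, float]
    intercept: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.coefficients) != set(self.descriptor_names):
            raise ValueError("coefficient keys must equal descriptor_names")
        vals = list(self.coefficients.values()) + [self.intercept]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite model parameters")

    @property
    def p(self) -> int:
        return len(self.descriptor_names)

    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[n] for n in self.descriptor_names])

    def to_json(self, path) -> None:
        payload = {
            "descriptor_names": self.descriptor_names,
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "MLRModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["descriptor_names"], d["coefficients"], d["intercept"], d.get("meta", {}))


def fit_ols(table: DescriptorTable, names: list[str] | None = None,
            response: pd.Series | None = None) -> MLRModel:
    """Least-squares fit of the response on the named descriptor columns.

    The intercept is always included.  Requires n >= p + 2 rows and a
    full-rank design; rank deficiency reports the offending columns.
    """
    names = table.descriptor_names if names is None else list(names)
    y_ser = table.response if response is None else response
    if y_ser is None:
        raise ValueError("no response available to fit")
    ids = y_ser.index.intersection(table.data.index)
    sub = DescriptorTable(data=table.data.loc[ids], response=None, set_label=None)
    X = sub.matrix(names)
    y = y_ser.loc[ids].to_numpy(dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least p+2={p + 2} rows, got {n}")
    Z = np.column_stack([np.ones(n), X])
    rank = np.linalg.matrix_rank(Z)
    if rank < p + 1:
        bad = _collinear_columns(X, names)
        raise ValueError(f"rank-deficient design (rank {rank} < {p + 1}); "
                         f"collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    return MLRModel(
        descriptor_names=names,
        coefficients=dict(zip(names, map(float, beta[1:]))),
        intercept=float(beta[0]),
        meta={"n_train": n, "training_ids": list(map(str, ids))},
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose removal restores full rank — a readable diagnostic."""
    n = X.shape[0]
    full = np.linalg.matrix_rank(np.column_stack([np.ones(n), X]))
    bad = []
    for j, name in enumerate(names):
        rest = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(n), rest])) == full:
            bad.append(name)
    return bad


def predict(model: MLRModel, rows) -> pd.Series:
    """Apply the model: yhat = sum(coef * descriptor) + intercept.

    *rows* may be a DescriptorTable, DescriptorVector, DataFrame or Series.
    Every model descriptor must be present; extra descriptors are ignored.
    """
    if isinstance(rows, DescriptorVector):
        df = rows.as_series().to_frame().T
    elif isinstance(rows, DescriptorTable):
        df = rows.data
    elif isinstance(rows, pd.Series):
        df = rows.to_frame().T
    else:
        df = pd.DataFrame(rows)
    missing = [n for n in model.descriptor_names if n not in df.columns]
    if missing:
        raise KeyError(f"missing descriptor(s): {missing}")
    X = df[model.descriptor_names].to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite descriptor values")
    yhat = X @ model.coef_vector() + model.intercept
    return pd.Series(yhat, index=df.index, name="log_inv_ec50_pred")


def published_model() -> MLRModel:
    """The published 11-descriptor sigma-profile model (8 cationic +
    3 anionic bins, coefficients as printed at 4 decimal places)."""
    ref = resources.files("ilqsar.data").joinpath("eq13.json")
    d = json.loads(ref.read_text())
    return MLRModel(d["descriptor_names"], d["coefficients"], d["intercept"], d.get("meta", {}))
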
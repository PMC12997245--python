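"""Applicability-domain analysis: leverages, standardized residuals and the
Williams plot.

A prediction is considered reliable when the compound sits inside the
training set's descriptor space (leverage h_i below the critical
h* = 3(p+1)/n) and its standardized residual is within +/-3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .mlr import MLRModel, predict

SDR_LIMIT = 3.0


@dataclass
class ADReport:
    """Per-compound Williams-plot table plus the global leverage threshold."""

    table: pd.DataFrame  # il_id index; set, leverage, sdr, h_flag, sdr_flag
    h_star: float

    @property
    def outliers(self) -> pd.DataFrame:
        return self.table[self.table.h_flag | self.table.sdr_flag]

    def summary(self) -> dict:
        return {
            "h_star": self.h_star,
            "n_high_leverage": int(self.table.h_flag.sum()),
            "n_response_outliers": int(self.table.sdr_flag.sum()),
            "n_outliers": int((self.table.h_flag | self.table.sdr_flag).sum()),
        }

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="il_id")


def h_star(p: int, n: int) -> float:
    """Critical leverage 3(p+1)/n for p descriptors and n training rows."""
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    return 3.0 * (p + 1) / n


def leverages(train: pd.DataFrame | np.ndarray,
              query: pd.DataFrame | np.ndarray | None = None) -> np.ndarray:
    """Hat-matrix leverages h_i = z_i (Z'Z)^-1 z_i' with an intercept column.

    *train* defines Z; *query* rows (default: the training rows themselves)
    are projected onto it.  Training leverages sum to p+1.
    """
    Xt = np.asarray(train, dtype=float)
    Xq = Xt if query is None else np.asarray(query, dtype=float)
    if Xq.shape[1] != Xt.shape[1]:
        raise ValueError("query and training descriptor dimensions differ")
    n = Xt.shape[0]
    Z = np.column_stack([np.ones(n), Xt])
    q = Z.shape[1]
    if np.linalg.matrix_rank(Z) < q:
        raise ValueError("rank-deficient training design")
    Zq = np.column_stack([np.ones(Xq.shape[0]), Xq])
    # h = rowwise z (Z'Z)^-1 z' via Cholesky solve, no explicit inverse
    G = Z.T @ Z
    sol = np.linalg.solve(G, Zq.T)
    return np.einsum("ij,ji->i", Zq, sol)


def standardized_residuals(y_exp, y_pre, reference_rmse: float) -> np.ndarray:
    """Residuals scaled by a reference RMSE (taken from the training set so
    train and test live on one Williams plot)."""
    if reference_rmse <= 0:
        raise ValueError("reference_rmse must be positive")
    y = np.asarray(y_exp, dtype=float)
    yh = np.asarray(y_pre, dtype=float)
    return (y - yh) / reference_rmse


def williams(train: DescriptorTable, test: DescriptorTable | None,
             model: MLRModel) -> ADReport:
    """Leverage / standardized-residual table for training and test sets.

    Flags structural outliers (h > h* = 3(p+1)/n_train) and response
    outliers (|SDR| > 3); the SDR scale is the training RMSE.
    """
    names = model.descriptor_names
    Xtr = train.data[names]
    ytr = train.response.loc[Xtr.index].to_numpy(dtype=float)
    yhat_tr = predict(model, Xtr).to_numpy()
    train_rmse = float(np.sqrt(((ytr - yhat_tr) ** 2).mean()))

    blocks = [("train", Xtr, ytr, yhat_tr)]
    if test is not None and len(test.data):
        Xte = test.data[names]
        yte = test.response.loc[Xte.index].to_numpy(dtype=float)
        blocks.append(("test", Xte, yte, predict(model, Xte).to_numpy()))

    hs = h_star(len(names), len(Xtr))
    frames = []
    for label, X, y, yh in blocks:
        h = leverages(Xtr, X)
        sdr = standardized_residuals(y, yh, train_rmse)
        frames.append(pd.DataFrame({
            "set": label, "leverage": h, "sdr": sdr,
            "h_flag": h > hs, "sdr_flag": np.abs(sdr) > SDR_LIMIT,
        }, index=X.index))
    return ADReport(table=pd.concat(frames), h_star=hs)
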
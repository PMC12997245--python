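"""Internal and external validation statistics for MLR-QSAR models.

Covers the goodness-of-fit block (R2, adjusted R2, Fisher F, standard
deviation of residuals S, RMSE, AAD, %AARD), leave-one-out and
leave-many-out cross-validation (Q2), Y-scrambling, and the external
predictivity battery (Lin's concordance correlation coefficient, Q2F1,
Q2F2, Q2F3 and the r2m through-origin metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .mlr import MLRModel, fit_ols, predict


@dataclass
class MetricReport:
    """Goodness-of-fit statistics for n observations and p descriptors.

    S is the residual standard deviation with n - p - 1 degrees of freedom;
    RMSE divides by n, so S = RMSE * sqrt(n / (n - p - 1)).  %AARD uses
    |y_exp| in the denominator so it stays positive for negative responses.
    """

    n: int
    p: int
    r2: float
    r2_adj: float | None
    fisher_f: float | None
    s: float | None
    rmse: float
    aad: float
    aard_pct: float
    q2_loo: float | None = None
    q2_lmo: float | None = None


@dataclass
class ExternalReport:
    ccc: float
    q2_f1: float
    q2_f2: float
    q2_f3: float
    r2m_avg: float
    r2m_delta: float


@dataclass
class ScrambleResult:
    n_iterations: int
    seed: int
    r2_values: list[float] = field(default_factory=list)
    q2_values: list[float] = field(default_factory=list)

    @property
    def mean_r2(self) -> float | None:
        return float(np.mean(self.r2_values)) if self.r2_values else None

    @property
    def mean_q2(self) -> float | None:
        return float(np.mean(self.q2_values)) if self.q2_values else None


def regression_metrics(y_exp, y_pre, p: int) -> MetricReport:
    """Goodness-of-fit block for experimental vs predicted responses."""
    y = np.asarray(y_exp, dtype=float)
    yh = np.asarray(y_pre, dtype=float)
    if y.shape != yh.shape or y.ndim != 1:
        raise ValueError("y_exp and y_pre must be 1-d and the same length")
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if p < 1:
        raise ValueError("p must be >= 1")
    sstot = float(((y - y.mean()) ** 2).sum())
    if sstot == 0:
        raise ValueError("y_exp has zero variance")
    ssres = float(((y - yh) ** 2).sum())
    r2 = 1.0 - ssres / sstot
    rmse = float(np.sqrt(ssres / n))
    aad = float(np.abs(y - yh).mean())
    # undefined (inf/nan) when any y_exp is exactly 0
    with np.errstate(divide="ignore", invalid="ignore"):
        aard = float((np.abs(y - yh) / np.abs(y)).mean() * 100.0)
    dof = n - p - 1
    if dof < 1:
        r2_adj = fisher = s = None
    else:
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
        ssreg = float(((yh - y.mean()) ** 2).sum())
        fisher = (ssreg / p) / (ssres / dof) if ssres > 0 else np.inf
        s = float(np.sqrt(ssres / dof))
    return MetricReport(n=n, p=p, r2=r2, r2_adj=r2_adj, fisher_f=fisher,
                        s=s, rmse=rmse, aad=aad, aard_pct=aard)


# ---------------------------------------------------------------------------
# cross-validation

def _design(table: DescriptorTable, names: list[str]):
    ids = table.response.index.intersection(table.data.index)
    X = table.data.loc[ids, list(names)].to_numpy(dtype=float)
    y = table.response.loc[ids].to_numpy(dtype=float)
    return ids, np.column_stack([np.ones(len(y)), X]), y


def loo_predictions(table: DescriptorTable, names: list[str]) -> pd.Series:
    """Leave-one-out cross-validated predictions via the PRESS shortcut.

    For OLS the held-out prediction is available in closed form from the
    full-sample fit: e_cv_i = e_i / (1 - h_ii) with h the hat-matrix
    diagonal, which equals refitting with row i removed.
    """
    ids, Z, y = _design(table, names)
    n, q = Z.shape
    if n < q + 2:
        raise ValueError(f"need n >= p+3 rows for LOO, got {n}")
    Q, R = np.linalg.qr(Z)
    if np.linalg.matrix_rank(R) < q:
        raise ValueError("rank-deficient design in cross-validation")
    beta = np.linalg.solve(R, Q.T @ y)
    resid = y - Z @ beta
    h = (Q ** 2).sum(axis=1)
    cv_resid = resid / (1.0 - h)
    return pd.Series(y - cv_resid, index=ids, name="loo_pred")


def q2_from_predictions(y_exp: np.ndarray, y_cv: np.ndarray) -> float:
    """Q2 = 1 - PRESS / SStot about the full-sample mean of y_exp."""
    y = np.asarray(y_exp, dtype=float)
    return float(1.0 - ((y - y_cv) ** 2).sum() / ((y - y.mean()) ** 2).sum())


def cross_validate(table: DescriptorTable, names: list[str], scheme: str = "LOO",
                   frac: float = 0.2, iterations: int = 1000,
                   seed: int | None = None) -> tuple[float, pd.Series | None]:
    """Cross-validated Q2 under leave-one-out or leave-many-out resampling.

    LOO returns (Q2, per-compound CV predictions).  LMO averages Q2 over
    random subsamplings that each hold out round(frac * n) rows; its
    per-fold predictions are not retained (returns None).
    """
    names = list(names)
    if scheme.upper() == "LOO":
        preds = loo_predictions(table, names)
        y = table.response.loc[preds.index].to_numpy(dtype=float)
        return q2_from_predictions(y, preds.to_numpy()), preds
    if scheme.upper() != "LMO":
        raise ValueError(f"unknown scheme {scheme!r}")
    if not (0.0 < frac < 0.5):
        raise ValueError("LMO fraction must be in (0, 0.5)")
    if iterations < 1:
        raise ValueError("LMO needs iterations >= 1")
    ids, Z, y = _design(table, names)
    n, q = Z.shape
    n_out = int(round(frac * n))
    if n - n_out < q + 1:
        raise ValueError(f"LMO fold leaves {n - n_out} rows, need >= {q + 1}")
    rng = np.random.default_rng(seed)
    q2s = np.empty(iterations)
    for it in range(iterations):
        out = rng.choice(n, size=n_out, replace=False)
        mask = np.ones(n, dtype=bool)
        mask[out] = False
        beta, *_ = np.linalg.lstsq(Z[mask], y[mask], rcond=None)
        e = y[out] - Z[out] @ beta
        q2s[it] = 1.0 - (e ** 2).sum() / ((y[out] - y.mean()) ** 2).sum()
    return float(q2s.mean()), None


def internal_report(table: DescriptorTable, names: list[str], *,
                    lmo_frac: float = 0.2, lmo_iterations: int = 1000,
                    seed: int | None = None) -> tuple[MetricReport, MLRModel]:
    """Fit on the table and assemble the full internal-validation block."""
    names = list(names)
    model = fit_ols(table, names)
    ids = table.response.index.intersection(table.data.index)
    yhat = predict(model, table.data.loc[ids])
    rep = regression_metrics(table.response.loc[ids], yhat, p=len(names))
    rep.q2_loo, _ = cross_validate(table, names, "LOO")
    rep.q2_lmo, _ = cross_validate(table, names, "LMO", frac=lmo_frac,
                                   iterations=lmo_iterations, seed=seed)
    return rep, model


# ---------------------------------------------------------------------------
# external validation

def _rto_r2(x: np.ndarray, y: np.ndarray) -> float:
    """R2 of the regression of y on x through the origin."""
    k = float((x * y).sum() / (x * x).sum())
    return float(1.0 - ((y - k * x) ** 2).sum() / ((y - y.mean()) ** 2).sum())


def concordance_ccc(y: np.ndarray, yh: np.ndarray) -> float:
    """Lin's concordance correlation coefficient."""
    y = np.asarray(y, dtype=float)
    yh = np.asarray(yh, dtype=float)
    n = y.size
    sxy = ((y - y.mean()) * (yh - yh.mean())).sum()
    denom = ((y - y.mean()) ** 2).sum() + ((yh - yh.mean()) ** 2).sum() \
        + n * (y.mean() - yh.mean()) ** 2
    return float(2.0 * sxy / denom)


def external_metrics(y_train, y_test, yhat_test) -> ExternalReport:
    """External predictivity battery on the held-out test block.

    Q2F1 centres the test responses on the training mean, Q2F2 on the test
    mean, and Q2F3 compares per-observation error against the training
    variance.  The r2m pair uses squared correlation r2 and the
    through-origin R2 with the two axis orders exchanged:
    r2m = r2 * (1 - sqrt(|r2 - r0^2|)).
    """
    ytr = np.asarray(y_train, dtype=float)
    y = np.asarray(y_test, dtype=float)
    yh = np.asarray(yhat_test, dtype=float)
    if y.size < 3:
        raise ValueError("need at least 3 test observations")
    if ((y - y.mean()) ** 2).sum() == 0 or ((ytr - ytr.mean()) ** 2).sum() == 0:
        raise ValueError("degenerate (zero-variance) responses")
    ssres = ((y - yh) ** 2).sum()
    q2f1 = 1.0 - ssres / ((y - ytr.mean()) ** 2).sum()
    q2f2 = 1.0 - ssres / ((y - y.mean()) ** 2).sum()
    q2f3 = 1.0 - (ssres / y.size) / (((ytr - ytr.mean()) ** 2).sum() / ytr.size)
    r = np.corrcoef(y, yh)[0, 1]
    r2 = float(r * r)
    r2m_fwd = r2 * (1.0 - np.sqrt(abs(r2 - _rto_r2(yh, y))))
    r2m_rev = r2 * (1.0 - np.sqrt(abs(r2 - _rto_r2(y, yh))))
    return ExternalReport(
        ccc=concordance_ccc(y, yh),
        q2_f1=float(q2f1), q2_f2=float(q2f2), q2_f3=float(q2f3),
        r2m_avg=float((r2m_fwd + r2m_rev) / 2.0),
        r2m_delta=float(abs(r2m_fwd - r2m_rev)),
    )


# ---------------------------------------------------------------------------
# Y-scrambling

def y_scramble(table: DescriptorTable, names: list[str], n_iter: int = 1000,
               seed: int | None = None, with_q2: bool = False) -> ScrambleResult:
    """Refit after random permutations of the response (chance-correlation
    check).  A sound model's scrambled R2 should collapse to ~p/(n-1)."""
    if n_iter < 0:
        raise ValueError("n_iter must be >= 0")
    seed = 0 if seed is None else seed
    result = ScrambleResult(n_iterations=n_iter, seed=seed)
    if n_iter == 0:
        return result
    names = list(names)
    ids, Z, y = _design(table, names)
    rng = np.random.default_rng(seed)
    sstot = ((y - y.mean()) ** 2).sum()
    Q, R = np.linalg.qr(Z)
    h = (Q ** 2).sum(axis=1)
    for _ in range(n_iter):
        yp = rng.permutation(y)
        coef = Q.T @ yp
        resid = yp - Q @ coef
        result.r2_values.append(float(1.0 - (resid ** 2).sum() / sstot))
        if with_q2:
            cv = resid / (1.0 - h)
            result.q2_values.append(float(1.0 - (cv ** 2).sum() / sstot))
    return result
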
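"""Small ordinary-least-squares engine shared by the scan stages.

The scans fit hundreds of thousands of tiny models, so the fit is a
direct normal-equations solve with t statistics from the coefficient
covariance; rank deficiency is detected and surfaced to the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class RankDeficientError(ValueError):
    """The design matrix does not have full column rank."""


@dataclass(frozen=True)
class OlsFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    rss: float
    df_resid: int
    n: int

    @property
    def r2(self) -> float:
        return 1.0 - self.rss / self.tss if self.tss > 0 else 0.0

    tss: float = 0.0

    def adjusted_r2(self) -> float:
        """1 - (1-R^2)(n-1)/df_resid."""
        if self.tss <= 0 or self.df_resid <= 0:
            return float("nan")
        return 1.0 - (self.rss / self.tss) * (self.n - 1) / self.df_resid


def ols_fit(y: np.ndarray, X: np.ndarray) -> OlsFit:
    """OLS of y on X (X must include any intercept column).

    Raises :class:`RankDeficientError` when X is column-rank deficient
    or there are no residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise RankDeficientError(f"n={n} rows for k={k} columns")
    XtX = X.T @ X
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        raise RankDeficientError(f"design rank {rank} < {k} columns")
    XtX_inv = np.linalg.inv(XtX)
    beta = XtX_inv @ (X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - k
    sigma2 = rss / df
    se = np.sqrt(np.clip(np.diag(XtX_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    return OlsFit(beta=beta, se=se, t=t, p=p, rss=rss, df_resid=df, n=n, tss=tss)


def design_with_intercept(*columns: np.ndarray) -> np.ndarray:
    cols = [np.ones(len(columns[0]))]
    cols.extend(np.asarray(c, dtype=float) for c in columns)
    return np.column_stack(cols)
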
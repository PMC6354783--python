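"""Shared statistical primitives: multiple-testing corrections and a
vectorised OLS used by the mass-univariate vertex models.

Benjamini-Hochberg adjustment is delegated to statsmodels; Bonferroni is
the explicit ``min(1, m*p)`` with a configurable family size so the family
can be larger than the number of p-values passed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up adjusted p-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def bh_reject(p: np.ndarray, q: float = 0.05) -> np.ndarray:
    """BH rejection mask at level ``q`` (equivalent to ``bh_adjust(p) <= q``)."""
    p = np.asarray(p, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return mask


def bonferroni_adjust(p, m: int | None = None):
    """Bonferroni-adjusted p-values ``min(1, m*p)``.

    ``m`` defaults to the number of finite p-values supplied; pass it
    explicitly when the correction family is defined externally (e.g. five
    karyotype contrasts corrected together but computed one at a time).
    """
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.isfinite(p).sum())
    return np.minimum(1.0, m * p)


@dataclass
class BatchOLS:
    """OLS of many response columns on one shared design matrix.

    Fits ``Y (n x V)`` on ``X (n x k)`` in a single solve; coefficient
    standard errors use the per-column residual variance with ``n - k``
    degrees of freedom.
    """

    coef: np.ndarray       # k x V
    se: np.ndarray         # k x V
    tvalues: np.ndarray    # k x V
    pvalues: np.ndarray    # k x V
    resid: np.ndarray      # n x V
    sigma: np.ndarray      # V (residual SD)
    dof: int

    @classmethod
    def fit(cls, X: np.ndarray, Y: np.ndarray) -> "BatchOLS":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        n, k = X.shape
        if n <= k:
            raise ValueError(f"need more observations ({n}) than parameters ({k})")
        xtx_inv = np.linalg.inv(X.T @ X)
        coef = xtx_inv @ X.T @ Y
        resid = Y - X @ coef
        dof = n - k
        sigma2 = (resid**2).sum(axis=0) / dof
        se = np.sqrt(np.outer(np.diag(xtx_inv), sigma2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = coef / se
        p = 2.0 * sps.t.sf(np.abs(t), dof)
        return cls(coef=coef, se=se, tvalues=t, pvalues=p, resid=resid,
                   sigma=np.sqrt(sigma2), dof=dof)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; NaN (with no exception) for constant input."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
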
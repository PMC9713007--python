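"""Vectorized mass-univariate GLM with Freedman-Lane permutation support.

One design matrix, many response columns (edges or features). The
Freedman-Lane scheme protects nuisance covariates: the reduced
(nuisance-only) model is fitted once, its residuals are row-permuted, the
permuted residuals are added back to the reduced fit, and the full model is
re-estimated on the reconstructed pseudo-responses.
"""

from __future__ import annotations

import numpy as np

_DEGENERATE_VAR = 1e-12


def check_design(X: np.ndarray, contrast: np.ndarray, n_responses_min: int = 1) -> None:
    X = np.asarray(X, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    if X.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    if contrast.shape != (X.shape[1],):
        raise ValueError("contrast length must equal the number of regressors")
    if not np.any(contrast):
        raise ValueError("contrast must be nonzero")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more subjects than regressors")


def glm_tstats(Y: np.ndarray, X: np.ndarray, contrast: np.ndarray) -> tuple[np.ndarray, int]:
    """OLS t-statistics of ``contrast`` for every column of ``Y``.

    Returns ``(t, df)`` with ``df = n - rank(X)``. Columns with (near-)zero
    residual variance are degenerate and get ``t = 0``.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    c = np.asarray(contrast, dtype=float)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    eff = c @ beta
    t = np.zeros(Y.shape[1])
    ok = denom2 > _DEGENERATE_VAR
    t[ok] = eff[ok] / np.sqrt(denom2[ok])
    return t, df


class FreedmanLane:
    """Precomputed state for Freedman-Lane permutations of one GLM."""

    def __init__(self, Y: np.ndarray, X: np.ndarray, contrast: np.ndarray):
        check_design(X, contrast)
        self.Y = np.asarray(Y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.contrast = np.asarray(contrast, dtype=float)
        nuis = np.flatnonzero(self.contrast == 0)
        Z = self.X[:, nuis] if len(nuis) else np.ones((self.X.shape[0], 1))
        coef, *_ = np.linalg.lstsq(Z, self.Y, rcond=None)
        self.fitted_reduced = Z @ coef
        self.resid_reduced = self.Y - self.fitted_reduced

    def observed(self) -> tuple[np.ndarray, int]:
        return glm_tstats(self.Y, self.X, self.contrast)

    def permuted(self, perm: np.ndarray) -> np.ndarray:
        """t-statistics after permuting the reduced-model residual rows."""
        Ystar = self.fitted_reduced + self.resid_reduced[perm]
        t, _ = glm_tstats(Ystar, self.X, self.contrast)
        return t


def perm_pvalue(n_as_extreme: int, n_perm: int, paper_convention: bool = False) -> float:
    """Permutation p-value; +1-corrected by default so p > 0 always."""
    if paper_convention:
        return n_as_extreme / n_perm
    return (1 + n_as_extreme) / (n_perm + 1)
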
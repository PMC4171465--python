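"""Functional linear model (FLM) association test — the comparison method.

Regresses a scalar (0/1) phenotype on the genotype function: with
y_i = alpha + int x_i(t) beta(t) dt + e_i and the coefficient function
expanded in a B-spline basis, beta(t) = sum_k b_k phi_k(t), the model
reduces to ordinary multiple regression of y on the n x K design

    X_ik = int x_i(t) phi_k(t) dt,

and the region test is the Wald test W = b' V^{-1} b on the K slope
coefficients, referred to a chi-squared distribution with K degrees of
freedom.  A linear model on the binary response is used deliberately (the
chi-squared and ANOVA tests coincide for dichotomous populations).  Because
basis choice and smoothing are data-dependent, a phenotype-permutation
p-value is also provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
from scipy.stats import chi2

from .smoothing import BasisSpec, CurveSet


@dataclass
class FlmResult:
    """Wald statistic for the functional linear model region test."""

    W: float
    K: int
    p_chisq: float
    p_permutation: float | None = None
    B: int = 0

    def to_row(self) -> dict:
        return {
            "W": self.W,
            "K": self.K,
            "p_chisq": self.p_chisq,
            "p_perm": self.p_permutation,
            "B": self.B,
        }


def flm_design(curves: CurveSet, beta_basis: BasisSpec) -> np.ndarray:
    """n x K design of numerically integrated curve-basis products.

    Entry (i, k) is the trapezoid-rule integral of x_i(t) phi_k(t) over
    [0, 1] on the curve grid (the endpoint-inclusive grid makes the
    trapezoid rule the accurate choice here; for the ANOVA F-ratio the
    quadrature weight cancels, so this choice only matters for the design).
    The intercept is appended by the fitting routine, not here.
    """
    Phi = beta_basis.design(curves.grid)  # T x K
    w = np.full(curves.n_grid, 1.0 / (curves.n_grid - 1))
    w[[0, -1]] /= 2.0
    X = (curves.values * w) @ Phi
    n, K = X.shape
    if K >= n - 2:
        raise ValueError(
            f"beta basis too rich: K = {K} coefficients for n = {n} subjects; "
            "use a smaller beta_basis (fewer knots)"
        )
    return X


def _independent_columns(X: np.ndarray) -> np.ndarray:
    """Indices of a maximal linearly independent column subset (pivoted QR)."""
    _, R, piv = sla.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return np.sort(piv[:rank])


def flm_wald(y: np.ndarray, X: np.ndarray) -> FlmResult:
    """Wald region test of the basis-expanded coefficient function.

    Fits y on [1, X] by least squares; W = b' V^{-1} b with
    V = sigma2 * (slope block of (X~'X~)^{-1}) and
    sigma2 = RSS / (n - K - 1).  Rank-deficient designs are reduced to an
    independent column subset (K adjusted accordingly).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.size
    keep = _independent_columns(X)
    if keep.size < X.shape[1]:
        X = X[:, keep]
    K = X.shape[1]
    if n <= K + 2:
        raise ValueError(f"too few subjects (n = {n}) for K = {K} coefficients")
    Xt = np.column_stack([np.ones(n), X])
    XtX_inv = sla.inv(Xt.T @ Xt)
    b_full = XtX_inv @ (Xt.T @ y)
    resid = y - Xt @ b_full
    sigma2 = float(resid @ resid) / (n - K - 1)
    b = b_full[1:]
    V = sigma2 * XtX_inv[1:, 1:]
    W = float(b @ sla.solve(V, b, assume_a="pos"))
    return FlmResult(W=W, K=K, p_chisq=float(chi2.sf(W, K)))


def flm_permutation(
    y: np.ndarray, X: np.ndarray, B: int = 999, seed: int | None = None
) -> FlmResult:
    """Phenotype-permutation p-value for the FLM Wald test.

    The phenotype vector is permuted ``B`` times and the chi-squared
    p-value recomputed with the design fixed;
    ``p_permutation = (1 + #{p_b <= p_obs}) / (B + 1)``.
    """
    obs = flm_wald(y, X)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)[:, _independent_columns(X)]
    n, K = X.shape
    Xt = np.column_stack([np.ones(n), X])
    XtX_inv = sla.inv(Xt.T @ Xt)
    C_inv = sla.inv(XtX_inv[1:, 1:])
    # with the design fixed, p_b <= p_obs iff W_b >= W_obs; permutations
    # are processed as one matrix of shuffled phenotype columns
    Yp = np.column_stack([rng.permutation(y) for _ in range(B)])
    Bf = XtX_inv @ (Xt.T @ Yp)
    resid = Yp - Xt @ Bf
    sigma2 = (resid * resid).sum(axis=0) / (n - K - 1)
    slopes = Bf[1:]
    quad = (slopes * (C_inv @ slopes)).sum(axis=0)
    W_b = quad / sigma2
    hits = int((W_b >= obs.W).sum())
    return FlmResult(
        W=obs.W,
        K=obs.K,
        p_chisq=obs.p_chisq,
        p_permutation=(1 + hits) / (B + 1),
        B=B,
    )
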
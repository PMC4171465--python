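"""Genotype-curve smoothing with cubic B-splines.

Each subject's discrete 0/1/2 genotype profile, indexed by scaled position
in [0, 1], is represented as a smooth function

    x(t) = sum_k c_k phi_k(t),

with cubic B-spline basis functions phi_k.  Three strategies are supported:

* ``SMALL_BASIS``   — a small number of equally spaced knots (default 6,
  giving 8 cubic B-splines); unpenalized least squares.  Heavy smoothing.
* ``EVERY_OTHER``   — a knot at every other variant position; unpenalized.
  Produces oscillating fits.
* ``PENALIZED_GCV`` — a knot at every variant position with a roughness
  penalty lambda * int x''(t)^2 dt; lambda chosen per subject by
  generalized cross validation (GCV).

All curves are then discretized on a common equally spaced grid of
``grid_multiplier * p`` points over [0, 1] (a :class:`CurveSet`), the form
consumed by the functional ANOVA and functional linear model tests.

The roughness penalty uses the exact B-spline second-derivative Gram
matrix (Gauss–Legendre quadrature per knot interval, exact for the
piecewise-polynomial integrand), so the large-lambda limit of the fit is
exactly the straight-line regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.interpolate import BSpline

from .genotype_data import GenotypeMatrix

logger = logging.getLogger(__name__)

_ORDER = 4  # cubic splines throughout


class Strategy(str, Enum):
    SMALL_BASIS = "small"
    EVERY_OTHER = "every-other"
    PENALIZED_GCV = "penalized"


@dataclass
class SmoothStrategy:
    """Smoothing strategy and its tuning knobs."""

    kind: Strategy = Strategy.PENALIZED_GCV
    n_knots_small: int = 6
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-8, 1e8, 50)
    )

    def __post_init__(self) -> None:
        self.kind = Strategy(self.kind)
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if (self.lambda_grid <= 0).any() or (np.diff(self.lambda_grid) <= 0).any():
            raise ValueError("lambda_grid must be positive and increasing")


@dataclass
class BasisSpec:
    """A cubic B-spline basis on [0, 1] defined by its breakpoints."""

    knots: np.ndarray  # breakpoints incl. both endpoints, weakly increasing
    order: int = _ORDER

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, dtype=float)
        if self.knots[0] != 0.0 or self.knots[-1] != 1.0:
            raise ValueError("knot sequence must span [0, 1]")
        if (np.diff(self.knots) < 0).any():
            raise ValueError("knots must be weakly increasing")

    @property
    def n_basis(self) -> int:
        # interior breakpoints + order
        return len(self.knots) - 2 + self.order

    @property
    def full_knots(self) -> np.ndarray:
        k = self.order - 1
        return np.concatenate([np.zeros(k), self.knots, np.ones(k)])

    def design(self, x: np.ndarray) -> np.ndarray:
        """Basis design matrix: entry (i, k) = phi_k(x_i)."""
        x = np.asarray(x, dtype=float)
        return BSpline.design_matrix(x, self.full_knots, self.order - 1).toarray()

    def penalty(self) -> np.ndarray:
        """Exact second-derivative Gram matrix P_kl = int phi_k'' phi_l'' dt."""
        t = self.full_knots
        nb = self.n_basis
        d2 = BSpline(t, np.eye(nb), self.order - 1).derivative(2)
        # 3-point Gauss–Legendre per breakpoint interval; the integrand is a
        # piecewise polynomial of degree <= 2, so this is exact.
        gx, gw = np.polynomial.legendre.leggauss(3)
        lo, hi = self.knots[:-1], self.knots[1:]
        half = (hi - lo) / 2.0
        pts = (lo[:, None] + half[:, None] * (gx[None, :] + 1.0)).ravel()
        wts = (half[:, None] * gw[None, :]).ravel()
        D = d2(pts)  # (n_pts, nb)
        return (D * wts[:, None]).T @ D


def build_basis(strategy: SmoothStrategy | Strategy | str, scaled_positions: np.ndarray) -> BasisSpec:
    """Knot placement for the given strategy.

    ``SMALL_BASIS``: equally spaced knots on [0, 1] (endpoints included).
    ``EVERY_OTHER``: both endpoint positions plus every other interior
    position (so 81 positions give 42 knots).  ``PENALIZED_GCV``: a knot at
    every scaled position.
    """
    if not isinstance(strategy, SmoothStrategy):
        strategy = SmoothStrategy(kind=Strategy(strategy))
    s = np.asarray(scaled_positions, dtype=float)
    if s.size < _ORDER:
        raise ValueError("need at least 4 positions for a cubic spline fit")
    if strategy.kind is Strategy.SMALL_BASIS:
        knots = np.linspace(0.0, 1.0, strategy.n_knots_small)
    elif strategy.kind is Strategy.EVERY_OTHER:
        knots = np.concatenate([[s[0]], s[1:-1:2], [s[-1]]])
    else:
        knots = s.copy()
    return BasisSpec(knots=knots)


@dataclass
class CurveSet:
    """Smoothed genotype curves discretized on a common grid."""

    grid: np.ndarray  # T equally spaced points on [0, 1]
    values: np.ndarray  # n x T
    strategy: Strategy
    lambdas: np.ndarray | None = None  # per-subject lambda (PENALIZED_GCV)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_grid(self) -> int:
        return self.values.shape[1]

    @property
    def delta(self) -> float:
        """Rectangle-rule integration weight, 1/T."""
        return 1.0 / self.n_grid

    def to_tsv(self, path: str | Path, sample_ids: list[str] | None = None) -> None:
        idx = sample_ids if sample_ids is not None else [
            f"S{i}" for i in range(self.n_subjects)
        ]
        df = pd.DataFrame(self.values, index=idx, columns=self.grid)
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


class _PenalizedFitter:
    """Penalized least squares on a fixed design, fast along a lambda path.

    Simultaneously diagonalizes the pencil (B'B, P) via a Cholesky factor of
    B'B + P, so each lambda costs one diagonal rescaling: with
    W' (B'B) W = diag(a) and W' P W = diag(1 - a),

        c(lambda) = W diag(1/(a + lambda (1-a))) W' B' y,
        tr H(lambda) = sum_i a_i / (a_i + lambda (1 - a_i)).

    Valid for any lambda > 0 even when B'B is singular (more basis functions
    than observation points), since null(B'B) and null(P) intersect trivially.
    """

    def __init__(self, basis: BasisSpec, x: np.ndarray):
        B = basis.design(x)
        P = basis.penalty()
        M = B.T @ B
        L = sla.cholesky(M + P, lower=True)
        Li_M = sla.solve_triangular(L, M, lower=True)
        F = sla.solve_triangular(L, Li_M.T, lower=True)
        a, U = sla.eigh((F + F.T) / 2.0)
        a = np.clip(a, 0.0, 1.0)
        # snap the penalty-null (linear) directions to exactly 1 so that
        # eigendecomposition noise is not amplified by large lambdas
        a[a > 1.0 - 1e-9] = 1.0
        self.a = a
        self.W = sla.solve_triangular(L.T, U, lower=False)
        self.A = B @ self.W  # m x nb; z = A' y
        self.m = B.shape[0]

    def _denom(self, lam: np.ndarray) -> np.ndarray:
        # shape (nb, len(lam))
        return self.a[:, None] + np.asarray(lam)[None, :] * (1.0 - self.a[:, None])

    def trace_hat(self, lam: np.ndarray) -> np.ndarray:
        return (self.a[:, None] / self._denom(lam)).sum(axis=0)

    def gcv(self, Y: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """GCV(lambda) = m RSS / (m - tr H)^2 on a shared lambda grid.

        ``Y``: m x n observations; returns an n x len(lam) score table.
        """
        Z = self.A.T @ Y  # nb x n
        lam = np.asarray(lam, dtype=float)
        out = np.empty((Y.shape[1], lam.size))
        edf = self.trace_hat(lam)
        den = self._denom(lam)  # nb x L
        for li in range(lam.size):
            C = Z / den[:, li][:, None]
            R = Y - self.A @ C
            out[:, li] = self.m * (R * R).sum(axis=0) / (self.m - edf[li]) ** 2
        return out

    def gcv_per_subject(self, Y: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """GCV with one lambda per subject (vectorized)."""
        Z = self.A.T @ Y
        den = self._denom(lam)  # nb x n
        C = Z / den
        R = Y - self.A @ C
        rss = (R * R).sum(axis=0)
        edf = (self.a[:, None] / den).sum(axis=0)
        return self.m * rss / (self.m - edf) ** 2

    def coefficients(self, Y: np.ndarray, lam: np.ndarray) -> np.ndarray:
        """Penalized LS coefficients, one lambda per subject; nb x n."""
        Z = self.A.T @ Y
        return self.W @ (Z / self._denom(lam))


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_refine(
    fitter: _PenalizedFitter,
    Y: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    n_iter: int = 24,
) -> np.ndarray:
    """Golden-section minimization of GCV in log-lambda, per subject."""
    a, b = np.log(lo), np.log(hi)
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc = fitter.gcv_per_subject(Y, np.exp(c))
    fd = fitter.gcv_per_subject(Y, np.exp(d))
    for _ in range(n_iter):
        left = fc < fd
        b = np.where(left, d, b)
        a = np.where(left, a, c)
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
        fc = fitter.gcv_per_subject(Y, np.exp(c))
        fd = fitter.gcv_per_subject(Y, np.exp(d))
    return np.exp((a + b) / 2.0)


def _select_lambda_grid(
    fitter: _PenalizedFitter, Y: np.ndarray, grid: np.ndarray
) -> np.ndarray:
    """Grid GCV minimum refined by a golden-section pass between neighbors."""
    g = fitter.gcv(Y, grid)  # n x L
    idx = np.argmin(g, axis=1)
    lo = grid[np.maximum(idx - 1, 0)]
    hi = grid[np.minimum(idx + 1, grid.size - 1)]
    lam = _golden_refine(fitter, Y, lo, hi)
    # degenerate inputs (constant profiles) take the maximal smoothing
    const = np.ptp(Y, axis=0) == 0
    lam[const] = grid[-1]
    return lam


def select_lambda_gcv(
    y: np.ndarray,
    basis: BasisSpec,
    lambda_grid: np.ndarray,
    x: np.ndarray | None = None,
) -> float:
    """GCV-optimal roughness penalty for one subject's observed codes.

    ``y`` are the observed codes at observed scaled positions ``x``
    (defaults to equally spaced points on [0, 1]).  The GCV score is
    ``m * RSS(lambda) / (m - tr H_lambda)^2``; the grid minimum is refined by
    a golden-section pass between its neighbors.  A constant input, for
    which every lambda reproduces the data exactly, returns the grid
    maximum (maximal smoothing).
    """
    y = np.asarray(y, dtype=float)
    if y.size < _ORDER:
        raise ValueError("need at least 4 observed points to select lambda")
    if x is None:
        x = np.linspace(0.0, 1.0, y.size)
    grid = np.asarray(lambda_grid, dtype=float)
    fitter = _PenalizedFitter(basis, np.asarray(x, dtype=float))
    lam = _select_lambda_grid(fitter, y[:, None], grid)
    return float(lam[0])


def _fit_unpenalized(B: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Ordinary least-squares spline coefficients, all subjects at once."""
    coef, _, rank, _ = np.linalg.lstsq(B, Y, rcond=None)
    if rank < B.shape[1]:
        logger.warning(
            "singular unpenalized spline system (rank %d < %d); "
            "falling back to ridge jitter 1e-8",
            rank,
            B.shape[1],
        )
        coef = sla.solve(
            B.T @ B + 1e-8 * np.eye(B.shape[1]), B.T @ Y, assume_a="pos"
        )
    return coef


def smooth_all(
    G: GenotypeMatrix,
    strategy: SmoothStrategy | Strategy | str = Strategy.PENALIZED_GCV,
    grid_multiplier: int = 2,
) -> CurveSet:
    """Smooth every subject's genotype profile and discretize on a common grid.

    The grid has ``T = grid_multiplier * p`` equally spaced points on [0, 1]
    (endpoints included).  Missing entries are allowed: each subject is
    fitted on its observed positions only.  For ``PENALIZED_GCV`` the
    roughness penalty is selected per subject by GCV; the two unpenalized
    strategies use ordinary least squares (with a logged ridge fallback if
    the system is singular).
    """
    if not isinstance(strategy, SmoothStrategy):
        strategy = SmoothStrategy(kind=Strategy(strategy))
    if G.scaled_positions is None:
        raise ValueError("scale_positions must be applied before smoothing")
    s = G.scaled_positions
    basis = build_basis(strategy, s)
    T = grid_multiplier * G.n_variants
    grid = np.linspace(0.0, 1.0, T)
    Bg = basis.design(grid)
    Y = G.codes.T  # p x n
    penalized = strategy.kind is Strategy.PENALIZED_GCV

    if not G.has_missing:
        if penalized:
            fitter = _PenalizedFitter(basis, s)
            lam = _select_lambda_grid(fitter, Y, strategy.lambda_grid)
            coef = fitter.coefficients(Y, lam)
        else:
            lam = None
            coef = _fit_unpenalized(basis.design(s), Y)
        values = (Bg @ coef).T
        return CurveSet(grid=grid, values=values, strategy=strategy.kind, lambdas=lam)

    # per-subject observed-data fits
    values = np.empty((G.n_subjects, T))
    lams = np.full(G.n_subjects, np.nan) if penalized else None
    for i in range(G.n_subjects):
        obs = ~np.isnan(G.codes[i])
        if obs.sum() < _ORDER:
            raise ValueError(
                f"subject {G.sample_ids[i]} has fewer than 4 observed genotypes"
            )
        xi, yi = s[obs], G.codes[i, obs][:, None]
        if penalized:
            fitter = _PenalizedFitter(basis, xi)
            lam_i = _select_lambda_grid(fitter, yi, strategy.lambda_grid)
            coef = fitter.coefficients(yi, lam_i)
            lams[i] = lam_i[0]
        else:
            coef = _fit_unpenalized(basis.design(xi), yi)
        values[i] = (Bg @ coef).ravel()
    return CurveSet(grid=grid, values=values, strategy=strategy.kind, lambdas=lams)
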
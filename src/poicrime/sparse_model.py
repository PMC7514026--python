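"""Sparse linear modelling of crime density from POI class densities.

The crime raster ``y`` is modelled as a sparse linear combination of the
basis-matrix columns.  Coefficients are obtained by LASSO — minimising

    (1 / 2n) * ||y - B w||^2  +  alpha * ||w||_1

on column-standardised regressors (zero mean, unit standard deviation;
standardisation removes the bias towards high-magnitude variables) with a
centred response, which is equivalent to fitting an unpenalised
intercept.  The penalty weight ``alpha`` is tuned by binary search so
that exactly ``k`` classes (default 10) survive, after which an ordinary
least-squares refit on the selected, unstandardised columns yields the
final sparse model.  A univariate alcohol-outlet-only regression serves
as the baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Lasso

from .density_estimation import BasisMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "LassoFit",
    "ModelFit",
    "SupportSelection",
    "DEFAULT_ALCOHOL_CLASSES",
    "lasso_fit",
    "alpha_max",
    "select_alpha_for_support",
    "ols_refit",
    "baseline_fit",
]

#: Class names treated as "alcohol outlets" by the baseline model.
DEFAULT_ALCOHOL_CLASSES = ("Pubs, Bars and Inns",)

_CD_TOL = 1e-8  # coordinate-descent tolerance; fits are deterministic


def _as_matrix(basis) -> tuple[np.ndarray, list[str]]:
    """Accept a BasisMatrix, a labelled DataFrame, or a bare ndarray."""
    if isinstance(basis, BasisMatrix):
        return basis.matrix, list(basis.columns)
    if hasattr(basis, "columns") and hasattr(basis, "to_numpy"):
        return basis.to_numpy(dtype=float), [str(c) for c in basis.columns]
    B = np.asarray(basis, dtype=float)
    return B, [f"col{j}" for j in range(B.shape[1])]


def _standardise(B: np.ndarray):
    mean = B.mean(axis=0)
    scale = B.std(axis=0)
    constant = scale == 0
    scale = np.where(constant, 1.0, scale)
    return (B - mean) / scale, mean, scale, constant


@dataclass
class LassoFit:
    """L1-penalised fit; coefficients on both standardised and raw scales."""

    alpha: float
    coefficients: dict[str, float]       # standardised scale (selection scale)
    raw_coefficients: dict[str, float]   # back-transformed to original units
    intercept: float                     # raw scale
    n_nonzero: int
    column_means: np.ndarray
    column_scales: np.ndarray

    @property
    def support(self) -> list[str]:
        return [c for c, w in self.coefficients.items() if w != 0.0]


@dataclass
class ModelFit:
    """Final sparse model: selected classes plus unpenalised coefficients."""

    selected_classes: list[str]
    ols_coefficients: dict[str, float]
    intercept: float
    alpha_used: float = float("nan")

    def predict(self, basis) -> np.ndarray:
        B, cols = _as_matrix(basis)
        out = np.full(B.shape[0], self.intercept)
        for name, w in self.ols_coefficients.items():
            out += w * B[:, cols.index(name)]
        return out

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("class,coefficient\n")
            fh.write(f"(intercept),{self.intercept!r}\n")
            for name in self.selected_classes:
                fh.write(f"\"{name}\",{self.ols_coefficients[name]!r}\n")


@dataclass
class SupportSelection:
    """Result of the alpha binary search for a fixed support size."""

    alpha: float
    fit: LassoFit
    selected_classes: list[str]
    fallback: bool = False
    visited: list[tuple[float, int]] = field(default_factory=list)


def _check_xy(B, y):
    y = np.asarray(y, dtype=float).ravel()
    if B.shape[0] != y.shape[0]:
        raise ValueError(f"basis rows {B.shape[0]} != response length {y.shape[0]}")
    if not (np.isfinite(B).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in basis or response")
    return y


def lasso_fit(basis, y, alpha: float) -> LassoFit:
    """Solve the L1-penalised least-squares problem at a given alpha.

    Columns are standardised and the response centred before fitting
    (constant columns get a forced zero coefficient).  ``alpha = 0``
    reduces to ordinary least squares and is solved directly.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    B, cols = _as_matrix(basis)
    y = _check_xy(B, y)
    Bs, mean, scale, constant = _standardise(B)
    Bs[:, constant] = 0.0
    ybar = y.mean()
    yc = y - ybar

    if alpha == 0:
        w, *_ = np.linalg.lstsq(Bs, yc, rcond=None)
    else:
        model = Lasso(alpha=alpha, fit_intercept=False, tol=_CD_TOL,
                      max_iter=100_000)
        model.fit(Bs, yc)
        w = model.coef_
    w = np.where(constant, 0.0, w)

    raw = w / scale
    intercept = ybar - float(raw @ mean)
    return LassoFit(
        alpha=float(alpha),
        coefficients={c: float(v) for c, v in zip(cols, w)},
        raw_coefficients={c: float(v) for c, v in zip(cols, raw)},
        intercept=intercept,
        n_nonzero=int(np.count_nonzero(w)),
        column_means=mean, column_scales=scale,
    )


def alpha_max(basis, y) -> float:
    """Smallest alpha with an all-zero LASSO solution: max_j |B~_j . y~| / n."""
    B, _ = _as_matrix(basis)
    y = _check_xy(B, y)
    Bs, _, _, constant = _standardise(B)
    Bs[:, constant] = 0.0
    yc = y - y.mean()
    return float(np.max(np.abs(Bs.T @ yc)) / len(y))


def select_alpha_for_support(basis, y, k: int = 10, max_iter: int = 60,
                             strict_paper: bool = False) -> SupportSelection:
    """Binary-search alpha so that exactly ``k`` classes are selected.

    The bracket is [0, alpha_max] (data-driven, valid at any response
    scale), or the literal [0, 1] under ``strict_paper``.  The search
    keeps the largest visited alpha whose support size is exactly ``k``.
    Because the support size is piecewise constant in alpha, exactly
    ``k`` may be unattainable; the fallback then takes the visited fit
    with support nearest to ``k`` (preferring larger supports) and
    truncates to the ``k`` largest-|coefficient| classes, flagging
    ``fallback=True``.
    """
    B, cols = _as_matrix(basis)
    y = _check_xy(B, y)
    usable = int(np.count_nonzero(B.std(axis=0) > 0))
    if usable < k:
        raise ValueError(f"only {usable} usable (non-constant) columns, need {k}")

    hi = 1.0 if strict_paper else alpha_max(basis, y)
    lo = 0.0
    visited: list[tuple[float, int, LassoFit]] = []
    best: tuple[float, LassoFit] | None = None

    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fit = lasso_fit(basis, y, mid)
        visited.append((mid, fit.n_nonzero, fit))
        if fit.n_nonzero == k:
            if best is None or mid > best[0]:
                best = (mid, fit)
            lo = mid  # look for the largest alpha that still gives k
        elif fit.n_nonzero > k:
            lo = mid  # too many survivors: increase the penalty
        else:
            hi = mid

    path = [(a, n) for a, n, _ in visited]
    if best is not None:
        alpha, fit = best
        return SupportSelection(alpha, fit, fit.support, False, path)

    # fallback: nearest support size, preferring > k, then truncate to k
    def rank(entry):
        _, n, _ = entry
        return (abs(n - k), 0 if n > k else 1)

    alpha, n, fit = min(visited, key=rank)
    logger.warning("exact support %d unattainable; falling back from support %d "
                   "at alpha=%.3g", k, n, alpha)
    order = sorted(fit.support, key=lambda c: -abs(fit.coefficients[c]))
    return SupportSelection(alpha, fit, order[:k], True, path)


def ols_refit(basis, selected_classes: list[str], y,
              alpha_used: float = float("nan")) -> ModelFit:
    """Unpenalised least squares on the selected, unstandardised columns.

    Rank deficiency is resolved by the minimum-norm solution (with a
    logged warning).
    """
    if not selected_classes:
        raise ValueError("empty selection")
    B, cols = _as_matrix(basis)
    y = _check_xy(B, y)
    idx = [cols.index(c) for c in selected_classes]
    X = np.column_stack([np.ones(B.shape[0]), B[:, idx]])
    w, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        logger.warning("rank-deficient refit (rank %d of %d): minimum-norm "
                       "solution used", rank, X.shape[1])
    return ModelFit(
        selected_classes=list(selected_classes),
        ols_coefficients={c: float(v) for c, v in zip(selected_classes, w[1:])},
        intercept=float(w[0]),
        alpha_used=alpha_used,
    )


def baseline_fit(alcohol_density, y, class_name: str = "alcohol") -> ModelFit:
    """Univariate OLS of crime density on alcohol-outlet density alone."""
    x = np.asarray(alcohol_density, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("length mismatch between regressor and response")
    if x.std() == 0:
        raise ValueError("alcohol density has zero variance")
    X = np.column_stack([np.ones_like(x), x])
    w, *_ = np.linalg.lstsq(X, y, rcond=None)
    return ModelFit(selected_classes=[class_name],
                    ols_coefficients={class_name: float(w[1])},
                    intercept=float(w[0]), alpha_used=0.0)
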
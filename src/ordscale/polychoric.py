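"""Two-step polychoric correlation estimation.

Thresholds come from the univariate margins (normal quantiles of cumulative
proportions); each pairwise correlation then maximises the bivariate-normal
likelihood of the 4x4 cross-table with thresholds held fixed.  The
asymptotic covariance of the stacked correlation estimates is computed from
empirical influence functions, which is what the DWLS fitter consumes both
as diagonal weights and in the mean-and-variance adjustment of its test
statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import rectangle_probabilities
from .synthetic import ItemResponseMatrix

__all__ = [
    "ThresholdSet",
    "PolychoricResult",
    "PairFit",
    "estimate_thresholds",
    "polychoric_pair",
    "polychoric_matrix",
    "smooth_to_pd",
    "pair_order",
]

logger = logging.getLogger(__name__)

_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class ThresholdSet:
    """Per-item increasing cut points on the standard-normal latent scale.

    Unobserved leading/trailing categories yield -inf / +inf sentinels,
    treated as open bounds by every consumer.
    """

    values: np.ndarray  # (J, m)
    item_labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "values", np.atleast_2d(np.asarray(self.values, float)))

    def __getitem__(self, item_label):
        return self.values[self.item_labels.index(item_label)]


@dataclass(frozen=True)
class PairFit:
    """Single-pair polychoric fit: estimate plus optimiser diagnostics."""

    rho: float
    converged: bool
    loglik: float


@dataclass(frozen=True)
class PolychoricResult:
    """Polychoric correlation matrix with thresholds and asymptotic covariance.

    ``acov`` is the estimated covariance matrix of the J(J-1)/2 stacked
    correlation estimates (column-major lower-triangle order), already on the
    sampling scale, i.e. entries shrink like 1/n.  ``smoothed`` records
    whether a nearest-PD adjustment was applied to R.
    """

    R: np.ndarray
    thresholds: ThresholdSet
    acov: np.ndarray | None
    n: int
    smoothed: bool = False

    @property
    def item_labels(self):
        return self.thresholds.item_labels

    @property
    def n_items(self) -> int:
        return self.R.shape[0]

    def lower_triangle(self) -> np.ndarray:
        """Stacked correlations in column-major lower-triangle order."""
        idx = pair_order(self.n_items)
        return np.array([self.R[i, j] for i, j in idx])


def pair_order(J: int):
    """Column-major lower-triangle pair ordering: (1,0), (2,0), ..., (J-1,J-2)."""
    return [(i, j) for j in range(J) for i in range(j + 1, J)]


def estimate_thresholds(matrix: ItemResponseMatrix, n_categories: int = 4) -> ThresholdSet:
    """Thresholds as normal quantiles of cumulative category proportions."""
    vals = matrix.values
    n = matrix.n
    out = np.empty((matrix.n_items, n_categories - 1))
    for j in range(matrix.n_items):
        counts = np.bincount(vals[:, j], minlength=n_categories)
        if np.count_nonzero(counts) < 2:
            raise ValueError(
                f"item {matrix.item_labels[j]!r} is constant; thresholds undefined"
            )
        cum = np.cumsum(counts)[:-1] / n
        with np.errstate(divide="ignore"):
            tau = ndtri(cum)
        tau[cum <= 0.0] = -np.inf
        tau[cum >= 1.0] = np.inf
        out[j] = tau
    return ThresholdSet(values=out, item_labels=matrix.item_labels)


def _thresholds_from_margin(counts: np.ndarray) -> np.ndarray:
    cum = np.cumsum(counts)[:-1] / counts.sum()
    with np.errstate(divide="ignore"):
        tau = ndtri(cum)
    tau[cum <= 0.0] = -np.inf
    tau[cum >= 1.0] = np.inf
    return tau


def _pair_loglik(table, tau_r, tau_c, rho):
    probs = np.maximum(rectangle_probabilities(tau_r, tau_c, rho), _PROB_FLOOR)
    return float(np.sum(table * np.log(probs)))


def polychoric_pair(table, thresholds=None) -> PairFit:
    """Two-step ML polychoric correlation from a contingency table.

    Margins with zero total collapse that category before fitting.  With
    thresholds fixed at their univariate estimates, the bivariate-normal
    log-likelihood is maximised over rho in (-1, 1) by bounded 1-D search.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or table.sum() <= 0:
        raise ValueError("contingency table must be nonnegative with positive total")
    row_m = table.sum(axis=1)
    col_m = table.sum(axis=0)
    table = table[row_m > 0][:, col_m > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("each margin needs at least two observed categories")
    if thresholds is None:
        tau_r = _thresholds_from_margin(table.sum(axis=1))
        tau_c = _thresholds_from_margin(table.sum(axis=0))
    else:
        tau_r, tau_c = thresholds

    res = minimize_scalar(
        lambda r: -_pair_loglik(table, tau_r, tau_c, r),
        bounds=(-0.9999, 0.9999),
        method="bounded",
        options={"xatol": 1e-8},
    )
    if not res.success:
        raise RuntimeError(f"polychoric optimiser failed: {res.message}")
    return PairFit(rho=float(res.x), converged=bool(res.success), loglik=-float(res.fun))


def polychoric_matrix(
    matrix: ItemResponseMatrix, compute_acov: bool = True, smooth: bool = True
) -> PolychoricResult:
    """Pairwise polychoric correlation matrix with influence-function acov."""
    J = matrix.n_items
    n = matrix.n
    thresholds = estimate_thresholds(matrix)
    R = np.eye(J)
    pairs = pair_order(J)
    vals = matrix.values

    influence = np.zeros((n, len(pairs))) if compute_acov else None
    for p, (i, j) in enumerate(pairs):
        cell = 4 * vals[:, i] + vals[:, j]
        table = np.bincount(cell, minlength=16).reshape(4, 4).astype(float)
        try:
            fit = polychoric_pair(table)
        except (ValueError, RuntimeError) as exc:
            raise RuntimeError(
                f"polychoric fit failed for pair "
                f"({matrix.item_labels[i]}, {matrix.item_labels[j]}): {exc}"
            ) from exc
        R[i, j] = R[j, i] = fit.rho
        if compute_acov:
            influence[:, p] = _pair_influence(table, cell, fit.rho)

    if compute_acov:
        centered = influence - influence.mean(axis=0, keepdims=True)
        acov = centered.T @ centered / (n * n)
    else:
        acov = None

    smoothed = False
    if smooth:
        R_pd = smooth_to_pd(R)
        smoothed = not np.array_equal(R_pd, R)
        R = R_pd
    return PolychoricResult(R=R, thresholds=thresholds, acov=acov, n=n, smoothed=smoothed)


def _pair_influence(table, cell, rho, h: float = 1e-5):
    """Per-respondent influence of the pair's rho estimate.

    Score of the cell log-probability w.r.t. rho (central differences),
    divided by the empirical information.  First-step threshold uncertainty
    is deliberately ignored; see the methods note.
    """
    tau_r = _thresholds_from_margin(table.sum(axis=1))
    tau_c = _thresholds_from_margin(table.sum(axis=0))
    lo = np.log(np.maximum(rectangle_probabilities(tau_r, tau_c, rho - h), _PROB_FLOOR))
    hi = np.log(np.maximum(rectangle_probabilities(tau_r, tau_c, rho + h), _PROB_FLOOR))
    score_by_cell = ((hi - lo) / (2 * h)).ravel()
    info = float(np.sum(table.ravel() * score_by_cell**2)) / table.sum()
    if info <= 0:
        info = 1.0
    return score_by_cell[cell] / info


def smooth_to_pd(R: np.ndarray, floor: float = 1e-6, max_iter: int = 100) -> np.ndarray:
    """Nearest-PD adjustment: eigenvalue flooring plus re-standardisation.

    Returns the input unchanged (same object content) when already PD.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10) or not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("input must be symmetric with unit diagonal")
    eigvals = np.linalg.eigvalsh(R)
    if eigvals.min() >= floor:
        return R
    out = R.copy()
    for _ in range(max_iter):
        vals, vecs = np.linalg.eigh(out)
        if vals.min() >= floor:
            break
        vals = np.maximum(vals, floor)
        out = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        out = (out + out.T) / 2
        np.fill_diagonal(out, 1.0)
    logger.info(
        "polychoric matrix smoothed to PD; max elementwise change %.3e",
        np.abs(out - R).max(),
    )
    return out
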
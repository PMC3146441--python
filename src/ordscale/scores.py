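"""Model-based factor scores and their relation to raw sum scores.

MAP (maximum a posteriori) scores are the posterior mode of a respondent's
latent factor values under the fitted ordinal threshold model and a normal
prior with the estimated factor correlations (identity for orthogonal
models).  The score table assembles MAP scores, raw sub-scale sums and the
total score, and their Pearson correlation matrix — the device used to ask
whether the 10-item raw total is an adequate stand-in for the general
factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .sem import FactorSolution
from .synthetic import ItemResponseMatrix

__all__ = ["map_scores", "eap_scores", "score_table", "ScoreSet"]

_DELTA_FLOOR = 0.01
_P_FLOOR = 1e-12
_THETA_BOUND = 8.0


def _measurement_arrays(solution: FactorSolution):
    lam = solution.loadings
    tau = np.asarray(solution.thresholds.values, dtype=float)
    delta = np.maximum(solution.delta, _DELTA_FLOOR)  # Heywood guard for scoring
    sd = np.sqrt(delta)
    # augmented thresholds with open bounds
    J = lam.shape[0]
    tau_aug = np.concatenate(
        [np.full((J, 1), -np.inf), tau, np.full((J, 1), np.inf)], axis=1
    )
    prior_prec = np.linalg.inv(solution.phi)
    return lam, tau_aug, sd, prior_prec


def _neg_log_posterior(theta, x, lam, tau_aug, sd, prior_prec):
    mean = lam @ theta
    z_hi = np.clip((tau_aug[np.arange(len(x)), x + 1] - mean) / sd, -39.0, 39.0)
    z_lo = np.clip((tau_aug[np.arange(len(x)), x] - mean) / sd, -39.0, 39.0)
    p = np.maximum(ndtr(z_hi) - ndtr(z_lo), _P_FLOOR)
    nll = -np.sum(np.log(p)) + 0.5 * theta @ prior_prec @ theta
    # gradient
    phi_hi = np.exp(-0.5 * z_hi**2) / np.sqrt(2 * np.pi)
    phi_lo = np.exp(-0.5 * z_lo**2) / np.sqrt(2 * np.pi)
    dlogp_dmean = (phi_hi - phi_lo) / (p * sd)  # d(-log p)/d mean
    grad = lam.T @ dlogp_dmean + prior_prec @ theta
    return nll, grad


def map_scores(
    solution: FactorSolution,
    matrix: ItemResponseMatrix,
    gtol: float = 1e-8,
) -> pd.DataFrame:
    """Posterior-mode factor scores, one column per factor.

    Identical response patterns receive identical scores (optimisation runs
    once per unique pattern).  Starts at the prior mode (0) and ascends the
    log posterior by quasi-Newton steps.
    """
    if matrix.n_items != solution.spec.n_items:
        raise ValueError("response matrix and solution disagree on the number of items")
    lam, tau_aug, sd, prior_prec = _measurement_arrays(solution)
    K = lam.shape[1]
    patterns, inverse = np.unique(matrix.values, axis=0, return_inverse=True)
    scores = np.empty((patterns.shape[0], K))
    for r, x in enumerate(patterns):
        res = minimize(
            _neg_log_posterior,
            np.zeros(K),
            args=(x, lam, tau_aug, sd, prior_prec),
            jac=True,
            method="L-BFGS-B",
            bounds=[(-_THETA_BOUND, _THETA_BOUND)] * K,
            options={"gtol": gtol, "maxiter": 200},
        )
        if not np.all(np.isfinite(res.x)):
            raise RuntimeError(f"non-finite posterior mode for pattern {x}")
        scores[r] = res.x
    return pd.DataFrame(scores[inverse], columns=list(solution.factor_labels))


def eap_scores(
    solution: FactorSolution,
    matrix: ItemResponseMatrix,
    n_draws: int = 4096,
    seed: int = 0,
) -> pd.DataFrame:
    """Posterior-mean factor scores by importance-weighted prior sampling.

    A sensitivity companion to :func:`map_scores` — the stated scoring
    method of record is MAP.
    """
    lam, tau_aug, sd, _ = _measurement_arrays(solution)
    K = lam.shape[1]
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(solution.phi)
    theta = rng.standard_normal((n_draws, K)) @ chol.T
    mean = theta @ lam.T  # draws x J
    patterns, inverse = np.unique(matrix.values, axis=0, return_inverse=True)
    out = np.empty((patterns.shape[0], K))
    J = lam.shape[0]
    cols = np.arange(J)
    for r, x in enumerate(patterns):
        z_hi = (tau_aug[cols, x + 1][None, :] - mean) / sd[None, :]
        z_lo = (tau_aug[cols, x][None, :] - mean) / sd[None, :]
        logw = np.log(np.maximum(ndtr(z_hi) - ndtr(z_lo), _P_FLOOR)).sum(axis=1)
        w = np.exp(logw - logw.max())
        out[r] = (w[:, None] * theta).sum(axis=0) / w.sum()
    return pd.DataFrame(out[inverse], columns=list(solution.factor_labels))


@dataclass(frozen=True)
class ScoreSet:
    """Factor scores, raw scores, and their Pearson correlation matrix."""

    scores: pd.DataFrame
    correlations: pd.DataFrame
    zero_variance: tuple

    def __post_init__(self):
        pass


def score_table(
    matrix: ItemResponseMatrix,
    solution: FactorSolution,
    item_sets: dict,
    method: str = "map",
) -> ScoreSet:
    """Assemble factor scores, raw sub-scores and total score with correlations.

    ``item_sets`` maps sub-scale labels to item labels; sets must be
    disjoint and cover all items, so the sub-scores add up to the total.
    Zero-variance columns are flagged and their correlations set to NaN
    rather than silently zeroed.
    """
    covered = [item for items in item_sets.values() for item in items]
    if sorted(covered) != sorted(matrix.item_labels):
        raise ValueError("item_sets must partition the scale's items")
    scorer = {"map": map_scores, "eap": eap_scores}[method]
    fs = scorer(solution, matrix)
    fs.columns = [f"score_{c}" for c in fs.columns]
    raw = {}
    for label, items in item_sets.items():
        idx = [matrix.item_labels.index(i) for i in items]
        raw[f"raw_{label}"] = matrix.values[:, idx].sum(axis=1)
    raw["raw_total"] = matrix.totals()
    table = pd.concat([fs, pd.DataFrame(raw)], axis=1)

    sd = table.std(ddof=0)
    zero_var = tuple(sd.index[sd == 0])
    corr = table.corr()
    for col in zero_var:
        corr.loc[col, :] = np.nan
        corr.loc[:, col] = np.nan
    return ScoreSet(scores=table, correlations=corr, zero_variance=zero_var)
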
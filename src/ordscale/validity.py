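"""AVE-based convergent/discriminant validity and bifactor variance partition.

The average variance extracted (AVE) of a congeneric factor is the mean of
its items' squared standardized loadings: the share of indicator variance
the factor absorbs rather than measurement error.  Convergent validity asks
AVE >= 0.50; the Fornell-Larcker criterion for discriminant validity asks
each factor's sqrt(AVE) to exceed its correlations with every other factor,
preferably without confidence-interval overlap.  Bootstrap intervals
resample respondents and rerun the polychoric + DWLS pipeline per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .polychoric import polychoric_matrix
from .sem import FactorSolution, ModelSpec, fit_model
from .synthetic import ItemResponseMatrix

__all__ = [
    "ave",
    "fornell_larcker",
    "bootstrap_validity",
    "variance_partition",
    "variance_partition_from_loadings",
    "ValidityReport",
    "VariancePartition",
]

logger = logging.getLogger(__name__)

CONVERGENT_THRESHOLD = 0.50


def ave(loadings) -> float:
    """Average variance extracted: mean of squared standardized loadings."""
    lam = np.asarray(loadings, dtype=float)
    if lam.size == 0:
        raise ValueError("AVE of an empty loading block is undefined")
    if np.any(np.abs(lam) > 1.0 + 1e-9):
        raise ValueError("standardized loadings must lie in [-1, 1]")
    return float(np.mean(lam**2))


def fornell_larcker(aves: dict, phi: np.ndarray, factor_labels=None,
                    sqrt_ave_ci: dict | None = None, phi_ci: dict | None = None):
    """Compare each factor's sqrt(AVE) against its factor correlations.

    Returns a DataFrame with one row per ordered (factor, other) pair and a
    ``passes`` flag (sqrt(AVE) >= |phi|).  When CIs are supplied, an
    additional ``ci_overlap`` column notes interval overlap, which the
    criterion prefers to avoid.
    """
    phi = np.asarray(phi, dtype=float)
    labels = list(factor_labels) if factor_labels is not None else list(aves)
    if len(labels) < 2:
        raise ValueError("discriminant validity needs at least two factors")
    if phi.shape != (len(labels), len(labels)):
        raise ValueError("phi dimension does not match the number of factors")
    rows = []
    for a, fa in enumerate(labels):
        sqrt_ave = np.sqrt(aves[fa])
        for b, fb in enumerate(labels):
            if a == b:
                continue
            corr = abs(phi[a, b])
            row = {
                "factor": fa,
                "other": fb,
                "sqrt_ave": sqrt_ave,
                "phi": phi[a, b],
                "passes": bool(sqrt_ave >= corr),
            }
            if sqrt_ave_ci is not None and phi_ci is not None:
                lo_s, hi_s = sqrt_ave_ci[fa]
                lo_p, hi_p = phi_ci[tuple(sorted((fa, fb)))]
                row["ci_overlap"] = bool(max(lo_s, lo_p) <= min(hi_s, hi_p))
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidityReport:
    """Per-factor AVE / sqrt(AVE) with bootstrap CIs and the F-L table."""

    ave: dict
    sqrt_ave: dict
    ave_ci: dict
    sqrt_ave_ci: dict
    phi: np.ndarray
    phi_ci: dict
    factor_labels: tuple
    comparisons: pd.DataFrame
    convergent: dict
    n_replicates: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for fac in self.factor_labels:
            rows.append({
                "factor": fac, "quantity": "ave", "estimate": self.ave[fac],
                "ci_low": self.ave_ci[fac][0], "ci_high": self.ave_ci[fac][1],
            })
            rows.append({
                "factor": fac, "quantity": "sqrt_ave", "estimate": self.sqrt_ave[fac],
                "ci_low": self.sqrt_ave_ci[fac][0], "ci_high": self.sqrt_ave_ci[fac][1],
            })
        for (fa, fb), (lo, hi) in self.phi_ci.items():
            a = self.factor_labels.index(fa)
            b = self.factor_labels.index(fb)
            rows.append({
                "factor": f"{fa}<->{fb}", "quantity": "phi",
                "estimate": self.phi[a, b], "ci_low": lo, "ci_high": hi,
            })
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "convergent": self.convergent,
            "discriminant_failures": [
                f"{r.factor} vs {r.other}"
                for r in self.comparisons.itertuples()
                if not r.passes
            ],
            "n_replicates": self.n_replicates,
            "n_failed": self.n_failed,
        }


def _factor_blocks(spec: ModelSpec):
    """Map each factor to the items loading (only) on it; congeneric check."""
    if spec.general_col is not None or spec.exploratory:
        raise ValueError("AVE-based validity expects a congeneric CFA spec")
    if np.any(spec.pattern.sum(axis=1) != 1):
        raise ValueError("AVE-based validity expects each item on exactly one factor")
    return {
        fac: np.where(spec.pattern[:, k])[0]
        for k, fac in enumerate(spec.factor_labels)
    }


def bootstrap_validity(
    matrix: ItemResponseMatrix,
    spec: ModelSpec,
    B: int = 1000,
    seed: int = 0,
    max_failure_rate: float = 0.20,
) -> ValidityReport:
    """Percentile bootstrap CIs for AVE, sqrt(AVE) and factor correlations.

    Respondents are resampled with replacement; each replicate reruns
    thresholds + polychoric correlations and refits the CFA starting from
    the full-sample solution.  Replicate weights reuse the full-sample
    asymptotic variances (ancillary to the point estimates).  Failed
    replicates are dropped and counted; more than ``max_failure_rate`` of
    them is an error.
    """
    if B < 50:
        raise ValueError("B must be at least 50")
    blocks = _factor_blocks(spec)
    stats = polychoric_matrix(matrix)
    base_solution, _ = fit_model(spec, stats, compute_fit=False)
    if not base_solution.converged:
        raise RuntimeError("full-sample CFA did not converge; bootstrap aborted")
    point = _validity_point(base_solution, blocks)

    rng = np.random.default_rng(seed)
    draws = []
    n_failed = 0
    base_acov = stats.acov
    for _ in range(B):
        idx = rng.integers(0, matrix.n, size=matrix.n)
        resampled = ItemResponseMatrix(matrix.values[idx], matrix.item_labels)
        try:
            rep_stats = polychoric_matrix(resampled, compute_acov=False)
            rep_stats = _with_acov(rep_stats, base_acov)
            sol, _ = fit_model(spec, rep_stats, start=base_solution.params,
                               compute_fit=False)
            if not sol.converged:
                raise RuntimeError("replicate non-convergence")
            draws.append(_validity_point(sol, blocks))
        except (ValueError, RuntimeError) as exc:
            n_failed += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if n_failed > max_failure_rate * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed (> {max_failure_rate:.0%})"
        )

    labels = spec.factor_labels
    ave_ci, sqrt_ci, phi_ci = {}, {}, {}
    for fac in labels:
        vals = np.array([d["ave"][fac] for d in draws])
        ave_ci[fac] = tuple(np.percentile(vals, [2.5, 97.5]))
        sqrt_ci[fac] = tuple(np.percentile(np.sqrt(vals), [2.5, 97.5]))
    for a in range(len(labels)):
        for b in range(a + 1, len(labels)):
            vals = np.array([d["phi"][a, b] for d in draws])
            phi_ci[(labels[a], labels[b])] = tuple(np.percentile(vals, [2.5, 97.5]))

    sqrt_ave = {fac: float(np.sqrt(point["ave"][fac])) for fac in labels}
    comparisons = fornell_larcker(
        point["ave"], point["phi"], labels, sqrt_ave_ci=sqrt_ci, phi_ci=phi_ci
    )
    return ValidityReport(
        ave=point["ave"],
        sqrt_ave=sqrt_ave,
        ave_ci=ave_ci,
        sqrt_ave_ci=sqrt_ci,
        phi=point["phi"],
        phi_ci=phi_ci,
        factor_labels=labels,
        comparisons=comparisons,
        convergent={
            fac: bool(point["ave"][fac] >= CONVERGENT_THRESHOLD) for fac in labels
        },
        n_replicates=B - n_failed,
        n_failed=n_failed,
    )


def _with_acov(stats, acov):
    from dataclasses import replace

    return replace(stats, acov=acov)


def _validity_point(solution: FactorSolution, blocks: dict):
    aves = {}
    for k, fac in enumerate(solution.factor_labels):
        lam = solution.loadings[blocks[fac], k]
        aves[fac] = ave(np.clip(lam, -1.0, 1.0))
    return {"ave": aves, "phi": solution.phi.copy()}


# ---------------------------------------------------------------------------
# Bifactor variance partition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariancePartition:
    """Squared-loading accounting of observed variance in a bifactor model.

    All percentages are of the total observed variance with each item
    contributing equally (100/J per item).
    """

    table: pd.DataFrame  # per item: pct_general, pct_specific, pct_error
    factor_totals: dict
    general_total: float
    specific_total: float
    error_total: float
    explained_total: float
    g_share_of_explained: float


def variance_partition(solution: FactorSolution) -> VariancePartition:
    """Partition variance from a fitted orthogonal bifactor solution."""
    spec = solution.spec
    if spec.general_col is None:
        raise ValueError("variance partition requires a bifactor solution")
    if spec.factor_cov != "orthogonal" or not np.allclose(solution.phi, np.eye(spec.n_factors)):
        raise ValueError("variance partition requires orthogonal factors")
    g = spec.general_col
    specific_cols = [k for k in range(spec.n_factors) if k != g]
    return variance_partition_from_loadings(
        solution.loadings[:, g],
        solution.loadings[:, specific_cols],
        item_labels=spec.item_labels,
        factor_labels=[spec.factor_labels[k] for k in specific_cols],
    )


def variance_partition_from_loadings(
    g_loadings, specific_loadings, item_labels=None, factor_labels=None
) -> VariancePartition:
    """Variance partition from standardized bifactor loadings.

    Residual shares are 1 minus the squared-loading communality, so the
    three per-item shares add exactly to that item's equal slice of the
    total; the headline ratio is the general factor's share of all
    *explained* variance, 100 * sum(lambda_g^2) / sum(all lambda^2).
    """
    g = np.asarray(g_loadings, dtype=float)
    S = np.atleast_2d(np.asarray(specific_loadings, dtype=float))
    if S.shape[0] != g.shape[0]:
        S = S.T
    J = g.shape[0]
    item_labels = list(item_labels) if item_labels else [f"i{j + 1}" for j in range(J)]
    factor_labels = (
        list(factor_labels) if factor_labels else [f"f{k + 1}" for k in range(S.shape[1])]
    )
    g2 = g**2
    s2 = S**2
    err = 1.0 - g2 - s2.sum(axis=1)
    unit = 100.0 / J
    table = pd.DataFrame(
        {
            "item": item_labels,
            **{
                f"pct_{fac}": s2[:, k] * unit for k, fac in enumerate(factor_labels)
            },
            "pct_general": g2 * unit,
            "pct_error": err * unit,
        }
    )
    g_total = float(g2.sum() * unit)
    spec_total = float(s2.sum() * unit)
    err_total = float(err.sum() * unit)
    factor_totals = {fac: float(s2[:, k].sum() * unit) for k, fac in enumerate(factor_labels)}
    explained = g_total + spec_total
    g_share = 100.0 * g_total / explained if explained > 0 else np.nan
    return VariancePartition(
        table=table,
        factor_totals=factor_totals,
        general_total=g_total,
        specific_total=spec_total,
        error_total=err_total,
        explained_total=explained,
        g_share_of_explained=g_share,
    )
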
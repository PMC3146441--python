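"""Shared fixtures: reference specs and multi-seed simulation runs.

The multi-seed runs are session-scoped because several property tests look
at different aspects of the same simulated fits (fit indices, factor
correlations, difference tests, score correlations, scalability).
"""

from __future__ import annotations

import numpy as np
import pytest

from ordscale import (
    EPDS_ITEM_SETS,
    bifactor_spec,
    cfa_spec,
    epds_spec,
    fit_exploratory,
    fit_model,
    generate_responses,
    loevinger_h,
    one_factor_spec,
    polychoric_matrix,
    score_table,
)

SEEDS20 = tuple(range(101, 121))


@pytest.fixture(scope="session")
def model_c_spec():
    """Three-correlated-factor generating spec, quartile thresholds."""
    return epds_spec("three_factor", "symmetric", n=811)


@pytest.fixture(scope="session")
def model_d_spec():
    """Bifactor generating spec, quartile thresholds."""
    return epds_spec("bifactor", "symmetric", n=811)


@pytest.fixture(scope="session")
def calibrated_d_spec():
    """Bifactor spec with thresholds calibrated to the reference moments."""
    return epds_spec("bifactor", "calibrated", n=811)


@pytest.fixture(scope="session")
def model_c_runs(model_c_spec):
    """Twenty seeds of n=811 three-factor data with 1f/3f CFA and 2/3f E/CFA."""
    labels = model_c_spec.item_labels
    runs = []
    for seed in SEEDS20:
        matrix = generate_responses(model_c_spec.replace(seed=seed))
        stats = polychoric_matrix(matrix)
        sol1, fit1 = fit_model(one_factor_spec(labels), stats)
        sol3, fit3 = fit_model(cfa_spec(EPDS_ITEM_SETS, labels), stats)
        e2, ef2 = fit_exploratory(stats, 2, seed=seed)
        e3, ef3 = fit_exploratory(stats, 3, seed=seed)
        runs.append(
            {
                "seed": seed,
                "matrix": matrix,
                "stats": stats,
                "one_factor": (sol1, fit1),
                "three_factor": (sol3, fit3),
                "ecfa2": (e2, ef2),
                "ecfa3": (e3, ef3),
            }
        )
    return runs


@pytest.fixture(scope="session")
def model_d_runs(calibrated_d_spec):
    """Twenty seeds of calibrated bifactor data with fits, scores and H."""
    labels = calibrated_d_spec.item_labels
    runs = []
    for seed in SEEDS20:
        matrix = generate_responses(calibrated_d_spec.replace(seed=seed))
        stats = polychoric_matrix(matrix)
        sol_d, fit_d = fit_model(bifactor_spec(EPDS_ITEM_SETS, labels), stats)
        sol_c, fit_c = fit_model(cfa_spec(EPDS_ITEM_SETS, labels), stats)
        scores = score_table(matrix, sol_d, EPDS_ITEM_SETS)
        runs.append(
            {
                "seed": seed,
                "matrix": matrix,
                "stats": stats,
                "bifactor": (sol_d, fit_d),
                "three_factor": (sol_c, fit_c),
                "r_g_total": float(scores.correlations.loc["score_g", "raw_total"]),
                "H": loevinger_h(matrix, se=False).H,
            }
        )
    return runs


@pytest.fixture(scope="session")
def model_d_recovery(model_d_spec):
    """Twenty seeds of symmetric-threshold bifactor fits for loading recovery."""
    labels = model_d_spec.item_labels
    out = []
    for seed in SEEDS20:
        matrix = generate_responses(model_d_spec.replace(seed=seed))
        stats = polychoric_matrix(matrix)
        sol, _ = fit_model(bifactor_spec(EPDS_ITEM_SETS, labels), stats)
        out.append(sol)
    return out


@pytest.fixture
def guttman_matrix():
    """Deterministic error-free Guttman (cumulative) polytomous data."""

    def build(n=60, j=4):
        from ordscale import ItemResponseMatrix

        trait = np.linspace(0, 1, n)
        cuts = np.linspace(0.1, 0.9, 3 * j).reshape(j, 3)
        vals = np.stack(
            [(trait[:, None] > cuts[item]).sum(axis=1) for item in range(j)], axis=1
        )
        return ItemResponseMatrix(vals)

    return build
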
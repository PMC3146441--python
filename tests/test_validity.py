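"""AVE arithmetic, Fornell-Larcker logic, bootstrap CIs, variance partition."""

import numpy as np
import pytest

from ordscale import (
    EPDS_ITEM_SETS,
    ItemResponseMatrix,
    ave,
    bootstrap_validity,
    cfa_spec,
    epds_spec,
    fornell_larcker,
    generate_responses,
    variance_partition,
    variance_partition_from_loadings,
)


class TestAve:
    @pytest.mark.parametrize(
        "loadings, expected",
        [
            ((0.60, 0.61, 0.74), 0.43),
            ((0.84, 0.83, 0.84, 0.70), 0.65),
            ((1.0, 1.0, 1.0), 1.00),
        ],
    )
    def test_known_values(self, loadings, expected):
        assert round(ave(loadings), 2) == expected

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            ave([])

    def test_equals_brute_force_on_implied_covariance(self):
        """AVE equals explained/total variance of the congeneric block."""
        spec = epds_spec("three_factor", "symmetric")
        for k, items in enumerate(EPDS_ITEM_SETS.values()):
            idx = [spec.item_labels.index(i) for i in items]
            lam = spec.loadings[idx, k]
            sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
            explained = np.sum(lam**2)
            assert ave(lam) == pytest.approx(explained / np.trace(sigma))


class TestFornellLarcker:
    def test_weak_factor_fails_both_comparisons(self):
        aves = {"f1": 0.56, "f2": 0.43, "f3": 0.65}
        phi = np.array([[1.0, 0.74, 0.80], [0.74, 1.0, 0.81], [0.80, 0.81, 1.0]])
        table = fornell_larcker(aves, phi, ["f1", "f2", "f3"])
        f2 = table[table["factor"] == "f2"]
        assert not f2["passes"].any()  # sqrt(.43)=.656 < .74 and < .81

    def test_orthogonal_factors_all_pass(self):
        table = fornell_larcker({"a": 0.4, "b": 0.4}, np.eye(2), ["a", "b"])
        assert table["passes"].all()

    def test_unit_ave_always_passes(self):
        phi = np.array([[1.0, 0.95], [0.95, 1.0]])
        table = fornell_larcker({"a": 1.0, "b": 1.0}, phi, ["a", "b"])
        assert table["passes"].all()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fornell_larcker({"a": 0.5, "b": 0.5}, np.eye(3), ["a", "b"])


class TestBootstrap:
    def test_determinism_under_fixed_seed(self, model_c_runs):
        matrix = model_c_runs[0]["matrix"]
        spec = cfa_spec(EPDS_ITEM_SETS, matrix.item_labels)
        a = bootstrap_validity(matrix, spec, B=60, seed=5)
        b = bootstrap_validity(matrix, spec, B=60, seed=5)
        assert a.ave_ci == b.ave_ci and a.phi_ci == b.phi_ci

    def test_sqrt_column_is_square_root(self, model_c_runs):
        matrix = model_c_runs[0]["matrix"]
        spec = cfa_spec(EPDS_ITEM_SETS, matrix.item_labels)
        rep = bootstrap_validity(matrix, spec, B=60, seed=6)
        for fac in rep.factor_labels:
            assert rep.sqrt_ave[fac] == pytest.approx(np.sqrt(rep.ave[fac]), abs=1e-12)

    def test_ci_covers_generating_ave(self, model_c_spec):
        """95% bootstrap CI for AVE_f3 covers the generating value."""
        true_f3 = ave(model_c_spec.loadings[6:, 2])
        spec = cfa_spec(EPDS_ITEM_SETS, model_c_spec.item_labels)
        covered = []
        for seed in range(210, 220):
            matrix = generate_responses(model_c_spec.replace(seed=seed))
            rep = bootstrap_validity(matrix, spec, B=200, seed=seed)
            lo, hi = rep.ave_ci["f3"]
            covered.append(lo <= true_f3 <= hi)
        assert np.mean(covered) >= 0.90

    def test_intervals_widen_with_smaller_n(self, model_c_spec):
        spec = cfa_spec(EPDS_ITEM_SETS, model_c_spec.item_labels)
        small = generate_responses(model_c_spec.replace(n=200, seed=31))
        large = generate_responses(model_c_spec.replace(n=811, seed=31))
        rep_s = bootstrap_validity(small, spec, B=60, seed=1)
        rep_l = bootstrap_validity(large, spec, B=60, seed=1)
        widths_s = [rep_s.ave_ci[f][1] - rep_s.ave_ci[f][0] for f in rep_s.factor_labels]
        widths_l = [rep_l.ave_ci[f][1] - rep_l.ave_ci[f][0] for f in rep_l.factor_labels]
        assert np.median(widths_s) / np.median(widths_l) > 1.0

    def test_degenerate_input_fails_or_reports_failures(self):
        # five respondents: resampling routinely produces constant items,
        # so the run either aborts or reports failed replicates
        vals = np.tile([0, 1, 2, 3, 0], (10, 1)).T[:5]
        matrix = ItemResponseMatrix(vals)
        spec = cfa_spec(EPDS_ITEM_SETS, matrix.item_labels)
        try:
            rep = bootstrap_validity(matrix, spec, B=50, seed=0)
        except (RuntimeError, ValueError):
            return
        assert rep.n_failed > 0

    def test_small_b_rejected(self, model_c_runs):
        matrix = model_c_runs[0]["matrix"]
        spec = cfa_spec(EPDS_ITEM_SETS, matrix.item_labels)
        with pytest.raises(ValueError):
            bootstrap_validity(matrix, spec, B=10, seed=0)


class TestVariancePartition:
    def test_reference_bifactor_g_share(self):
        """General factor's share of explained variance from reference loadings."""
        spec = epds_spec("bifactor", "symmetric")
        part = variance_partition_from_loadings(
            spec.loadings[:, 0], spec.loadings[:, 1:], item_labels=spec.item_labels
        )
        assert part.g_share_of_explained == pytest.approx(79.2, abs=0.5)

    def test_zero_specific_loadings_give_full_g_share(self):
        part = variance_partition_from_loadings(
            np.full(6, 0.7), np.zeros((6, 2))
        )
        assert part.g_share_of_explained == pytest.approx(100.0)

    def test_equal_loadings_split_evenly(self):
        lam = np.full(6, 0.5)
        part = variance_partition_from_loadings(lam, lam.reshape(-1, 1))
        assert part.g_share_of_explained == pytest.approx(50.0)

    def test_item_shares_sum_to_equal_slice(self):
        spec = epds_spec("bifactor", "symmetric")
        part = variance_partition_from_loadings(
            spec.loadings[:, 0], spec.loadings[:, 1:], item_labels=spec.item_labels
        )
        cols = [c for c in part.table.columns if c.startswith("pct_")]
        row_sums = part.table[cols].sum(axis=1)
        np.testing.assert_allclose(row_sums, 10.0, atol=0.5)

    def test_non_orthogonal_solution_rejected(self, model_c_runs):
        sol3 = model_c_runs[0]["three_factor"][0]
        with pytest.raises(ValueError):
            variance_partition(sol3)

    def test_fitted_bifactor_partition(self, model_d_runs):
        part = variance_partition(model_d_runs[0]["bifactor"][0])
        assert 0 < part.g_share_of_explained < 100
        assert part.explained_total + part.error_total == pytest.approx(100.0, abs=0.5)
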
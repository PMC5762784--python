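"""TPM normalisation, fold change, Fisher testing, BH and DE calling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mirprof as m
from mirprof.de import NS, DEThresholds


def toy_matrix() -> m.CountMatrix:
    counts = pd.DataFrame(
        {
            "CK": [100, 0, 113],
            "L1": [200, 10, 113],
            "L2": [50, 0, 113],
        },
        index=["m1", "m2", "m3"],
    )
    sizes = pd.Series({"CK": 1_000_000, "L1": 1_000_000, "L2": 10_373_946},
                      name="lib_size")
    return m.CountMatrix(counts=counts, lib_sizes=sizes)


class TestTPM:
    def test_formula(self):
        tpm = m.tpm_normalize(toy_matrix())
        assert tpm.loc["m1", "CK"] == pytest.approx(100.0)
        assert tpm.loc["m2", "CK"] == 0.0
        assert tpm.loc["m3", "L2"] == pytest.approx(113 * 1e6 / 10_373_946)

    def test_zero_libsize_fails(self):
        matrix = toy_matrix()
        matrix.lib_sizes["CK"] = 0
        with pytest.raises(ValueError, match="CK"):
            m.tpm_normalize(matrix)


class TestGroupMeans:
    def test_flat_and_skewed_means(self):
        tpm = pd.DataFrame(
            {lib: [10.0] for lib in ["CK", "L1", "L2", "L3", "L4", "L5", "L6"]},
            index=["m1"],
        )
        spec = m.GroupSpec(control_libs=["CK"],
                           treatment_libs=[f"L{i}" for i in range(1, 7)])
        means = m.group_mean_tpm(tpm, spec)
        assert means.loc["m1", "group_tpm"] == pytest.approx(10.0)
        tpm.loc["m1", ["L1", "L2", "L3", "L4", "L5"]] = 0.0
        tpm.loc["m1", "L6"] = 60.0
        means = m.group_mean_tpm(tpm, spec)
        assert means.loc["m1", "group_tpm"] == pytest.approx(10.0)

    def test_matches_brute_force_on_random_matrix(self):
        rng = np.random.default_rng(0)
        libs = ["CK1", "CK2", "L1", "L2", "L3"]
        tpm = pd.DataFrame(rng.uniform(0, 100, size=(20, 5)), columns=libs)
        spec = m.GroupSpec(control_libs=["CK1", "CK2"],
                           treatment_libs=["L1", "L2", "L3"])
        means = m.group_mean_tpm(tpm, spec)
        for i in range(20):
            assert means.iloc[i]["group_tpm"] == pytest.approx(
                sum(tpm.iloc[i][l] for l in spec.treatment_libs) / 3)
            assert means.iloc[i]["ck_tpm"] == pytest.approx(
                sum(tpm.iloc[i][l] for l in spec.control_libs) / 2)

    def test_unknown_library_fails(self):
        tpm = pd.DataFrame({"CK": [1.0]}, index=["m1"])
        spec = m.GroupSpec(control_libs=["CK"], treatment_libs=["L1"])
        with pytest.raises(ValueError, match="L1"):
            m.group_mean_tpm(tpm, spec)


class TestFoldChange:
    @pytest.mark.parametrize(
        "group,ck,expected",
        [
            (119.39, 11.00, 119.39 / 11.00),
            (22.40, 71.49, 22.40 / 71.49),
            (42.0, 42.0, 1.0),
            (0.0, 50.0, 0.01 / 50.0),
            (50.0, 0.0, 50.0 / 0.01),
            (0.0, 0.0, 1.0),
        ],
    )
    def test_values(self, group, ck, expected):
        assert m.fold_change(group, ck) == pytest.approx(expected)

    def test_negative_input_fails(self):
        with pytest.raises(ValueError):
            m.fold_change(-1.0, 5.0)

    def test_always_positive_and_finite(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            fc = m.fold_change(rng.uniform(0, 1000), rng.uniform(0, 1000))
            assert 0 < fc < np.inf


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        counts = pd.DataFrame({"CK": [10], "L1": [10]}, index=["m1"])
        sizes = pd.Series({"CK": 1000, "L1": 1000}, name="lib_size")
        matrix = m.CountMatrix(counts=counts, lib_sizes=sizes)
        spec = m.GroupSpec(control_libs=["CK"], treatment_libs=["L1"])
        assert m.test_counts(matrix, spec)["m1"] == pytest.approx(1.0)

    def test_both_zero_gives_p_one(self):
        counts = pd.DataFrame({"CK": [0], "L1": [0]}, index=["m1"])
        sizes = pd.Series({"CK": 1000, "L1": 1000}, name="lib_size")
        matrix = m.CountMatrix(counts=counts, lib_sizes=sizes)
        spec = m.GroupSpec(control_libs=["CK"], treatment_libs=["L1"])
        assert m.test_counts(matrix, spec)["m1"] == 1.0

    def test_matches_hypergeometric_tail_enumeration(self):
        """Two-sided Fisher p equals summing hypergeometric outcome
        probabilities no larger than the observed one, on fixed margins."""
        a, b, c, d = 10, 999_990, 0, 1_000_000
        counts = pd.DataFrame({"CK": [c], "L1": [a]}, index=["m1"])
        sizes = pd.Series({"CK": c + d, "L1": a + b}, name="lib_size")
        matrix = m.CountMatrix(counts=counts, lib_sizes=sizes)
        spec = m.GroupSpec(control_libs=["CK"], treatment_libs=["L1"])
        p = m.test_counts(matrix, spec)["m1"]

        total = a + b + c + d
        k_total = a + c
        n_row = a + b
        support = np.arange(0, k_total + 1)
        pmf = stats.hypergeom.pmf(support, total, k_total, n_row)
        p_oracle = pmf[pmf <= pmf[a] * (1 + 1e-7)].sum()
        assert p == pytest.approx(p_oracle, rel=1e-6)


class TestBH:
    def test_single_p_unchanged(self):
        assert m.adjust_bh([0.2]) == pytest.approx([0.2])

    def test_hand_worked_step_up(self):
        # 0.01*3/1 = 0.03, 0.02*3/2 = 0.03, 0.03*3/3 = 0.03
        assert m.adjust_bh([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(1e-6, 1, 30)
        perm = rng.permutation(30)
        direct = m.adjust_bh(p)[perm]
        permuted = m.adjust_bh(p[perm])
        np.testing.assert_allclose(direct, permuted)

    def test_dominates_raw_and_capped_at_one(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(1e-9, 1, 100)
        adj = m.adjust_bh(p)
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.uniform(1e-12, 1, int(rng.integers(1, 80)))
            _, expected, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(m.adjust_bh(p), expected, rtol=1e-10)

    def test_empty_list(self):
        assert len(m.adjust_bh([])) == 0


class TestCallDE:
    def _call_published(self, thresholds=None):
        table = m.reference_de_table()
        means = table[["group_tpm", "ck_tpm"]]
        p = table["corrected_p"]
        return m.call_de(means, p, p, thresholds)

    def test_published_rows_all_called_with_printed_directions(self):
        calls = self._call_published()
        expected = m.reference_de_table()["direction"]
        assert (calls["direction"] == expected).all()
        assert (calls["direction"] == "UP").sum() == 7
        assert (calls["direction"] == "DOWN").sum() == 14

    def test_boundary_row_uses_unrounded_fold_change(self):
        # 55.07/27.50 = 2.0025... > 2 even though it prints as 2.00
        calls = self._call_published()
        assert calls.loc["miR1870-3p", "fold_change"] > 2.0
        assert calls.loc["miR1870-3p", "direction"] == "UP"

    def test_expression_floor_passes_via_either_group(self):
        # treatment TPM 16.25 < 30, control 33.00 > 30: still eligible
        calls = self._call_published()
        assert calls.loc["miR2118e", "direction"] == "DOWN"

    def test_misaligned_ids_fail(self):
        table = m.reference_de_table()
        means = table[["group_tpm", "ck_tpm"]]
        p = table["corrected_p"].iloc[:-1]
        with pytest.raises(ValueError, match="ids"):
            m.call_de(means, p, p)

    def test_threshold_monotonicity(self):
        def n_calls(thresholds):
            calls = self._call_published(thresholds)
            return int((calls["direction"] != NS).sum())

        base = n_calls(DEThresholds())
        assert n_calls(DEThresholds(max_adj_p=0.01)) <= base
        assert n_calls(DEThresholds(fc_up=3.0, fc_down=0.3)) <= base

    def test_null_simulation_has_no_calls(self, small_reference):
        cfg = m.SimConfig(n_mirnas=50, reads_per_library=50_000, seed=13)
        matrix, _ = m.simulate_counts(small_reference, cfg)
        spec = m.GroupSpec(control_libs=cfg.control_libraries,
                           treatment_libs=cfg.treatment_libraries)
        de = m.differential_expression(matrix, spec)
        assert (de["direction"] == NS).all()


class TestSummary:
    def test_unchanged_count(self):
        calls = m.call_de(
            m.reference_de_table()[["group_tpm", "ck_tpm"]],
            m.reference_de_table()["corrected_p"],
            m.reference_de_table()["corrected_p"],
        )
        summary = m.summarize_calls(calls, n_detected=m.CONSERVED_MIRNAS_DETECTED)
        assert summary["total_de"] == 21
        assert summary["unchanged"] == 547
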
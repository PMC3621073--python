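import numpy as np
import pandas as pd
import pytest

from camta_drought import (ContrastSpec, ExpressionMatrix, SAMParams, call_de,
                           log2_fold_change, permutation_pq, sam_d_statistic,
                           signed_linear_fc)
from camta_drought.diffexpr import _d_from_groups, _distinct_assignments

from conftest import make_design


def matrix_from_groups(drought, control, design, tissue="LEAF", genotype="WT"):
    """Build a matrix whose WT leaf cells hold the given per-gene replicate
    values; every other cell is filled with the control values."""
    drought = np.atleast_2d(drought).astype(float)
    control = np.atleast_2d(control).astype(float)
    n_genes = drought.shape[0]
    cols = design.sample_ids
    data = np.zeros((n_genes, len(cols)))
    d_cols = design.samples_for(tissue, genotype, "DROUGHT")
    c_cols = design.samples_for(tissue, genotype, "CONTROL")
    for j, col in enumerate(cols):
        if col in d_cols:
            data[:, j] = drought[:, d_cols.index(col)]
        elif col in c_cols:
            data[:, j] = control[:, c_cols.index(col)]
        else:
            data[:, j] = control[:, 0]
    return ExpressionMatrix(pd.DataFrame(
        data, index=[f"g{i}" for i in range(n_genes)], columns=cols))


CONTRAST = ContrastSpec("LEAF", "WT")


class TestFoldChange:
    def test_exact_arithmetic(self, small_design):
        m = matrix_from_groups([[9, 9, 9]], [[8, 8, 8]], small_design)
        fc = log2_fold_change(m, small_design, CONTRAST)
        assert fc.iloc[0] == pytest.approx(1.0)
        assert signed_linear_fc(fc)[0] == pytest.approx(2.0)

    def test_equal_means_zero(self, small_design):
        m = matrix_from_groups([[8, 9, 7]], [[9, 8, 7]], small_design)
        fc = log2_fold_change(m, small_design, CONTRAST)
        assert fc.iloc[0] == pytest.approx(0.0)
        assert signed_linear_fc(fc)[0] == pytest.approx(1.0)

    def test_matches_two_loop_recomputation(self, small_matrix, small_design):
        fc = log2_fold_change(small_matrix, small_design, CONTRAST)
        d_cols = small_design.samples_for("LEAF", "WT", "DROUGHT")
        c_cols = small_design.samples_for("LEAF", "WT", "CONTROL")
        for gene in small_matrix.gene_ids:
            acc_d = sum(small_matrix.values.loc[gene, c] for c in d_cols)
            acc_c = sum(small_matrix.values.loc[gene, c] for c in c_cols)
            expected = acc_d / len(d_cols) - acc_c / len(c_cols)
            assert fc[gene] == pytest.approx(expected)

    def test_signed_linear_convention(self):
        np.testing.assert_allclose(signed_linear_fc(np.array([1.0, -1.0, 0.0])),
                                   [2.0, -2.0, 1.0])


class TestDStatistic:
    def test_hand_computed_pooled_se(self, small_design):
        # x=(1,2,3) vs y=(3,4,5): pooled var 1, SE = sqrt(2/3), d = -2/SE
        m = matrix_from_groups([[1, 2, 3]], [[3, 4, 5]], small_design)
        d, s0 = sam_d_statistic(m, small_design, CONTRAST, s0=0.0)
        assert d.iloc[0] == pytest.approx(-2.0 / np.sqrt(2.0 / 3.0), abs=1e-3)
        assert d.iloc[0] == pytest.approx(-2.449, abs=1e-3)

    def test_identical_means_give_zero(self, small_design):
        m = matrix_from_groups([[5, 6, 7]], [[7, 6, 5]], small_design)
        for s0 in (0.0, 0.5, 2.0):
            d, _ = sam_d_statistic(m, small_design, CONTRAST, s0=s0)
            assert d.iloc[0] == pytest.approx(0.0)

    def test_abs_d_monotone_decreasing_in_s0(self, small_matrix, small_design):
        prev = None
        for s0 in (0.0, 0.1, 0.5, 1.0, 5.0):
            d, _ = sam_d_statistic(small_matrix, small_design, CONTRAST, s0=s0)
            if prev is not None:
                assert (np.abs(d.to_numpy()) <= prev + 1e-12).all()
            prev = np.abs(d.to_numpy())

    def test_zero_variance_flagged_infinite_never_nan(self):
        d = _d_from_groups(np.array([[4.0, 4.0, 4.0]]),
                           np.array([[2.0, 2.0, 2.0]]), s0=0.0)
        assert np.isposinf(d[0])
        d0 = _d_from_groups(np.array([[2.0, 2.0, 2.0]]),
                            np.array([[2.0, 2.0, 2.0]]), s0=0.0)
        assert d0[0] == 0.0

    def test_default_s0_is_median_se(self, small_matrix, small_design):
        _, s0 = sam_d_statistic(small_matrix, small_design, CONTRAST)
        assert s0 > 0


class TestPermutationPQ:
    def test_exhaustive_mode_with_three_reps(self, small_design):
        # C(6,3) = 20 distinct assignments, 19 excluding the observed one
        assert len(_distinct_assignments(3, 3)) == 19
        rng = np.random.default_rng(0)
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(8, 1, (30, 12)),
            index=[f"g{i}" for i in range(30)],
            columns=small_design.sample_ids))
        res = permutation_pq(m, small_design, CONTRAST, SAMParams(seed=1))
        # pooled p-values live on the grid k/(19*30 + 1)
        n_pool = 19 * 30
        k = res["p_value"] * (n_pool + 1)
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)

    def test_d_zero_gene_has_p_one(self, small_design):
        drought = np.vstack([[5, 6, 7], [1, 5, 9]])
        control = np.vstack([[7, 6, 5], [9, 5, 1]])
        m = matrix_from_groups(drought, control, small_design)
        res = permutation_pq(m, small_design, CONTRAST, SAMParams(seed=0))
        n_pool = 19 * 2
        assert res["p_value"].iloc[0] >= 1.0 - 1.0 / (n_pool + 1)

    def test_monte_carlo_agrees_with_exhaustive(self):
        design = make_design(n_reps=5)  # C(10,5)=252 distinct assignments
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(8, 1, (40, len(design.sample_ids))),
            index=[f"g{i}" for i in range(40)], columns=design.sample_ids))
        exact = permutation_pq(m, design, CONTRAST,
                               SAMParams(n_permutations=300, seed=0))
        mc = permutation_pq(m, design, CONTRAST,
                            SAMParams(n_permutations=150, seed=3))
        # binomial error of a proportion from 150*40 pooled draws
        tol = 3 * np.sqrt(0.25 / (150 * 40)) + 0.02
        assert np.max(np.abs(exact["p_value"] - mc["p_value"])) < tol

    def test_q_values_monotone_in_abs_d(self, small_design):
        rng = np.random.default_rng(5)
        m = ExpressionMatrix(pd.DataFrame(
            rng.normal(8, 1, (50, 12)),
            index=[f"g{i}" for i in range(50)],
            columns=small_design.sample_ids))
        res = permutation_pq(m, small_design, CONTRAST, SAMParams(seed=1))
        res = res.reindex(res["d_stat"].abs().sort_values(ascending=False).index)
        assert (np.diff(res["q_value"]) >= -1e-12).all()


class TestCallDE:
    @pytest.mark.parametrize("fc,p,expected", [
        (2.0, 0.05, "UP"),       # boundaries inclusive
        (1.99, 0.001, "NS"),     # below fold gate
        (-2.5, 0.04, "DOWN"),
        (-2.0, 0.05, "DOWN"),
        (3.0, 0.051, "NS"),      # above p gate
        (1.0, 0.5, "NS"),
    ])
    def test_gate_boundaries(self, fc, p, expected):
        log2fc = np.sign(fc) * np.log2(abs(fc)) if fc != 1.0 else 0.0
        table = pd.DataFrame({"gene_id": ["g"], "log2fc": [log2fc],
                              "p_value": [p], "q_value": [p],
                              "d_stat": [1.0]})
        out = call_de(table, SAMParams())
        assert out["call"].iloc[0] == expected

    def test_calls_partition_all_genes(self, leaf_de_tables):
        de_wt, _ = leaf_de_tables
        assert set(de_wt["call"]) <= {"UP", "DOWN", "NS"}
        assert de_wt["call"].notna().all()
        n = len(de_wt)
        assert sum((de_wt["call"] == c).sum() for c in ("UP", "DOWN", "NS")) == n

    def test_fc_linear_invariant(self, leaf_de_tables):
        de_wt, _ = leaf_de_tables
        expected = np.sign(de_wt["log2fc"]) * 2.0 ** np.abs(de_wt["log2fc"])
        expected = np.where(de_wt["log2fc"] == 0, 1.0, expected)
        np.testing.assert_allclose(de_wt["fc_linear"], expected)
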
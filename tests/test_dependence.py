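import numpy as np
import pandas as pd
import pytest

from camta_drought import (ContrastSpec, SimulationConfig, classify_dependence,
                           column_stats, differential_expression,
                           partition_complement, partition_summary,
                           response_ratio, simulate_expression)


def de_table(gene_fc_call):
    """Minimal DE table from (gene, log2fc, call) triples."""
    rows = [{"gene_id": g, "log2fc": fc, "fc_linear": np.sign(fc) * 2 ** abs(fc)
             if fc else 1.0, "d_stat": fc, "p_value": 0.01, "q_value": 0.01,
             "call": call} for g, fc, call in gene_fc_call]
    return pd.DataFrame(rows)


class TestResponseRatio:
    def test_unchanged_response(self):
        wt = de_table([("g1", 2.0, "UP")])
        mut = de_table([("g1", 2.0, "NS")])
        r = response_ratio(wt, mut)
        assert r["rho"].iloc[0] == pytest.approx(1.0)
        assert r["attenuation"].iloc[0] == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        wt = de_table([("g1", 2.0, "UP")])
        mut = de_table([("g1", 0.4, "NS")])
        r = response_ratio(wt, mut)
        assert r["rho"].iloc[0] == pytest.approx(0.2)
        assert r["attenuation"].iloc[0] == pytest.approx(0.8)

    def test_only_wt_significant_genes_kept(self):
        wt = de_table([("g1", 2.0, "UP"), ("g2", 0.1, "NS"),
                       ("g3", -2.0, "DOWN")])
        mut = de_table([("g1", 1.0, "NS"), ("g2", 0.1, "NS"),
                        ("g3", -1.0, "NS")])
        r = response_ratio(wt, mut)
        assert list(r["gene_id"]) == ["g1", "g3"]

    def test_missing_mutant_gene_fatal(self):
        wt = de_table([("g1", 2.0, "UP")])
        mut = de_table([("g2", 1.0, "NS")])
        with pytest.raises(ValueError, match="missing from mutant"):
            response_ratio(wt, mut)

    def test_matches_elementwise_loop(self, leaf_de_tables):
        de_wt, de_mut = leaf_de_tables
        r = response_ratio(de_wt, de_mut).set_index("gene_id")
        wt = de_wt.set_index("gene_id")
        mut = de_mut.set_index("gene_id")
        for gene in r.index:
            rho = mut.loc[gene, "log2fc"] / wt.loc[gene, "log2fc"]
            assert r.loc[gene, "rho"] == pytest.approx(rho)
            assert r.loc[gene, "attenuation"] == pytest.approx(1 - rho)


class TestColumnStats:
    def test_hand_computed_99_ci(self):
        cs = column_stats([1, 2, 3, 4], ci_level=0.99)
        assert cs.mean == pytest.approx(2.5)
        assert cs.sd == pytest.approx(1.2910, abs=1e-4)
        assert cs.sem == pytest.approx(0.6455, abs=1e-4)
        assert cs.ci_low == pytest.approx(-1.271, abs=1e-3)
        assert cs.ci_high == pytest.approx(6.271, abs=1e-3)

    def test_zero_variance_degenerate_interval(self):
        cs = column_stats([3.0, 3.0, 3.0])
        assert cs.ci_low == cs.mean == cs.ci_high == 3.0

    def test_95_ci_strictly_inside_99_ci(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=20)
        cs95 = column_stats(values, 0.95)
        cs99 = column_stats(values, 0.99)
        assert cs99.ci_low < cs95.ci_low and cs95.ci_high < cs99.ci_high

    def test_n_below_two_fatal(self):
        with pytest.raises(ValueError, match="n >= 2"):
            column_stats([1.0])


class TestClassifyDependence:
    def test_all_rho_one_yields_zero_dependent(self):
        genes = [(f"g{i}", 2.0, "UP") for i in range(10)]
        wt = de_table(genes)
        mut = de_table([(g, 2.0, "NS") for g, _, _ in genes])
        cls = classify_dependence(wt, mut)
        assert cls.counts["CDPRG"] == 0 and cls.counts["CDNRG"] == 0
        assert cls.counts["CIDIG"] == 10

    def test_empty_wt_set_warns_not_errors(self):
        wt = de_table([("g1", 0.1, "NS")])
        mut = de_table([("g1", 0.1, "NS")])
        with pytest.warns(UserWarning, match="empty"):
            cls = classify_dependence(wt, mut)
        assert len(cls.table) == 0
        assert sum(cls.counts.values()) == 0

    def test_partition_identities(self, leaf_de_tables):
        de_wt, de_mut = leaf_de_tables
        cls = classify_dependence(de_wt, de_mut, tissue="LEAF")
        c = cls.counts
        n_up = (de_wt["call"] == "UP").sum()
        n_down = (de_wt["call"] == "DOWN").sum()
        assert c["CDPRG"] + c["CIDIG"] == n_up
        assert c["CDNRG"] + c["CIDRG"] == n_down
        labels = set(cls.table["class_label"])
        assert labels <= {"CDPRG", "CDNRG", "CIDIG", "CIDRG"}

    def test_lower_ci_level_never_fewer_dependent(self, leaf_de_tables):
        de_wt, de_mut = leaf_de_tables
        n99 = sum(classify_dependence(de_wt, de_mut, 0.99).counts[c]
                  for c in ("CDPRG", "CDNRG"))
        n95 = sum(classify_dependence(de_wt, de_mut, 0.95).counts[c]
                  for c in ("CDPRG", "CDNRG"))
        assert n95 >= n99

    def test_recovers_planted_dependent_genes(self, leaf_simulation,
                                              leaf_de_tables):
        _, _, _, truth = leaf_simulation
        de_wt, de_mut = leaf_de_tables
        cls = classify_dependence(de_wt, de_mut, tissue="LEAF")
        called = set(cls.genes_of_class("CDPRG", "CDNRG"))
        dep = truth.dependent_genes
        others = set(truth.genes.index) - dep
        sensitivity = len(called & dep) / len(dep)
        specificity = 1 - len(called & others) / len(others)
        assert sensitivity >= 0.95
        assert specificity >= 0.95

    def test_planted_attenuation_recovered(self):
        config = SimulationConfig(n_genes=800, seed=21, attenuation=0.4,
                                  tissues=("LEAF",))
        matrix, design, truth = simulate_expression(config)
        de_wt = differential_expression(matrix, design,
                                        ContrastSpec("LEAF", "WT"))
        de_mut = differential_expression(matrix, design,
                                         ContrastSpec("LEAF", "MUT"))
        ratios = response_ratio(de_wt, de_mut).set_index("gene_id")
        dep = [g for g in truth.dependent_genes if g in ratios.index]
        kappa_hat = np.median(1.0 - ratios.loc[dep, "attenuation"])
        assert abs(kappa_hat - 0.4) <= 0.1

    def test_opposite_regulation_counts_as_dependent(self):
        genes = [(f"g{i}", 2.0, "UP") for i in range(20)]
        wt = de_table(genes)
        mut_fc = [2.0] * 19 + [-1.0]  # one gene flips sign in the mutant
        mut = de_table([(f"g{i}", fc, "NS") for i, fc in enumerate(mut_fc)])
        cls = classify_dependence(wt, mut)
        assert cls.class_map()["g19"] == "CDPRG"

    def test_percentile_method_available(self, leaf_de_tables):
        de_wt, de_mut = leaf_de_tables
        cls = classify_dependence(de_wt, de_mut, method="percentile")
        assert sum(cls.counts.values()) == len(cls.table)


class TestPartitionSummary:
    @pytest.mark.parametrize("total,dependent,expected", [
        (1042, 796, 246),   # leaf up
        (1225, 934, 291),   # leaf down
        (2152, 1192, 960),  # root up
        (1962, 881, 1081),  # root down
    ])
    def test_published_complements(self, total, dependent, expected):
        assert partition_complement(total, dependent) == expected

    def test_summary_satisfies_identities(self, leaf_de_tables):
        de_wt, de_mut = leaf_de_tables
        cls = classify_dependence(de_wt, de_mut, tissue="LEAF")
        s = partition_summary(cls)
        row = s.iloc[0]
        assert row["CDPRG"] + row["CIDIG"] == row["wt_up"]
        assert row["CDNRG"] + row["CIDRG"] == row["wt_down"]
        assert row["total"] == row["wt_up"] + row["wt_down"]

    def test_empty_input_all_zero(self):
        s = partition_summary([])
        assert (s[["CDPRG", "CDNRG", "CIDIG", "CIDRG", "total"]].iloc[0] == 0).all()
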
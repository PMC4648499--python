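"""Differential expression and the component permutation test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosspath.diffexpr import (
    component_permutation_test,
    count_de_components,
    de_test,
    union_deg,
)
from crosspath.iocore import ComponentDefinition, ExpressionMatrix, GenePanel
from crosspath.synthgen import SynthConfig, generate_expression, generate_network


def make_expr(values, n_case, n_ctrl, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = [f"c{i}" for i in range(n_case)] + \
              [f"n{i}" for i in range(n_ctrl)]
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=samples)
    groups = pd.Series(["case"] * n_case + ["control"] * n_ctrl,
                       index=samples)
    return ExpressionMatrix(values=frame, groups=groups)


def predicted_bh_recovery(effect, sd, n, n_genes, n_planted, alpha=0.05):
    """Closed-form oracle: Welch power at the BH fixed-point cutoff."""
    df = 2 * n - 2
    ncp = effect / (sd * np.sqrt(2.0 / n))

    def power(cutoff):
        tcrit = stats.t.isf(cutoff / 2, df)
        return stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)

    c = alpha
    for _ in range(100):
        n_reject = n_planted * power(c) + (n_genes - n_planted) * c
        c_new = alpha * n_reject / n_genes
        if abs(c_new - c) < 1e-12:
            break
        c = c_new
    return power(c)


class TestDeTest:
    def test_constant_gene_untestable(self):
        expr = make_expr([[5, 5, 5, 5], [1, 2, 3, 4]], 2, 2)
        tab = de_test(expr)
        assert not tab.loc["G0", "testable"]
        assert not tab.loc["G0", "significant"]
        assert tab.loc["G1", "testable"]

    def test_identical_groups_give_zero_statistic(self):
        expr = make_expr([[1.0, 2.0, 1.0, 2.0]], 2, 2)
        tab = de_test(expr)
        assert tab.loc["G0", "statistic"] == pytest.approx(0.0)
        assert tab.loc["G0", "p_raw"] == pytest.approx(1.0)

    def test_recovery_matches_closed_form_power_oracle(self):
        cfg = SynthConfig(n_genes=1000, n_de_genes=50, de_effect=2.0,
                          noise_sd=1.0, n_samples_per_group=10, seed=2)
        net, _ = generate_network(cfg)
        expr, planted = generate_expression(net, cfg)
        tab = de_test(expr)
        sig = set(tab.index[tab["significant"]])
        recovery = len(sig & planted) / len(planted)
        predicted = predicted_bh_recovery(2.0, 1.0, 10, 1000, 50)
        # binomial noise over 50 planted genes: 3 sigma ≈ 0.18
        assert abs(recovery - predicted) < 0.2
        null_fp = len(sig - planted) / (1000 - 50)
        assert null_fp <= 0.05

    def test_global_null_fraction_small(self):
        rng = np.random.default_rng(30)
        fractions = []
        for _ in range(20):
            vals = rng.normal(0, 1, size=(300, 12))
            expr = make_expr(vals, 6, 6)
            tab = de_test(expr)
            fractions.append(tab["significant"].mean())
        assert np.mean(fractions) < 0.10


class TestUnionDeg:
    @staticmethod
    def _table(sig_genes, all_genes):
        return pd.DataFrame(
            {"significant": [g in sig_genes for g in all_genes]},
            index=pd.Index(all_genes, name="gene"),
        )

    def test_union(self):
        t1 = self._table({"a", "b"}, ["a", "b", "c"])
        t2 = self._table({"b", "c"}, ["a", "b", "c"])
        assert union_deg([t1, t2]).genes == {"a", "b", "c"}

    def test_all_empty_warns(self, caplog):
        t = self._table(set(), ["a"])
        with caplog.at_level("WARNING"):
            panel = union_deg([t, t])
        assert panel.genes == set() and "no significant" in caplog.text

    def test_single_list_identity(self):
        t = self._table({"x"}, ["x", "y"])
        assert union_deg([t]).genes == {"x"}


COMPONENTS = [
    ComponentDefinition("alpha-catenin", "adherens",
                        frozenset({"CTNNA1", "CTNNA2", "CTNNA3"})),
    ComponentDefinition("single", "adherens", frozenset({"CDH1"})),
    ComponentDefinition("other", "tight", frozenset({"TJP1"})),
]


class TestCountDeComponents:
    def test_multi_protein_component_hit_by_any_member(self):
        deg = GenePanel.from_iterable("deg", {"CTNNA2"})
        assert count_de_components(deg, COMPONENTS, "adherens") == 1

    def test_disjoint_deg_counts_zero(self):
        deg = GenePanel.from_iterable("deg", {"XYZ"})
        assert count_de_components(deg, COMPONENTS, "adherens") == 0

    def test_all_single_gene_components_hit(self):
        comps = [ComponentDefinition(f"c{i}", "P", frozenset({f"g{i}"}))
                 for i in range(5)]
        deg = GenePanel.from_iterable("deg", {f"g{i}" for i in range(5)})
        assert count_de_components(deg, comps, "P") == 5

    def test_unknown_pathway_rejected(self):
        deg = GenePanel.from_iterable("deg", {"CDH1"})
        with pytest.raises(KeyError):
            count_de_components(deg, COMPONENTS, "missing")


class TestComponentPermutationTest:
    UNIVERSE = {f"g{i}" for i in range(100)}

    def test_observed_zero_gives_p_one(self):
        comps = [ComponentDefinition("c", "P", frozenset({"g0"}))]
        res = component_permutation_test(5, self.UNIVERSE, comps, "P",
                                         observed_hits=0, n_replicates=50,
                                         seed=0)
        assert res.permutation.p_empirical == 1.0

    def test_saturation_when_deg_is_whole_universe(self):
        comps = [ComponentDefinition(f"c{i}", "P", frozenset({f"g{i}"}))
                 for i in range(10)]
        res = component_permutation_test(
            len(self.UNIVERSE), self.UNIVERSE, comps, "P",
            observed_hits=10, n_replicates=20, seed=1,
        )
        assert res.permutation.p_empirical == 1.0

    def test_planted_concentration_significant_and_reproducible(self):
        universe = {f"g{i}" for i in range(2000)}
        comps = [ComponentDefinition(f"c{i}", "P",
                                     frozenset({f"g{3*i}", f"g{3*i+1}"}))
                 for i in range(40)]
        deg = GenePanel.from_iterable(
            "deg", {f"g{3*i}" for i in range(20)} |
                   {f"g{i}" for i in range(1500, 1530)})
        observed = count_de_components(deg, comps, "P")
        res = component_permutation_test(
            len(deg.genes), universe, comps, "P", observed,
            n_replicates=500, seed=9,
        )
        assert res.permutation.p_empirical < 0.05
        rerun = component_permutation_test(
            len(deg.genes), universe, comps, "P", observed,
            n_replicates=500, seed=9,
        )
        assert rerun == res

    def test_oversized_deg_rejected(self):
        comps = [ComponentDefinition("c", "P", frozenset({"g0"}))]
        with pytest.raises(ValueError):
            component_permutation_test(101, self.UNIVERSE, comps, "P",
                                       observed_hits=0, n_replicates=1,
                                       seed=0)
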
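"""Pearson/F-test edge statistics and CePIN assembly."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from cepin import (build_cepin, pearson_with_p, significant_subnetwork,
                   UndefinedCorrelationError, SyntheticConfig,
                   generate_dataset, CePIN)
from tests.conftest import cepin_from_pccs, expression_from_array


class TestPearsonWithP:
    def test_perfect_correlation(self):
        r, p = pearson_with_p([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r == pytest.approx(1.0)
        assert p < 1e-6  # -> 0 up to floating-point roundoff in r

    def test_hand_computed_example(self):
        # cov = 4, centered norms sqrt(5) each -> r = 4/5
        r, p = pearson_with_p([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8, abs=1e-12)
        t = 0.8 * math.sqrt(2 / (1 - 0.64))
        assert p == pytest.approx(2 * stats.t.sf(t, df=2), rel=1e-10)

    def test_matches_scipy_pearsonr(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x, y = rng.standard_normal(n), rng.standard_normal(n)
            r, p = pearson_with_p(x, y)
            ref = stats.pearsonr(x, y)
            assert r == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_agrees_with_exhaustive_permutation_oracle(self, rng):
        """At n = 6 the F-test p tracks the all-720-permutations null."""
        for _ in range(10):
            x, y = rng.standard_normal(6), rng.standard_normal(6)
            r, p = pearson_with_p(x, y)
            null = [abs(np.corrcoef(x, perm)[0, 1])
                    for perm in itertools.permutations(y)]
            p_perm = np.mean(np.asarray(null) >= abs(r) - 1e-12)
            assert p == pytest.approx(p_perm, abs=0.1)

    def test_zero_variance_signals_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_with_p([1.0, 2.0], [3.0, 4.0])


class TestWeightMap:
    @settings(max_examples=50, deadline=None)
    @given(st.floats(-1.0, 1.0))
    def test_weight_symmetry_and_range(self, r):
        w = 0.5 * (1.0 + r)
        w_neg = 0.5 * (1.0 - r)
        assert 0.0 <= w <= 1.0
        assert w + w_neg == pytest.approx(1.0)

    def test_anchor_points(self):
        cep = cepin_from_pccs({("a", "b"): -1.0, ("b", "c"): 0.0, ("c", "d"): 1.0})
        w = {frozenset(e): d["weight"] for *e, d in cep.graph.edges(data=True)}
        assert w[frozenset({"a", "b"})] == 0.0
        assert w[frozenset({"b", "c"})] == 0.5
        assert w[frozenset({"c", "d"})] == 1.0


class TestBuildCepin:
    def _two_gene_expr(self, y, n=10):
        x = np.linspace(1, 2, n)
        return expression_from_array(np.vstack([x, y]), genes=["A", "B"],
                                     groups=["t"] * n)

    def test_perfect_anticorrelation_gives_weight_zero(self, triangle_net):
        x = np.linspace(1, 2, 10)
        expr = self._two_gene_expr(3.0 - x)
        cep = build_cepin(triangle_net, expr, "t", transform="none")
        d = cep.graph["A"]["B"]
        assert d["pcc"] == pytest.approx(-1.0)
        assert d["weight"] == pytest.approx(0.0)

    def test_constant_gene_edges_dropped(self, triangle_net):
        expr = expression_from_array(
            [[1, 2, 3, 4], [5, 5, 5, 5], [2, 4, 1, 3]],
            genes=["A", "B", "C"], groups=["t"] * 4)
        cep = build_cepin(triangle_net, expr, "t", transform="none")
        assert not cep.graph.has_node("B") or cep.graph.degree("B") == 0
        assert cep.n_dropped_undefined == 2

    def test_matches_per_pair_loop_oracle(self):
        cfg = SyntheticConfig(seed=5, n_genes=40, n_modules=2, module_size=10,
                              n_samples_per_group=20)
        net, expr = generate_dataset(cfg)
        cep = build_cepin(net, expr, "coherent", transform="log2p1")
        vals = np.log2(expr.values.loc[:, expr.samples_in_group("coherent")] + 1)
        for a, b, d in cep.graph.edges(data=True):
            r_ref, p_ref = stats.pearsonr(vals.loc[a], vals.loc[b])
            assert d["pcc"] == pytest.approx(r_ref, abs=1e-10)
            assert d["pvalue"] == pytest.approx(p_ref, rel=1e-6, abs=1e-12)
            assert d["weight"] == pytest.approx(0.5 * (1 + r_ref), abs=1e-10)

    def test_group_errors(self, triangle_net):
        expr = expression_from_array([[1, 2], [3, 4], [5, 6]],
                                     genes=["A", "B", "C"], groups=["t", "t"])
        with pytest.raises(ValueError, match="absent"):
            build_cepin(triangle_net, expr, "nope")
        with pytest.raises(ValueError, match=">= 3"):
            build_cepin(triangle_net, expr, "t")


class TestSignificantSubnetwork:
    def test_alpha_one_keeps_everything(self):
        cep = cepin_from_pccs({("a", "b"): 0.1, ("b", "c"): 0.9}, n_samples=10)
        assert significant_subnetwork(cep, 1.0).n_edges == 2

    def test_boundary_is_strict(self):
        cep = cepin_from_pccs({("a", "b"): 0.5}, n_samples=10)
        p = cep.graph["a"]["b"]["pvalue"]
        assert significant_subnetwork(cep, p).n_edges == 0
        assert significant_subnetwork(cep, p + 1e-9).n_edges == 1

    def test_node_set_is_surviving_endpoints(self):
        cep = cepin_from_pccs({("a", "b"): 0.99, ("b", "c"): 0.01}, n_samples=10)
        sub = significant_subnetwork(cep, 0.05)
        assert set(sub.graph.nodes) == {"a", "b"}

    def test_matches_refilter_oracle(self, rng):
        pccs = {(f"g{i}", f"g{j}"): float(rng.uniform(-0.9, 0.9))
                for i in range(15) for j in range(i + 1, 15) if rng.random() < 0.4}
        cep = cepin_from_pccs(pccs, n_samples=12)
        sub = significant_subnetwork(cep, 0.05)
        oracle = sum(1 for _, _, d in cep.graph.edges(data=True)
                     if d["pvalue"] < 0.05)
        assert sub.n_edges == oracle

    @pytest.mark.parametrize("alpha", [0.0, 1.5, -0.2])
    def test_invalid_alpha_rejected(self, alpha):
        cep = cepin_from_pccs({("a", "b"): 0.5})
        with pytest.raises(ValueError):
            significant_subnetwork(cep, alpha)


class TestSerialization:
    def test_cepin_roundtrip(self, tmp_path, rng):
        pccs = {(f"g{i}", f"g{i+1}"): float(rng.uniform(-1, 1)) for i in range(8)}
        cep = cepin_from_pccs(pccs, n_samples=30, group="tumor")
        path = tmp_path / "cepin.tsv"
        cep.write(path)
        back = CePIN.read(path)
        assert back.group == "tumor"
        assert back.n_samples == 30
        for a, b, d in cep.graph.edges(data=True):
            for key in ("pcc", "weight", "pvalue"):
                assert back.graph[a][b][key] == pytest.approx(d[key], rel=1e-12)
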
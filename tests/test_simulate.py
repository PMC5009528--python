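"""Synthetic interactome and two-condition cohort generator."""

import itertools

import networkx as nx
import numpy as np
import pytest

from cepin import (SyntheticConfig, generate_network, generate_expression,
                   generate_dataset, write_dataset, enumerate_triangles,
                   build_cepin, entropy_profile, load_network, load_expression)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"n_genes": 5},
        {"loading_coherent": 0.3, "loading_degraded": 0.8},
        {"loading_coherent": 1.0},
        {"negative_fraction": 1.5},
        {"n_modules": 10, "module_size": 50, "n_genes": 100},
        {"network_model": "smallworld"},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SyntheticConfig(**kw)

    def test_equal_loadings_allowed_for_null_experiments(self):
        cfg = SyntheticConfig(loading_coherent=0.5, loading_degraded=0.5)
        assert cfg.loading("coherent") == cfg.loading("degraded")


class TestGenerateNetwork:
    def test_modules_contain_triangles(self):
        cfg = SyntheticConfig(seed=2, n_genes=30, n_modules=3, module_size=10,
                              within_module_density=0.8)
        net = generate_network(cfg)
        module_of = nx.get_node_attributes(net, "module")
        tri_by_module = {m: 0 for m in range(3)}
        for t in enumerate_triangles(net):
            mods = {module_of[v] for v in t}
            if len(mods) == 1 and None not in mods:
                tri_by_module[mods.pop()] += 1
        assert all(c >= 1 for c in tri_by_module.values())

    def test_determinism(self):
        cfg = SyntheticConfig(seed=9, n_genes=50, n_modules=2, module_size=10)
        e1 = set(generate_network(cfg).edges)
        e2 = set(generate_network(cfg).edges)
        assert e1 == e2

    def test_full_density_module_triangle_count(self):
        cfg = SyntheticConfig(seed=1, n_genes=10, n_modules=1, module_size=5,
                              within_module_density=1.0, density=0.0)
        net = generate_network(cfg)
        members = [v for v, m in nx.get_node_attributes(net, "module").items()
                   if m == 0]
        sub = net.subgraph(members)
        assert sum(1 for _ in enumerate_triangles(nx.Graph(sub))) == 10  # C(5,3)

    def test_barabasi_albert_background(self):
        cfg = SyntheticConfig(seed=3, n_genes=60, n_modules=2, module_size=10,
                              network_model="barabasi_albert", attachment=2)
        net = generate_network(cfg)
        assert net.number_of_edges() > 0


class TestGenerateExpression:
    def test_bit_reproducibility(self):
        cfg = SyntheticConfig(seed=11, n_genes=40, n_modules=2, module_size=10,
                              n_samples_per_group=15)
        net = generate_network(cfg)
        a = generate_expression(net, cfg, "coherent")
        b = generate_expression(net, cfg, "coherent")
        np.testing.assert_array_equal(a.values.to_numpy(), b.values.to_numpy())

    def test_values_non_negative_and_group_labelled(self):
        cfg = SyntheticConfig(seed=12, n_genes=40, n_modules=2, module_size=10,
                              n_samples_per_group=10, baseline_expression=0.0)
        net = generate_network(cfg)
        expr = generate_expression(net, cfg, "degraded")
        assert (expr.values.to_numpy() >= 0).all()
        assert set(expr.sample_groups) == {"degraded"}

    def test_coherent_module_pccs_strongly_positive(self):
        cfg = SyntheticConfig(seed=13, n_genes=40, n_modules=1, module_size=15,
                              n_samples_per_group=80, loading_coherent=0.9,
                              loading_degraded=0.1, negative_fraction=0.0,
                              noise_sd=0.1, within_module_density=1.0)
        net = generate_network(cfg)
        expr = generate_expression(net, cfg, "coherent")
        members = [v for v, m in nx.get_node_attributes(net, "module").items()
                   if m == 0]
        vals = expr.values.loc[members].to_numpy()
        corr = np.corrcoef(vals)
        off_diag = corr[np.triu_indices_from(corr, k=1)]
        assert (off_diag > 0.5).all()

    def test_zero_loading_gives_near_maximal_entropy(self):
        cfg = SyntheticConfig(seed=14, n_genes=60, n_modules=2, module_size=15,
                              n_samples_per_group=60, loading_coherent=0.8,
                              loading_degraded=0.0)
        net = generate_network(cfg)
        expr = generate_expression(net, cfg, "degraded")
        cep = build_cepin(net, expr, "degraded")
        prof = entropy_profile(cep)
        assert prof.summary()["mean"] > 0.99

    def test_mixed_sign_modules_follow_gene_axes(self):
        # with maximal loading each gene sits on its base axis, so the PCC
        # sign between module mates is the product of their axis signs
        cfg = SyntheticConfig(seed=15, n_genes=30, n_modules=1, module_size=12,
                              n_samples_per_group=120, loading_coherent=0.95,
                              loading_degraded=0.1, negative_fraction=0.5,
                              noise_sd=0.1, within_module_density=1.0)
        net = generate_network(cfg)
        expr = generate_expression(net, cfg, "coherent")
        from cepin.simulate import _gene_axes
        base, _ = _gene_axes(cfg)
        members = [v for v, m in nx.get_node_attributes(net, "module").items()
                   if m == 0]
        vals = expr.values.loc[members].to_numpy()
        corr = np.corrcoef(vals)
        agree = 0
        pairs = list(itertools.combinations(range(len(members)), 2))
        for i, j in pairs:
            s = 1 if base[members[i]] == base[members[j]] else -1
            agree += np.sign(corr[i, j]) == s
        assert agree / len(pairs) > 0.9


class TestWriteDataset:
    def test_emitted_files_reload_into_pipeline_inputs(self, tmp_path):
        cfg = SyntheticConfig(seed=21, n_genes=30, n_modules=2, module_size=10,
                              n_samples_per_group=10)
        paths = write_dataset(cfg, tmp_path / "ds")
        assert sorted(p.name for p in (tmp_path / "ds").iterdir()) == sorted(
            ["network.tsv", "expression.tsv", "metadata.tsv", "config.yaml",
             "modules.tsv"])
        net = load_network(paths["network"])
        expr = load_expression(paths["expression"], paths["metadata"])
        assert set(expr.genes) <= set(net.nodes) | set(expr.genes)
        assert sorted(set(expr.sample_groups)) == ["coherent", "degraded"]
        assert len(expr.samples) == 20

    def test_same_seed_identical_bytes(self, tmp_path):
        cfg = SyntheticConfig(seed=22, n_genes=30, n_modules=2, module_size=10,
                              n_samples_per_group=8)
        p1 = write_dataset(cfg, tmp_path / "a")
        p2 = write_dataset(cfg, tmp_path / "b")
        for key in ("network", "expression", "metadata"):
            assert p1[key].read_bytes() == p2[key].read_bytes()
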
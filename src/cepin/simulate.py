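"""Synthetic interactomes and two-condition expression cohorts.

The generator emulates the statistical structure the pipeline's measures
respond to: a sparse interactome with densely wired gene modules, and
module-level co-expression that is strong and sign-structured in one
condition ("coherent", the normal-tissue-like state) and weakened in the
other ("degraded", the tumor-like state).

Expression follows a latent-factor model with two factors per module.
Each module m draws a factor pair (f1_s, f2_s) ~ N(0,1) per sample; gene g
in module m loads on the factor plane at an angle theta_g:

    x_gs = baseline + lambda * (cos(theta_g) f1_s + sin(theta_g) f2_s)
           + noise_sd * eps_gs,                      eps ~ N(0,1)

    theta_g = base_g + (1 - lambda) * delta_g,       delta_g ~ U(-pi, pi)

where lambda in (0,1) is the group's loading, base_g is 0 or pi (pi with
probability negative_fraction, giving the module signed structure), and
delta_g is a fixed per-gene perturbation shared by both groups.  Genes
outside any module are baseline plus noise; values are clipped at zero to
satisfy the expression non-negativity invariant.

Two same-module genes then have expected correlation
cos(theta_g - theta_h) * lambda^2 / (lambda^2 + noise_sd^2), so the loading
controls both the magnitude and the angular (sign) coherence of
co-expression.  High loading pins every gene near its base axis: edge signs
reduce to the product s_g * s_h, weights concentrate near 0 or 1, and every
module triangle is structurally balanced (low entropy, balanced motifs).
Low loading disperses the angles: weights crowd 0.5 and triplets at
intermediate angles (e.g. 0, pi/3, 2*pi/3) produce two positive and one
negative edge -- genuinely unbalanced triangles (high entropy, raised
p_um).  With equal loadings the two groups are exchangeable by
construction, so no spurious contrast can arise.

One global seed drives the network and each group's matrix through
independent derived streams, so adding a group never perturbs the network.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .expression import ExpressionMatrix
from .ppi import write_network

__all__ = ["SyntheticConfig", "generate_network", "generate_expression",
           "generate_dataset", "write_dataset"]

GROUPS = ("coherent", "degraded")
_STREAM = {"network": 0, "coherent": 1, "degraded": 2}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic study.

    Defaults define the standard two-condition experiment: 300 genes, six
    25-gene modules, 60 samples per group, module loading 0.8 (coherent)
    vs 0.3 (degraded), 30 % of module genes with negated loading.
    """

    n_genes: int = 300
    n_samples_per_group: int = 60
    network_model: str = "erdos_renyi"  # or "barabasi_albert"
    density: float = 0.02               # ER edge probability between non-module pairs
    attachment: int = 2                 # BA edges per new node (if BA background)
    n_modules: int = 6
    module_size: int = 25
    within_module_density: float = 0.6
    loading_coherent: float = 0.8
    loading_degraded: float = 0.3
    negative_fraction: float = 0.3
    noise_sd: float = 0.3
    baseline_expression: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not 0.0 <= self.loading_degraded <= self.loading_coherent < 1.0:
            raise ValueError(
                "loadings must satisfy 0 <= loading_degraded <= loading_coherent < 1")
        if not 0.0 <= self.negative_fraction <= 1.0:
            raise ValueError("negative_fraction must be in [0, 1]")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("modules cannot cover more genes than n_genes")
        if self.network_model not in ("erdos_renyi", "barabasi_albert"):
            raise ValueError(f"unknown network_model {self.network_model!r}")
        if self.baseline_expression < 0:
            raise ValueError("baseline_expression must be >= 0")

    def loading(self, group: str) -> float:
        if group == "coherent":
            return self.loading_coherent
        if group == "degraded":
            return self.loading_degraded
        raise ValueError(f"unknown group {group!r}; choose from {GROUPS}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAM[stream]])


def _gene_names(n: int) -> list[str]:
    width = len(str(n))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SyntheticConfig) -> nx.Graph:
    """Seeded modular interactome.

    Module genes are wired densely within their module (so triangles exist
    inside modules); the background (all remaining pairs) follows the
    configured random-graph model at low density.  Each node carries a
    ``module`` attribute (module index, or None for background genes).
    """
    rng = cfg.rng("network")
    genes = _gene_names(cfg.n_genes)
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(genes)

    module_of: dict[str, int | None] = {v: None for v in genes}
    for m in range(cfg.n_modules):
        members = genes[m * cfg.module_size:(m + 1) * cfg.module_size]
        for v in members:
            module_of[v] = m
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if rng.random() < cfg.within_module_density:
                    g.add_edge(a, b)

    if cfg.network_model == "erdos_renyi":
        bg = nx.erdos_renyi_graph(cfg.n_genes, cfg.density,
                                  seed=int(rng.integers(2**31)))
    else:
        bg = nx.barabasi_albert_graph(cfg.n_genes, cfg.attachment,
                                      seed=int(rng.integers(2**31)))
    relabel = dict(enumerate(genes))
    for i, j in bg.edges:
        a, b = relabel[i], relabel[j]
        if module_of[a] is not None and module_of[a] == module_of[b]:
            continue  # within-module wiring is governed by within_module_density
        g.add_edge(a, b)

    nx.set_node_attributes(g, module_of, "module")
    if g.number_of_edges() == 0:
        raise ValueError("configuration produced an empty edge set")
    return g


def _gene_axes(cfg: SyntheticConfig) -> tuple[dict[str, float], dict[str, float]]:
    """Per-gene base angle (0 or pi) and angular perturbation delta_g.

    Drawn from a dedicated stream so both groups share the same gene axes;
    the base is pi with probability ``negative_fraction``.
    """
    rng = np.random.default_rng([cfg.seed, 3])
    genes = _gene_names(cfg.n_genes)
    base = np.where(rng.random(cfg.n_genes) < cfg.negative_fraction, np.pi, 0.0)
    delta = rng.uniform(-np.pi, np.pi, cfg.n_genes)
    return dict(zip(genes, base.tolist())), dict(zip(genes, delta.tolist()))


def generate_expression(net: nx.Graph, cfg: SyntheticConfig, group: str) -> ExpressionMatrix:
    """One group's cohort from the latent-factor model (bit-reproducible).

    ``net`` must carry the ``module`` node annotations written by
    :func:`generate_network`.
    """
    lam = cfg.loading(group)
    rng = cfg.rng(group)
    module_of = nx.get_node_attributes(net, "module")
    if not module_of:
        raise ValueError("network lacks module annotations; use generate_network")
    genes = sorted(net.nodes)
    base, delta = _gene_axes(cfg)
    n_s = cfg.n_samples_per_group

    factors = rng.standard_normal((cfg.n_modules, 2, n_s))
    noise = rng.standard_normal((len(genes), n_s)) * cfg.noise_sd
    x = np.full((len(genes), n_s), cfg.baseline_expression) + noise
    for gi, gene in enumerate(genes):
        m = module_of.get(gene)
        if m is not None:
            theta = base[gene] + (1.0 - lam) * delta[gene]
            x[gi] += lam * (np.cos(theta) * factors[m, 0]
                            + np.sin(theta) * factors[m, 1])
    np.clip(x, 0.0, None, out=x)

    samples = [f"{group}_s{j:03d}" for j in range(1, n_s + 1)]
    values = pd.DataFrame(x, index=genes, columns=samples)
    groups = pd.Series(group, index=values.columns, name="group")
    return ExpressionMatrix(values, groups)


def generate_dataset(cfg: SyntheticConfig) -> tuple[nx.Graph, ExpressionMatrix]:
    """Network plus the combined two-group cohort (coherent + degraded)."""
    net = generate_network(cfg)
    parts = [generate_expression(net, cfg, grp) for grp in GROUPS]
    values = pd.concat([p.values for p in parts], axis=1)
    groups = pd.concat([p.sample_groups for p in parts])
    return net, ExpressionMatrix(values, groups)


def write_dataset(cfg: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the pipeline's input formats.

    Emits ``network.tsv`` (edge list), ``expression.tsv``, ``metadata.tsv``
    and a ``config.yaml`` echo of the generative parameters for provenance.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    net, expr = generate_dataset(cfg)
    paths = {
        "network": outdir / "network.tsv",
        "expression": outdir / "expression.tsv",
        "metadata": outdir / "metadata.tsv",
        "config": outdir / "config.yaml",
        "modules": outdir / "modules.tsv",
    }
    write_network(net, paths["network"])
    expr.write(paths["expression"], paths["metadata"])
    module_of = nx.get_node_attributes(net, "module")
    pd.DataFrame(
        {"gene": sorted(net.nodes),
         "module": [module_of.get(v) for v in sorted(net.nodes)]}
    ).to_csv(paths["modules"], sep="\t", index=False)
    with paths["config"].open("w") as fh:
        yaml.safe_dump(asdict(cfg), fh, sort_keys=False)
    return paths
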
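import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cepin import CePIN, ExpressionMatrix


def cepin_from_pccs(pccs: dict, n_samples: int = 50, group: str = "g") -> CePIN:
    """Build a CePIN directly from {(a, b): pcc}; weight and p follow."""
    g = nx.Graph()
    for (a, b), r in pccs.items():
        if abs(r) == 1.0:
            p = 0.0
        else:
            f = r * r * (n_samples - 2) / (1.0 - r * r)
            p = float(stats.f.sf(f, 1, n_samples - 2))
        g.add_edge(a, b, pcc=float(r), weight=0.5 * (1.0 + r), pvalue=p)
    return CePIN(g, group=group, n_samples=n_samples)


def cepin_from_weights(weights: dict, group: str = "g") -> CePIN:
    """CePIN with explicit weights (pcc back-solved, pvalue left small)."""
    g = nx.Graph()
    for (a, b), w in weights.items():
        g.add_edge(a, b, pcc=2.0 * w - 1.0, weight=float(w), pvalue=1e-6)
    return CePIN(g, group=group, n_samples=50)


def expression_from_array(values, genes=None, samples=None, groups=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    if groups is None:
        groups = ["grp"] * len(samples)
    return ExpressionMatrix(df, pd.Series(groups, index=samples))


@pytest.fixture
def triangle_net() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C")])
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
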
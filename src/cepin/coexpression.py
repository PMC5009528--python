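"""Building co-expressed protein-interaction networks (CePINs).

For one sample group, every PIN edge whose endpoints are in the (filtered)
expression matrix gets the Pearson correlation r of the two genes across the
group's samples, the weight w = (1 + r)/2 in [0, 1], and a two-sided
significance p from the simple-regression F statistic F = t^2 with
t = r * sqrt((n-2)/(1-r^2)) on (1, n-2) degrees of freedom -- identical to
the usual two-sided t test for a correlation.

Edges whose correlation is undefined (a gene constant within the group) are
dropped: a constant gene carries no co-expression evidence, and assigning it
weight 0.5 would manufacture entropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CePIN",
    "UndefinedCorrelationError",
    "pearson_with_p",
    "build_cepin",
    "significant_subnetwork",
    "apply_transform",
    "TRANSFORMS",
]

TRANSFORMS = ("none", "log2p1")


class UndefinedCorrelationError(ValueError):
    """A correlation was requested for a zero-variance vector."""


@dataclass
class CePIN:
    """A PIN whose edges carry group-specific co-expression annotations.

    Edge attributes on ``graph``: ``pcc`` (Pearson r), ``weight``
    ((1+r)/2), ``pvalue`` (two-sided F-test significance).
    """

    graph: nx.Graph
    group: str
    n_samples: int
    transform: str = "log2p1"
    n_dropped_undefined: int = 0
    provenance: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": a, "gene_b": b, "pcc": d["pcc"], "weight": d["weight"],
             "pvalue": d["pvalue"], "n_samples": self.n_samples, "group": self.group}
            for a, b, d in self.graph.edges(data=True)
        ]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "pcc", "weight",
                                         "pvalue", "n_samples", "group"])
        return df.sort_values(["gene_a", "gene_b"], ignore_index=True)

    def write(self, path: str | Path) -> None:
        self.edge_table().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "CePIN":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(row.gene_a, row.gene_b, pcc=row.pcc,
                       weight=row.weight, pvalue=row.pvalue)
        group = str(df["group"].iloc[0]) if len(df) else ""
        n = int(df["n_samples"].iloc[0]) if len(df) else 0
        return cls(g, group=group, n_samples=n)


def pearson_with_p(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided F-test significance.

    ``p`` comes from F = r^2 (n-2) / (1 - r^2) on (1, n-2) df, the overall
    F test of the simple regression of y on x; it equals the two-sided
    t-test p-value for r.

    Raises
    ------
    ValueError
        If n < 3.
    UndefinedCorrelationError
        If either vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if n < 3:
        raise ValueError(f"correlation needs n >= 3 samples, got {n}")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance: correlation undefined")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    f = r * r * (n - 2) / (1.0 - r * r)
    p = float(stats.f.sf(f, 1, n - 2))
    return r, p


def apply_transform(values: pd.DataFrame, transform: str) -> pd.DataFrame:
    """Value transform applied before correlation (never before filtering)."""
    if transform == "none":
        return values
    if transform == "log2p1":
        return np.log2(values + 1.0)
    raise ValueError(f"unknown transform {transform!r}; choose from {TRANSFORMS}")


def build_cepin(
    net: nx.Graph,
    expr: ExpressionMatrix,
    group: str,
    transform: str = "log2p1",
) -> CePIN:
    """Assemble the CePIN for one sample group.

    The PIN is restricted to genes present in ``expr``; each surviving edge
    gets r, w = (1+r)/2 and the F-test p computed across the group's samples
    on transformed values.  Edges touching a gene that is constant within
    the group are dropped (counted in ``n_dropped_undefined``).

    ``expr`` should already be gene-filtered; the group must have >= 3
    samples (the p-value needs n - 2 >= 1 degrees of freedom).
    """
    if group not in set(expr.sample_groups):
        raise ValueError(f"group {group!r} absent from sample metadata")
    samples = expr.samples_in_group(group)
    n = len(samples)
    if n < 3:
        raise ValueError(f"group {group!r} has {n} samples; >= 3 required")

    keep = set(expr.genes) & set(net.nodes)
    sub = net.subgraph(keep)
    vals = apply_transform(expr.values.loc[:, samples], transform)
    data = vals.to_numpy(dtype=float)
    gene_row = {g: i for i, g in enumerate(vals.index)}

    # standardize once; r for every edge is then a dot product
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", centered, centered))
    constant = norms == 0.0

    edges = [(a, b) for a, b in sub.edges]
    g = nx.Graph()
    n_dropped = 0
    if edges:
        ia = np.array([gene_row[a] for a, _ in edges])
        ib = np.array([gene_row[b] for _, b in edges])
        ok = ~(constant[ia] | constant[ib])
        n_dropped = int((~ok).sum())
        kept_edges = [e for e, k in zip(edges, ok) if k]
        idx_a, idx_b = ia[ok], ib[ok]
        if len(kept_edges):
            r = np.einsum("ij,ij->i", centered[idx_a], centered[idx_b])
            r = np.clip(r / (norms[idx_a] * norms[idx_b]), -1.0, 1.0)
            with np.errstate(divide="ignore"):
                f = r * r * (n - 2) / (1.0 - r * r)
            p = stats.f.sf(f, 1, n - 2)
            p = np.where(np.abs(r) == 1.0, 0.0, p)
            w = 0.5 * (1.0 + r)
            for (a, b), ri, wi, pi in zip(kept_edges, r, w, p):
                g.add_edge(a, b, pcc=float(ri), weight=float(wi), pvalue=float(pi))
    if n_dropped:
        logger.info("group %r: %d edge(s) dropped for undefined correlation", group, n_dropped)
    return CePIN(g, group=group, n_samples=n, transform=transform,
                 n_dropped_undefined=n_dropped,
                 provenance={"transform": transform, "n_samples": n,
                             "n_edges": g.number_of_edges(),
                             "n_dropped_undefined": n_dropped})


def significant_subnetwork(cepin: CePIN, alpha: float = 0.05) -> CePIN:
    """Edge-filtered copy keeping edges with p < alpha (strict).

    The node set of the result is exactly the endpoints of surviving edges.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    g = nx.Graph()
    for a, b, d in cepin.graph.edges(data=True):
        if d["pvalue"] < alpha:
            g.add_edge(a, b, **d)
    return CePIN(g, group=cepin.group, n_samples=cepin.n_samples,
                 transform=cepin.transform,
                 provenance={**cepin.provenance, "alpha": alpha})
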
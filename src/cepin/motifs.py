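"""Signed triangle motifs and structural balance of a CePIN.

Each edge of the significance-filtered CePIN is signed by its correlation:
positive when r > 0, negative when r < 0.  Classical structural balance
theory classifies a triangle by its number of positive edges:

    3 positives -> balanced type I        1 positive -> balanced type II
    2 positives -> unbalanced type II     0 positives -> unbalanced type I

A triangle is balanced iff its positive count is odd.  The disorder index
p_um = N_um / N_tm is the fraction of unbalanced triangles among all
triangles; a stable, modular network has mostly balanced triangles and a
small p_um.

Triangle enumeration is degree-ordered neighbor intersection (each triangle
reported exactly once), which scales to the ~1e4-node, ~1e5-edge networks
the pipeline targets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterator

import networkx as nx
import pandas as pd

from .coexpression import CePIN, significant_subnetwork

logger = logging.getLogger(__name__)

__all__ = ["edge_sign", "enumerate_triangles", "classify_triangle",
           "motif_census", "MotifCensus", "MOTIF_TYPES"]

MOTIF_TYPES = ("balanced_I", "balanced_II", "unbalanced_I", "unbalanced_II")

# positive-edge count -> motif type
_TYPE_BY_POSITIVES = {3: "balanced_I", 1: "balanced_II",
                      2: "unbalanced_II", 0: "unbalanced_I"}


def edge_sign(pcc: float) -> int:
    """+1 for r > 0, -1 for r < 0.

    r = 0 raises: a zero correlation has p = 1 and can never pass the
    significance filter, so an unsigned edge indicates the census was asked
    to run on an unfiltered CePIN.
    """
    if pcc > 0.0:
        return 1
    if pcc < 0.0:
        return -1
    raise ValueError("unsigned edge: PCC = 0 cannot occur on a significance-filtered CePIN")


def enumerate_triangles(net: nx.Graph) -> Iterator[tuple]:
    """Yield each triangle of a simple undirected graph exactly once.

    Nodes are ranked by (degree, label) -- the lexicographic tie-break makes
    the emitted triple order deterministic -- and each triangle is reported
    from its lowest-ranked vertex via neighbor-set intersection.
    """
    rank = {v: i for i, v in enumerate(
        sorted(net.nodes, key=lambda v: (net.degree(v), str(v))))}
    higher = {v: {u for u in net[v] if rank[u] > rank[v]} for v in net.nodes}
    for u in sorted(net.nodes, key=rank.get):
        hu = higher[u]
        for v in sorted(hu, key=rank.get):
            for w in sorted(hu & higher[v], key=rank.get):
                yield (u, v, w)


def classify_triangle(signs) -> str:
    """Map three edge signs to the balance type via the positive count."""
    positives = sum(1 for s in signs if s > 0)
    return _TYPE_BY_POSITIVES[positives]


@dataclass
class MotifCensus:
    """Counts of the four signed-triangle types in one CePIN."""

    group: str
    counts: dict  # motif type -> count
    n_tm: int  # total triangles

    @property
    def n_um(self) -> int:
        return self.counts["unbalanced_I"] + self.counts["unbalanced_II"]

    @property
    def n_bm(self) -> int:
        return self.counts["balanced_I"] + self.counts["balanced_II"]

    @property
    def p_um(self) -> float | None:
        """Fraction of unbalanced triangles; None when no triangle exists."""
        return self.n_um / self.n_tm if self.n_tm else None

    @property
    def p_bm(self) -> float | None:
        return 1.0 - self.p_um if self.n_tm else None

    def as_dict(self) -> dict:
        return {
            "group": self.group,
            "n_triangles": self.n_tm,
            **{k: self.counts[k] for k in MOTIF_TYPES},
            "n_balanced": self.n_bm,
            "n_unbalanced": self.n_um,
            "fraction_balanced": self.p_bm,
            "fraction_unbalanced": self.p_um,
        }

    def table_row(self) -> dict:
        """Three-decimal fractions, the convention of the published tables."""
        d = self.as_dict()
        for k in ("fraction_balanced", "fraction_unbalanced"):
            if d[k] is not None:
                d[k] = round(d[k], 3)
        return d


def motif_census(
    cepin: CePIN,
    alpha: float = 0.05,
    collect_triangles: bool = False,
) -> MotifCensus | tuple[MotifCensus, pd.DataFrame]:
    """Signed-triangle census of the significance-filtered CePIN.

    Applies the p < alpha edge filter, enumerates triangles, classifies each
    by its positive-edge count, and returns counts plus the unbalanced
    fraction p_um.  With ``collect_triangles`` a per-triangle table
    (gene_a, gene_b, gene_c, signs, motif_type) is returned as well.

    When the filtered network has no triangle the fractions are undefined
    (``None``, with a warning), not zero.
    """
    sig = significant_subnetwork(cepin, alpha)
    g = sig.graph
    counts = {t: 0 for t in MOTIF_TYPES}
    rows = []
    for u, v, w in enumerate_triangles(g):
        signs = (edge_sign(g[u][v]["pcc"]), edge_sign(g[u][w]["pcc"]),
                 edge_sign(g[v][w]["pcc"]))
        mtype = classify_triangle(signs)
        counts[mtype] += 1
        if collect_triangles:
            rows.append({"gene_a": u, "gene_b": v, "gene_c": w,
                         "signs": "".join("+" if s > 0 else "-" for s in signs),
                         "motif_type": mtype})
    n_tm = sum(counts.values())
    if n_tm == 0:
        warnings.warn(f"group {cepin.group!r}: no triangles after the p < {alpha} "
                      "filter; motif fractions undefined", stacklevel=2)
    census = MotifCensus(group=cepin.group, counts=counts, n_tm=n_tm)
    if collect_triangles:
        cols = ["gene_a", "gene_b", "gene_c", "signs", "motif_type"]
        return census, pd.DataFrame(rows, columns=cols)
    return census
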
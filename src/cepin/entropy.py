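"""Local network entropy of genes in a weighted co-expression network.

For gene i with neighbors N(i), degree k_i = |N(i)| and incident edge
weights w_ij, the proportions p_ij = w_ij / sum_j w_ij define the normalized
local Shannon entropy

    S_i = -(1 / log k_i) * sum_j p_ij log p_ij,   0 <= S_i <= 1,

with the 0 * log 0 = 0 convention (an exactly -1 correlation gives weight
0).  S_i = 1 when the incident weights are uniform (promiscuous, disordered
local co-expression) and 0 when all weight sits on one edge.  The log base
cancels in the ratio; natural logs are used.

Entropy is computed on the full CePIN -- every co-expression edge, not only
the significance-filtered ones used for motif analysis.  Degree-1 nodes are
excluded (log 1 = 0 leaves S_i undefined), as are nodes whose total incident
weight is zero; both exclusions are reported with reasons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .coexpression import CePIN

logger = logging.getLogger(__name__)

__all__ = ["UndefinedEntropyError", "local_entropy", "entropy_profile",
           "gene_set_profile", "EntropyProfile"]


class UndefinedEntropyError(ValueError):
    """Entropy is undefined: degree < 2 or zero total incident weight."""


def local_entropy(weights) -> float:
    """Normalized local Shannon entropy of one node's incident weights.

    ``weights`` is the vector of the node's k >= 2 incident edge weights
    (all >= 0, not all zero).  Returns S in [0, 1].
    """
    w = np.asarray(weights, dtype=float)
    k = w.size
    if k < 2:
        raise UndefinedEntropyError(f"degree {k} < 2: normalization log(k) degenerate")
    if (w < 0).any():
        raise ValueError("negative weight")
    total = w.sum()
    if total == 0.0:
        raise UndefinedEntropyError("zero total incident weight")
    p = w / total
    nz = p[p > 0.0]
    s = float(-(nz * np.log(nz)).sum() / np.log(k))
    # clamp away roundoff excursions outside [0, 1]
    return min(max(s, 0.0), 1.0)


@dataclass
class EntropyProfile:
    """Per-gene local entropies over one CePIN, with summary statistics."""

    table: pd.DataFrame  # columns: gene, degree, entropy
    group: str
    excluded: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "reason"]))

    @property
    def entropies(self) -> np.ndarray:
        return self.table["entropy"].to_numpy(dtype=float)

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def summary(self) -> dict:
        """Mean +/- SEM (the conventional 'mean ± sem' report), SD, median, n."""
        s = self.entropies
        n = s.size
        mean = float(s.mean()) if n else float("nan")
        sd = float(s.std(ddof=1)) if n > 1 else float("nan")
        return {
            "group": self.group,
            "n": int(n),
            "mean": mean,
            "sd": sd,
            "sem": sd / np.sqrt(n) if n > 1 else float("nan"),
            "median": float(np.median(s)) if n else float("nan"),
        }

    def write(self, path: str | Path) -> None:
        out = self.table.copy()
        out["group"] = self.group
        out.to_csv(path, sep="\t", index=False)


def entropy_profile(cepin: CePIN) -> EntropyProfile:
    """Compute S_i for every eligible node of the (unfiltered) CePIN.

    Eligible nodes have degree >= 2 and positive total incident weight;
    others are listed in ``excluded`` with the reason.
    """
    g = cepin.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty CePIN: no nodes to profile")
    rows, skipped = [], []
    for node in g.nodes:
        w = np.array([d["weight"] for _, _, d in g.edges(node, data=True)], dtype=float)
        if w.size < 2:
            skipped.append({"gene": node, "reason": "degree < 2"})
            continue
        if w.sum() == 0.0:
            skipped.append({"gene": node, "reason": "zero total weight"})
            continue
        rows.append({"gene": node, "degree": int(w.size),
                     "entropy": local_entropy(w)})
    table = pd.DataFrame(rows, columns=["gene", "degree", "entropy"])
    table = table.sort_values("gene", ignore_index=True)
    excluded = pd.DataFrame(skipped, columns=["gene", "reason"])
    if len(excluded):
        logger.info("group %r: %d node(s) without defined entropy", cepin.group, len(excluded))
    return EntropyProfile(table, group=cepin.group, excluded=excluded)


def gene_set_profile(profile: EntropyProfile, gene_set) -> EntropyProfile:
    """Restrict a profile to a gene set (e.g. oncogenes, tumor suppressors).

    Raises a ValueError (reporting the overlap counts) when the set shares
    no genes with the profile; members absent from the profile are logged.
    """
    gene_set = set(gene_set)
    mask = profile.table["gene"].isin(gene_set)
    n_hit = int(mask.sum())
    if n_hit == 0:
        raise ValueError(
            f"gene set ({len(gene_set)} symbols) has 0 overlap with the "
            f"{len(profile.table)} profiled genes")
    n_absent = len(gene_set) - n_hit
    if n_absent:
        logger.info("gene set: %d member(s) absent from profile or ineligible", n_absent)
    return EntropyProfile(profile.table[mask].reset_index(drop=True),
                          group=profile.group, excluded=profile.excluded)
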
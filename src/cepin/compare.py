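"""Contrasting entropy distributions and motif ratios between sample groups.

The genome-wide contrast is an unpaired two-sided Wilcoxon rank-sum
(Mann-Whitney) test on the two per-gene entropy vectors, pooled per group:
genes eligible in only one group's CePIN stay in that group's vector, no
intersection is forced.  A paired-by-gene mode (Wilcoxon signed-rank on
shared genes) is available as an option.  Motif censuses on the
significance-filtered networks are attached to each contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .coexpression import CePIN
from .entropy import EntropyProfile, entropy_profile, gene_set_profile
from .motifs import MotifCensus, motif_census

logger = logging.getLogger(__name__)

__all__ = ["wilcoxon_rank_sum", "compare_groups", "ComparisonResult"]


def wilcoxon_rank_sum(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact distribution when min(n_a, n_b) <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    Returns (U statistic of the first sample, two-sided p-value).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("values must be finite")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1", stacklevel=2)
        return float(a.size * b.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ComparisonResult:
    """One entropy + motif contrast between two sample groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    pvalue: float
    direction: str  # group label with the higher median entropy, or "none"
    summary_a: dict
    summary_b: dict
    census_a: MotifCensus | None = None
    census_b: MotifCensus | None = None
    gene_set_results: dict = field(default_factory=dict)
    paired: bool = False

    @property
    def p_um_difference(self) -> float | None:
        if self.census_a is None or self.census_b is None:
            return None
        pa, pb = self.census_a.p_um, self.census_b.p_um
        if pa is None or pb is None:
            return None
        return pb - pa

    def as_dict(self) -> dict:
        d = {
            "group_a": self.group_a, "group_b": self.group_b,
            "n_genes_a": self.n_a, "n_genes_b": self.n_b,
            "statistic": self.statistic, "pvalue": self.pvalue,
            "direction": self.direction, "paired": self.paired,
            "summary_a": self.summary_a, "summary_b": self.summary_b,
        }
        if self.census_a is not None and self.census_b is not None:
            d["motif_contrast"] = {
                "p_um_a": self.census_a.p_um,
                "p_um_b": self.census_b.p_um,
                "p_um_difference": self.p_um_difference,
                "census_a": self.census_a.as_dict(),
                "census_b": self.census_b.as_dict(),
            }
        if self.gene_set_results:
            d["gene_sets"] = {name: r.as_dict() if isinstance(r, ComparisonResult) else r
                              for name, r in self.gene_set_results.items()}
        return d


def _direction(summary_a: dict, summary_b: dict, a: str, b: str) -> str:
    ma, mb = summary_a["median"], summary_b["median"]
    if np.isnan(ma) or np.isnan(mb) or ma == mb:
        return "none"
    return b if mb > ma else a


def _contrast_profiles(pa: EntropyProfile, pb: EntropyProfile,
                       group_a: str, group_b: str, paired: bool) -> tuple:
    if paired:
        shared = sorted(set(pa.genes) & set(pb.genes))
        if not shared:
            raise ValueError("paired mode requires genes shared by both profiles")
        ta = pa.table.set_index("gene").loc[shared, "entropy"].to_numpy()
        tb = pb.table.set_index("gene").loc[shared, "entropy"].to_numpy()
        diffs = ta - tb
        if np.all(diffs == 0):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(ta, tb)
            stat, p = float(res.statistic), float(res.pvalue)
        n_a = n_b = len(shared)
    else:
        va, vb = pa.entropies, pb.entropies
        stat, p = wilcoxon_rank_sum(va, vb)
        n_a, n_b = va.size, vb.size
    sa, sb = pa.summary(), pb.summary()
    return stat, p, n_a, n_b, sa, sb, _direction(sa, sb, group_a, group_b)


def compare_groups(
    cepin_a: CePIN,
    cepin_b: CePIN,
    gene_sets: dict | None = None,
    alpha_motif: float = 0.05,
    paired: bool = False,
) -> ComparisonResult:
    """Full two-group contrast: entropy rank-sum + motif censuses.

    Entropy profiles are computed on the full CePINs (all edges); the motif
    censuses apply the p < ``alpha_motif`` significance filter.  Each named
    gene set yields a nested contrast restricted to that set.

    Both CePINs should be built on the same underlying PIN and filtered
    gene universe.
    """
    pa = entropy_profile(cepin_a)
    pb = entropy_profile(cepin_b)
    if not len(pa.table) or not len(pb.table):
        raise ValueError("one of the entropy profiles is empty")
    stat, p, n_a, n_b, sa, sb, direction = _contrast_profiles(
        pa, pb, cepin_a.group, cepin_b.group, paired)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # triangle-free nets report p_um=None
        ca = motif_census(cepin_a, alpha_motif)
        cb = motif_census(cepin_b, alpha_motif)

    gene_set_results: dict = {}
    for name, genes in (gene_sets or {}).items():
        try:
            ra = gene_set_profile(pa, genes)
            rb = gene_set_profile(pb, genes)
        except ValueError as exc:
            logger.warning("gene set %r skipped: %s", name, exc)
            gene_set_results[name] = {"error": str(exc)}
            continue
        gstat, gp, gn_a, gn_b, gsa, gsb, gdir = _contrast_profiles(
            ra, rb, cepin_a.group, cepin_b.group, paired)
        gene_set_results[name] = ComparisonResult(
            group_a=cepin_a.group, group_b=cepin_b.group,
            n_a=gn_a, n_b=gn_b, statistic=gstat, pvalue=gp,
            direction=gdir, summary_a=gsa, summary_b=gsb, paired=paired)

    return ComparisonResult(
        group_a=cepin_a.group, group_b=cepin_b.group,
        n_a=n_a, n_b=n_b, statistic=stat, pvalue=p, direction=direction,
        summary_a=sa, summary_b=sb, census_a=ca, census_b=cb,
        gene_set_results=gene_set_results, paired=paired)
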
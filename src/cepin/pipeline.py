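"""End-to-end orchestration: load -> filter -> CePINs -> entropy -> motifs -> contrasts.

A :class:`RunConfig` names the input files and parameters; :func:`run_pipeline`
executes every stage, writes per-gene entropy tables, motif censuses and the
contrast report, and embeds the resolved configuration plus dropped-record
accounting in a provenance block so a run is reproducible from its report.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .compare import compare_groups
from .coexpression import build_cepin, TRANSFORMS
from .entropy import entropy_profile
from .expression import load_expression, filter_expressed_genes
from .motifs import motif_census
from .ppi import load_network

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    network: str
    expression: str
    metadata: str
    outdir: str
    gene_sets: dict = field(default_factory=dict)  # name -> file of symbols
    sample_quantile: float = 0.20
    min_sample_frac: float = 0.20
    transform: str = "log2p1"
    alpha_motif: float = 0.05
    comparisons: list = field(default_factory=list)  # [(a, b)]; empty = all pairs
    paired: bool = False

    def validate(self) -> None:
        for name in ("network", "expression", "metadata"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        for name, path in self.gene_sets.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"gene set {name!r} file not found: {path}")
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        for frac_name in ("sample_quantile", "min_sample_frac"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must be in [0, 1], got {v}")
        if not 0.0 < self.alpha_motif <= 1.0:
            raise ValueError(f"alpha_motif must be in (0, 1], got {self.alpha_motif}")


def _load_gene_set(path: str | Path) -> set[str]:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and write the run report.

    Returns the report dict (also written to ``<outdir>/report.json``).
    Output files per group: ``entropy_<group>.tsv``, ``census_<group>.json``,
    ``cepin_<group>.tsv``; plus ``contrasts.tsv`` and ``report.json``.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    net = _stage("load_network")(load_network)(cfg.network)
    expr = _stage("load_expression")(load_expression)(cfg.expression, cfg.metadata)
    n_genes_raw = len(expr.genes)
    expr = _stage("filter")(filter_expressed_genes)(
        expr, cfg.sample_quantile, cfg.min_sample_frac)

    gene_sets = {name: _load_gene_set(p) for name, p in cfg.gene_sets.items()}

    groups = expr.groups
    if cfg.comparisons:
        pairs = [tuple(p) for p in cfg.comparisons]
        for a, b in pairs:
            for g in (a, b):
                if g not in groups:
                    raise PipelineError(f"stage 'contrasts' failed: group {g!r} "
                                        f"absent from metadata (has {groups})")
    else:
        pairs = list(itertools.combinations(groups, 2))

    cepins, profiles, censuses = {}, {}, {}
    needed = sorted({g for pair in pairs for g in pair}, key=groups.index)
    for grp in needed:
        cep = _stage("build_cepin")(build_cepin)(net, expr, grp, cfg.transform)
        cep.write(outdir / f"cepin_{grp}.tsv")
        prof = _stage("entropy")(entropy_profile)(cep)
        prof.write(outdir / f"entropy_{grp}.tsv")
        cen = _stage("motifs")(motif_census)(cep, cfg.alpha_motif)
        (outdir / f"census_{grp}.json").write_text(
            json.dumps(cen.as_dict(), indent=2) + "\n")
        cepins[grp], profiles[grp], censuses[grp] = cep, prof, cen

    contrasts = []
    for a, b in pairs:
        res = _stage("contrasts")(compare_groups)(
            cepins[a], cepins[b], gene_sets or None, cfg.alpha_motif, cfg.paired)
        contrasts.append(res.as_dict())

    report = {
        "tool": {"name": "cepin", "version": __version__},
        "config": asdict(cfg),
        "provenance": {
            "n_network_nodes": net.number_of_nodes(),
            "n_network_edges": net.number_of_edges(),
            "n_genes_loaded": n_genes_raw,
            "n_genes_after_filter": len(expr.genes),
            "n_samples": len(expr.samples),
            "groups": {g: len(expr.samples_in_group(g)) for g in groups},
            "dropped_undefined_edges": {g: cepins[g].n_dropped_undefined for g in cepins},
        },
        "entropy_summaries": {g: profiles[g].summary() for g in profiles},
        "motif_censuses": {g: censuses[g].as_dict() for g in censuses},
        "contrasts": contrasts,
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

    flat_rows = []
    for c in contrasts:
        row = {"group_a": c["group_a"], "group_b": c["group_b"],
               "n_genes_a": c["n_genes_a"], "n_genes_b": c["n_genes_b"],
               "statistic": c["statistic"], "pvalue": c["pvalue"],
               "direction": c["direction"]}
        mc = c.get("motif_contrast") or {}
        row["p_um_a"] = mc.get("p_um_a")
        row["p_um_b"] = mc.get("p_um_b")
        flat_rows.append(row)
    pd.DataFrame(flat_rows).to_csv(outdir / "contrasts.tsv", sep="\t", index=False)
    return report
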
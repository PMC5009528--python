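# cepin

Network entropy and signed-motif analysis of co-expressed
protein-interaction networks (CePINs), for systems-biology studies that ask
whether one condition's cellular network is more *heterogeneous* than
another's — tumor vs normal tissue, stages of progression, smokers vs
non-smokers, drug-resistant vs sensitive cell lines.

## The measures

Starting from an undirected protein-interaction network (PIN) and a
genes × samples expression matrix with per-sample group labels, the
pipeline builds one **CePIN** per group: each PIN edge *ij* gets the
Pearson correlation *r<sub>ij</sub>* of its endpoint genes across the
group's samples, the weight

> *w<sub>ij</sub>* = (1 + *r<sub>ij</sub>*)/2 ∈ [0, 1],

and a two-sided significance *p* from the regression F statistic
*F* = *r*²(*n*−2)/(1−*r*²) on (1, *n*−2) df. Two quantities are then read
off each CePIN:

**Local network entropy.** For gene *i* with neighbors *N(i)*, degree
*k<sub>i</sub>*, and proportions
*p<sub>ij</sub>* = *w<sub>ij</sub>* / Σ<sub>j∈N(i)</sub> *w<sub>ij</sub>*,

> *S<sub>i</sub>* = −(1/log *k<sub>i</sub>*) Σ<sub>j∈N(i)</sub> *p<sub>ij</sub>* log *p<sub>ij</sub>* ∈ [0, 1].

*S<sub>i</sub>* = 1 when co-expression spreads uniformly over the gene's
partners (promiscuous, disordered signaling) and 0 when it concentrates on
one partner. Entropy is computed on the full CePIN.

**Structural balance of signed triangles.** On the significance-filtered
CePIN (*p* < 0.05), each edge is signed by its correlation. A triangle
with an odd number of positive edges (3 or 1) is *balanced*; with an even
number (2 or 0), *unbalanced*. The disorder index is

> *p<sub>um</sub>* = *N<sub>um</sub>* / *N<sub>tm</sub>*,

the unbalanced fraction among all triangles.

Groups are contrasted with an unpaired two-sided Wilcoxon rank-sum test on
the per-gene entropy vectors, optionally restricted to gene sets
(oncogenes, tumor suppressors, …), with motif censuses attached.

Before any of this, genes pass a two-step expressed-gene filter: (i) per
sample, a gene is expressed iff its value exceeds the sample's 20 %
expression quantile; (ii) genes expressed in under 20 % of samples are
dropped.

## Worked example

The built-in generator produces a modular interactome and paired cohorts:
a *coherent* group with strong sign-structured module co-expression and a
*degraded* group in which that structure decays — the statistical caricature
of normal vs tumor. `examples/04_group_contrast.py`:

```python
from cepin import (SyntheticConfig, generate_dataset, filter_expressed_genes,
                   build_cepin, compare_groups)

cfg = SyntheticConfig(seed=42)        # 300 genes, 60 samples/group
net, expr = generate_dataset(cfg)
expr = filter_expressed_genes(expr)
res = compare_groups(build_cepin(net, expr, "coherent"),
                     build_cepin(net, expr, "degraded"))
```

prints

```
entropy medians: 0.9848 (coherent) vs 0.9903 (degraded)
Wilcoxon rank-sum: U = 33508, p = 4.05e-07
higher-entropy group: degraded
p_um: 0.0000 (coherent) vs 0.0076 (degraded)
```

The degraded condition has significantly higher per-gene entropy and a
larger unbalanced-triangle fraction: more heterogeneous and less
structurally stable, the signature this analysis was built to detect. The
other scripts in `examples/` walk through the generator, the entropy
profile, and the motif census one capability at a time.

A `cepin` command-line tool wraps the same library
(`cepin simulate`, `cepin run`, plus stagewise `build` / `entropy` /
`motifs` / `compare`); `cepin run` writes per-gene entropy tables, motif
censuses, a contrast table, and a JSON report embedding the resolved
configuration and per-stage accounting.

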
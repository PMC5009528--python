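# Methods

## Model and procedure

The pipeline quantifies cellular network heterogeneity from the interplay
of a static protein-interaction network (PIN) and condition-specific
co-expression. For each sample group it builds a co-expressed PIN (CePIN):
the PIN restricted to the expressed genes, with each edge *ij* annotated by
the Pearson correlation *r* of its endpoints across the group's samples,
the weight *w* = (1+*r*)/2, and the two-sided significance of *r* from the
simple-regression F statistic *F* = *t*² = *r*²(*n*−2)/(1−*r*²) on
(1, *n*−2) df (identical to the t test for a correlation; cross-checked
against `scipy.stats.pearsonr` in the tests).

Two measures are read off each CePIN:

- **Local network entropy** per gene: proportions
  *p_ij* = *w_ij*/Σ*w_ij* over the gene's incident edges, then
  *S_i* = −Σ *p_ij* log *p_ij* / log *k_i*, with natural logs (the base
  cancels) and 0·log 0 ≡ 0 so that an exact *r* = −1 edge contributes
  nothing. Entropy uses **all** CePIN edges: the significance filter
  belongs to the motif analysis only, where a sign must be trustworthy.
- **Signed-triangle balance** on the *p* < 0.05 edge-filtered CePIN:
  triangles classified by their count of positive edges (3 → balanced I,
  1 → balanced II, 2 → unbalanced II, 0 → unbalanced I); the unbalanced
  fraction *p_um* = *N_um*/*N_tm* indexes structural disorder.

Conditions are contrasted by an unpaired two-sided Wilcoxon rank-sum test
on the pooled per-gene entropy vectors (exact distribution when the smaller
sample has ≤ 8 untied values, otherwise the tie- and continuity-corrected
normal approximation via `scipy.stats.mannwhitneyu`). Genes eligible in
only one group stay in that group's vector; a paired signed-rank mode on
shared genes exists but is not the default, since the pooled unpaired
contrast is the primary design. Multiple contrasts (stage series, many
drugs) are reported with raw p-values; a Bonferroni column is optional.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `sample_quantile` | 0.20 | per-sample expression quantile a gene must strictly exceed to count as expressed in that sample |
| `min_sample_frac` | 0.20 | minimum fraction of samples (inclusive ≥) a gene must be expressed in |
| `transform` | `log2p1` | value transform before correlation (never before filtering); use `none` for already-log microarray intensities |
| `alpha_motif` | 0.05 | strict `p < alpha` edge filter for the motif census |

Quantiles use linear interpolation between order statistics (NumPy's
default, the "type 7" convention). The choice matters only for boundary
genes, so it is fixed and documented rather than configurable. Ties at the
quantile count as *not* expressed — this makes the all-constant matrix
degenerate case well defined (everything is filtered out) — while the
sample-fraction comparison is inclusive.

## Conventions and degenerate inputs

- Gene identity is the whitespace-trimmed symbol string, case preserved;
  inputs must be pre-harmonized to one symbol namespace (no ID mapping).
- Self-loops and duplicate PIN pairs (either orientation) are dropped at
  load time and counted; isolated nodes are retained in the node set but
  can never carry entropy.
- Degree-1 genes are excluded from entropy profiles (log 1 = 0 leaves
  *S_i* undefined); a fixed fill-in value would distort group comparisons
  because degree distributions differ between CePINs. Genes whose incident
  weights are all zero (every *r* = −1) are likewise excluded; both
  exclusions are reported with reasons.
- The degree *k_i* counts **all** neighbors, including zero-weight edges:
  a zero-weight edge leaves Σ *p* log *p* unchanged but still enlarges the
  normalizer log *k_i* (asserted in the tests).
- Edges touching a gene that is constant within a group are dropped from
  that group's CePIN rather than assigned *r* = 0: a constant gene carries
  no co-expression evidence, and a manufactured weight of 0.5 would inject
  entropy.
- An edge with *r* exactly 0 cannot survive the significance filter
  (*p* = 1), so the sign function treats *r* = 0 as an error — a guard
  against running the census on unfiltered networks.
- A filtered network with no triangles reports its motif fractions as
  undefined (`None`) with a warning, never as 0.
- No multiple-testing correction is applied to the per-edge 0.05 filter by
  design; the measures are descriptive network statistics, not edge-level
  discoveries.

Triangle enumeration is degree-ordered neighbor intersection with
lexicographic tie-breaks, so the census is deterministic and independent of
node or edge insertion order; correctness is defined against (and tested
against) exhaustive all-triples classification.

## The synthetic-data generator

The generator emulates exactly the features the measures respond to, and
nothing else. A modular interactome (default 300 genes: six 25-gene
modules wired at density 0.6, background Erdős–Rényi at density 0.02 —
sparse overall but triangle-rich inside modules, qualitatively like a
curated interactome) carries a two-factor latent model per module: gene
*g* in module *m* has

    x_gs = baseline + λ (cos θ_g · f1_ms + sin θ_g · f2_ms) + σ ε_gs
    θ_g  = base_g + (1 − λ) δ_g,   δ_g ~ U(−π, π),   base_g ∈ {0, π}

with *f*, *ε* standard normal, baseline 10, σ = `noise_sd` = 0.3, and
base_g = π with probability `negative_fraction` = 0.3. The loading λ is
0.8 in the coherent group and 0.3 in the degraded group (60 samples each).

One parameter, λ, thus controls both facets of co-expression coherence:
its *magnitude* (expected within-module correlation
cos(θ_g−θ_h)·λ²/(λ²+σ²), ≈ 0.88·cos Δθ coherent vs ≈ 0.5·cos Δθ degraded)
and its *sign structure* (at high λ every gene sits on its base axis, edge
signs reduce to the product of axis signs, and every module triangle is
balanced; at low λ the angles disperse, weights crowd 0.5, and triplets at
intermediate angles yield genuinely unbalanced sign patterns). The noise
scale is set equal to the degraded loading so that signal-to-noise is 1:1
in the degraded state — weak mixed-sign correlations still reach
significance at *n* = 60, which is what lets the degraded census contain
unbalanced triangles rather than nothing at all. With equal loadings the
two groups are exchangeable by construction, so the null contrast is
calibrated. One global seed feeds separate derived streams for the
network, the gene axes, and each group's matrix, so adding a group never
perturbs the network and identical configurations are bit-reproducible.

What the generator does **not** emulate: count-distribution realism
(negative binomial dispersion, library-size variation), batch structure,
or any dependence beyond one factor pair per module. Passing tests
therefore demonstrate that the measures recover planted coherence
differences through the full pipeline — not that real tumor cohorts carry
such differences; on real data the transform choice and the unstated
normalization of the inputs matter more than they can here.

## Problem sizes and numerics

Tests and the acceptance script run the default study (300 genes, ~2,000
edges, 60 samples per group) and oracle checks on graphs of up to a few
hundred nodes — sizes where the exhaustive oracles (all-triples triangle
classification, all-720-permutations correlation null at *n* = 6,
rank-assignment enumeration for the exact rank-sum) are themselves cheap to
evaluate, chosen so the whole suite completes in seconds. Entropy values
are clamped to [0, 1] against roundoff; agreement with the brute-force
evaluation is asserted to 1e−12. The parametric correlation p is compared
to the exhaustive permutation null within 0.1, the small-sample gap between
normal-theory and exact permutation inference at *n* = 6. Type-I
calibration of the edge filter is asserted within three binomial standard
errors at 2,500 null edges.

## Known limitations

- Pearson correlation only; no partial correlation or mutual information.
- The local entropy is the simple per-node measure, not a
  stationary-distribution-weighted global entropy rate.
- Balance analysis stops at triangles; no higher-order motifs and no null
  model for *p_um* (raw ratios are compared, by design).
- Expression inputs are taken as normalized; the package does not
  normalize, batch-correct, or map identifiers.
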
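"""Build one group's CePIN and profile its local network entropy.

A gene's entropy S_i is the Shannon entropy of its normalized incident
edge weights w_ij = (1 + r_ij)/2, divided by log(degree): S_i = 1 when
co-expression spreads evenly over all neighbors (disordered), S_i = 0 when
it concentrates on a single partner.
"""

from cepin import (SyntheticConfig, generate_dataset, filter_expressed_genes,
                   build_cepin, entropy_profile, gene_set_profile)

cfg = SyntheticConfig(seed=42)
net, expr = generate_dataset(cfg)
expr = filter_expressed_genes(expr)  # two-step 20 % expressed-gene filter

for group in ("coherent", "degraded"):
    cep = build_cepin(net, expr, group)  # log2(x+1) transform by default
    prof = entropy_profile(cep)
    s = prof.summary()
    print(f"{group:>8}: n = {s['n']:3d} genes, "
          f"mean S = {s['mean']:.4f} +/- {s['sem']:.4f} (SEM), "
          f"median = {s['median']:.4f}")
    module_genes = {g for g in net.nodes if net.nodes[g].get("module") is not None}
    sub = gene_set_profile(prof, module_genes)
    print(f"          module genes only: mean S = {sub.summary()['mean']:.4f}")
# The degraded group sits closer to the S = 1 ceiling: weakened, more
# uniform co-expression raises every gene's local entropy, and the effect
# is carried by the module genes (background genes are near 1 in both).
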
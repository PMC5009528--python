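"""Census of balanced vs unbalanced signed triangles in each condition.

Edges of the significance-filtered CePIN (correlation p < 0.05) are signed
by their correlation.  A triangle with an odd number of positive edges is
structurally balanced; p_um, the unbalanced fraction, indexes network
disorder.
"""

from cepin import (SyntheticConfig, generate_dataset, filter_expressed_genes,
                   build_cepin, motif_census)

cfg = SyntheticConfig(seed=42)
net, expr = generate_dataset(cfg)
expr = filter_expressed_genes(expr)

for group in ("coherent", "degraded"):
    cep = build_cepin(net, expr, group)
    census = motif_census(cep, alpha=0.05)
    row = census.table_row()
    print(f"{group:>8}: {census.n_tm:4d} triangles | "
          + " ".join(f"{t}={census.counts[t]}" for t in census.counts)
          + f" | balanced {row['fraction_balanced']:.3f}"
          + f" unbalanced {row['fraction_unbalanced']:.3f}")
# The coherent group's signs follow its module sign structure, so nearly
# every triangle is balanced (fraction ~1.000).  The degraded group keeps
# far fewer significant triangles and a visible unbalanced remainder --
# the same direction of change seen between normal and tumor tissue.
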
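"""Downstream analysis: differential expression, co-expression screening,
clustering, and reference-gene stability ranking."""

import numpy as np

from boutiquenorm import (
    SimulationConfig,
    cluster_expression,
    coexpression_screen,
    differential_expression,
    genorm_stability,
    median_scale_rows,
    rims_normalize,
    simulate_experiment,
)

cfg = SimulationConfig(n_probesets=300, n_invariant=60, n_marker=10, seed=9)
plm, annot, truth = simulate_experiment(cfg)
expr, _ = rims_normalize(plm, annot.ids_in_category("invariant"))

groups = expr.groups()
res = differential_expression(expr, {"control": groups["control"],
                                     "treated": groups["treated"]})
sig = res.significant_ids
true = set(truth.shifted_ids)
print(f"differential expression at q < 0.05: {len(sig)} called, "
      f"{sum(s in true for s in sig)} of {len(true)} true inductions found")

seed_gene = truth.shifted_ids[0]
co = coexpression_screen(expr, seed_gene)
frac_true = np.mean([g in true for g in co.index])
print(f"co-expression with {seed_gene}: {len(co)} genes at r^2 >= 0.7 "
      f"({frac_true:.0%} are truly co-induced)")

scaled = median_scale_rows(expr)
tree = cluster_expression(scaled.loc[sig[:40]])
print(f"clustered {len(tree.leaf_order)} significant genes; "
      f"first merge at height {tree.merges[0][2]:.4f} (1 - Pearson r)")

inv = annot.ids_in_category("invariant")[:10]
stab = genorm_stability(2.0 ** expr.values.loc[inv])
print("most stable reference candidates (geNorm M, lower = better):")
print(stab.table.head(4).round(4).to_string())
# Genes with low M keep constant expression ratios across samples and
# make good qRT-PCR reference genes.
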
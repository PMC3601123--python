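"""Simulate a boutique family chip and normalize it three ways.

Builds a probe-level dataset (700 probe sets, 11 PM/MM pairs each, two
conditions x 3 replicates) in which 70% of the expressed family genes are
induced 4-fold in the treated condition, then runs stable-gene quantile
normalization (SBQ), RMA + median-absent scaling (RMAPS) and RMA +
invariant-median scaling (RIMS).
"""

import numpy as np

from boutiquenorm import (
    SimulationConfig,
    mas5_detection,
    rims_normalize,
    rma_summarize,
    rmaps_normalize,
    sbq_normalize,
    simulate_experiment,
)

cfg = SimulationConfig(seed=42)
plm, annot, truth = simulate_experiment(cfg)
print(f"simulated {len(plm.probesets)} probe sets x {plm.n_arrays} arrays "
      f"({len(truth.shifted_ids)} genes induced in '{cfg.shifted_condition}')")

invariants = annot.ids_in_category("invariant")

# SBQ: summarize without cross-array quantile normalization, then anchor
# every array's distribution on the invariant genes
raw = rma_summarize(plm, quantile=False)
sbq = sbq_normalize(raw, invariants)

calls = mas5_detection(plm)
rmaps, rmaps_report = rmaps_normalize(plm, calls)
rims, rims_report = rims_normalize(plm, invariants)

est = {}
for name, expr in (("sbq", sbq), ("rmaps", rmaps), ("rims", rims)):
    groups = expr.groups()
    lfc = (expr.values[groups["treated"]].mean(axis=1)
           - expr.values[groups["control"]].mean(axis=1))
    est[name] = lfc[truth.shifted_ids].mean()

print(f"true induction: {cfg.effect_log2:.2f} log2")
for name, val in est.items():
    print(f"  {name:6s} estimated mean fold change of induced genes: "
          f"{val:.2f} log2")
print("RMAPS group offsets (log2):",
      {g: round(o, 3) for g, o in rmaps_report.offsets.items()},
      f"anchored on {rmaps_report.anchor_n} always-absent probe sets")
# SBQ and RIMS keep most of the true 2.0 log2 induction (the remaining
# shortfall is the usual RMA-style attenuation of fold changes for genes
# near the background level), while normalizations that force arrays to
# share a global distribution shrink the induced genes much further.
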
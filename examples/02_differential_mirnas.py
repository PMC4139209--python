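"""Permutation-ANOVA screen for condition-regulated miRNAs.

Simulates the default study, tests every probe across the 8 conditions with
the permutation F-test (1,000 label permutations) and classifies each
(probe, condition) pair by linear fold change: down < 0.8, up > 1.2, both at
p <= 0.05.  The two focal miRNAs should be called up in late denervation.
"""

from atromir import (SimulationConfig, classify_de, fold_change,
                     permutation_anova, simulate_expression)

mirna, _, _ = simulate_expression(SimulationConfig(rng_seed=7))
results = {r.feature_id: r for r in
           permutation_anova(mirna, n_perm=1000, rng_seed=7)}

background = next(n for n in mirna.feature_ids
                  if n.startswith("miR-bg-") and results[n].tested)
print(f"{'miRNA':12s} {'p_perm':>8s}  Den7 fc/class    Den14 fc/class")
for name in ("miR-206", "miR-21", background):
    r = results[name]
    cells = [f"{name:12s}", f"{r.p_perm:8.4f}"]
    for cond in ("Den7", "Den14"):
        fc = fold_change(mirna, cond)[name]
        cells.append(f"{fc:5.2f} {classify_de(fc, r.p_perm):9s}")
    print("  ".join(cells))
print("\nThe planted miRNAs are significant and >1.2-fold up in late "
      "denervation; background probes sit in the dead band.")
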
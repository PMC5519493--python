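"""The double-dissociation battery: 2x2 ANOVAs on held-out sessions.

Runs the full flow at the powered study conditions: seeds and a priori
regions are fixed using only the odd (discovery) sessions; each even
(replication) session then contributes one Fisher-z value per
(seed, target) cell, giving balanced 2x2 designs with 12 values per
cell.  A crossover interaction in a zone means each seed correlates
more with its own network's target there — in both directions.
"""

from interdigitate.experiments import power_battery

report = power_battery(master_seed=1)
df = report.to_frame()

print(df[["subject", "zone", "mean_AA", "mean_AB", "mean_BA", "mean_BB",
          "F_interaction", "p_interaction", "crossover_class"]]
      .round(3).to_string(index=False))
print(f"\n{report.n_significant}/{report.n_tests} interactions significant at "
      f"p < {report.alpha}; {report.n_crossover} crossover")
print(f"expected false positives under the null: {report.null_expectation:.1f}")
print("all 20 tests significant with crossover = the two planted networks"
      " are doubly dissociated in every zone and subject")
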
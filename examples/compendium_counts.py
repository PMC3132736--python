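"""Class/subtype bookkeeping and balanced subsampling on a synthetic compendium.

Simulates a compendium whose good/poor-prognosis counts per subtype equal a
published 892-sample breast-cancer compendium, prints its count table, and
draws a balanced sub-compendium (identical per-subtype class counts via
undersampling of the majority class).
"""

from strateval import count_table, draw_balanced_compendium, max_balanced_sizes
from strateval.synthetic import TABLE1_COUNTS, simulate_compendium, table1_config

compendium, truth = simulate_compendium(table1_config(n_genes=250), seed=0)
table = count_table(compendium, order=list(TABLE1_COUNTS))

print("subtype x class count table (ratio = good:poor prognosis):")
print(table.to_frame())
print()
print("per-subtype share of the compendium (%):",
      {s: round(float(v), 1) for s, v in table.shares().items()})

n_neg, n_pos = max_balanced_sizes(table)
balanced = draw_balanced_compendium(compendium, seed=0)
print()
print(f"a fully balanced compendium holds at most {n_neg} negatives and "
      f"{n_pos} positives per subtype -> {len(balanced.sample_ids)} samples total")
bal_table = count_table(compendium.subset(list(balanced.sample_ids)))
print("balanced draw ratios per subtype:",
      {s: round(float(v), 2) for s, v in bal_table.ratios.items()})
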
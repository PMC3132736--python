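"""Enumerate all partitions of a four-subtype alphabet and their merge lattice.

Each partition of {lumA, lumB, Her2, basal} is one stratification scheme:
one predictor per part. The Hasse diagram connects partitions that differ by
a single merge of two parts.
"""

from strateval import (
    ElementarySubtypeSet,
    enumerate_compound_subtypes,
    enumerate_partitions,
    hasse_edges,
    partition_label,
)

subtypes = ElementarySubtypeSet(["lumA", "lumB", "Her2", "basal"])

compound = enumerate_compound_subtypes(subtypes)
partitions = enumerate_partitions(subtypes)
edges = hasse_edges(partitions)

print(f"{len(subtypes)} elementary subtypes -> {len(compound)} compound subtypes "
      f"(2^4 - 1), {len(partitions)} partitions (Bell(4)), {len(edges)} merge edges")
print()
print("partitions, coarse to fine (one predictor per '|'-separated part):")
for p in partitions:
    print(f"  {len(p)} part(s): {partition_label(p, subtypes)}")
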
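"""Derive MIE labels from chemical-protein annotations and cluster paralogs.

Builds a small synthetic annotation table, resolves opposing-mode
conflicts, drops unspecified-mode records, and merges MIEs whose chemical
sets have Jaccard dissimilarity below the 0.7 cut height.
"""

from miescreen import SimConfig, simulate_dataset
from miescreen.annotations import build_mies, cluster_mies, derive_mie_records

dataset = simulate_dataset(SimConfig(seed=1))
records = derive_mie_records(dataset.records, min_support=5)
print(f"{len(dataset.records)} raw annotation rows -> "
      f"{len(records)} MIE records after conflict resolution")

clusters = cluster_mies(build_mies(records), cut_height=0.7)
for c in clusters:
    print(f"  {c.display_name:16s} members={sorted(c.members)} "
          f"chemicals={len(c.chemicals)}")

# Paralog target pairs (e.g. PRL0A/PRL0B) share >= 90% of their chemicals,
# so they collapse into one cluster and will be modelled by one classifier;
# unrelated targets keep their own singleton clusters.
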
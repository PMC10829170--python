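"""Scaffold-level mining of a DDI table: frequent patterns, profiles, clusters.

Each drug pair becomes a transaction of its two Murcko scaffolds; FP-Growth
finds frequently co-occurring scaffold combinations and association rules
score how strongly one scaffold's presence predicts another's. Binary
profile matrices then describe each scaffold by its interaction partners or
its side effects, and scaffolds with similar profiles are clustered and
compared structurally.
"""

import ddikit as dk

# a deliberately small pair table: sparse profiles make the cluster
# structure visible (a saturated matrix has every scaffold meeting every other)
cfg = dk.FixtureConfig(n_scaffold_families=8, per_family=25, n_pairs=120, seed=0)
library = dk.generate_molecule_library(cfg)
pairs = dk.generate_ddi_dataset(library, cfg)

trans = dk.pair_transactions(pairs)
frequent = dk.fp_growth(trans, min_support=0.01)
print(f"{len(frequent)} frequent itemsets at 1% support; top 5:")
for itemset, support in frequent[:5]:
    print(f"  {sorted(itemset)}  support={support:.3f}")

rules = dk.association_rules(frequent, trans, min_confidence=0.3)
print(f"\n{len(rules)} association rules at confidence >= 0.3; strongest:")
r = rules[0]
print(f"  {sorted(r.antecedent)} -> {sorted(r.consequent)}  "
      f"support={r.support:.3f} confidence={r.confidence:.3f} lift={r.lift:.3f}")

matrix = dk.build_profile_matrix(pairs, "interaction")
print(f"\nbinary interaction profile matrix: {matrix.values.shape[0]} x "
      f"{matrix.values.shape[1]} scaffolds, {int(matrix.values.sum())} observed combinations")

# cut at a raw Jaccard distance to resolve profile families
labels = dk.cluster_binary_profiles(matrix, threshold=0.34, criterion="distance")
print("profile clusters:", len(set(labels)))

fps = [dk.circular_fingerprint(s if s else "C") for s in matrix.row_names]
intra, inter, table = dk.cluster_similarity_summary(labels, fps, metric="tanimoto")
print(f"mean Tanimoto within clusters {intra:.3f} vs across clusters {inter:.3f}")
# scaffolds sharing an interaction profile need not be structurally similar:
# on this tiny random table the within/across means are close, while larger
# tables with real interaction biology can pull intra above inter
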
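"""Between-network contrasts: difference networks and subgroup-unique pairs.

A-not-in-B keeps the significant edges of subgroup A absent from subgroup B;
a subgroup-unique pair is a significant edge present in exactly one of the
four diabetes-type x sex networks — the sex-specific co-occurrence
signatures the analysis is after.
"""

from morbnet import difference_network, unique_pairs
from morbnet.config import recovery_config
from morbnet.evaluation import subgroup_edge_sets
from morbnet.network import build_network
from morbnet.synthetic import planted_truth

cfg = recovery_config(n_per_cohort=10_000, seed=3)
edge_sets = subgroup_edge_sets(cfg)

nets = {}
for sg, keys in edge_sets.items():
    nodes = sorted({n for k in keys for n in k})
    nets[sg] = build_network(nodes, [(i, j, 0.5) for i, j in sorted(keys)], label=sg)

diff = difference_network(nets["T1DM_male"], nets["T1DM_female"])
print("male-not-in-female (T1DM) difference edges:")
for i, j, _ in diff.edges:
    print(f"  {i} - {j}")

print("\nsubgroup-unique significant pairs:")
uniq = unique_pairs(nets)
for sg, pairs in uniq.items():
    for i, j, _ in pairs:
        print(f"  {sg}: {i} - {j}")

truth = planted_truth(cfg)
print("\nplanted subgroup-unique ground truth (should match the above):")
for sg in nets:
    others = [o for o in nets if o != sg]
    only = truth.pairs_by_subgroup[sg] - frozenset().union(
        *(truth.pairs_by_subgroup[o] for o in others)
    )
    for i, j in sorted(only):
        print(f"  {sg}: {i} - {j}")
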
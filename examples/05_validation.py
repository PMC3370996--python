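"""Score predictions against known mutually exclusive groups.

Part 1 replays the seven-node worked example: three predicted clusters
against three ground-truth exclusivity groups, counted with the
per-cluster confusion scheme.  Part 2 runs the full synthetic two-group
study and pools the counts into summary statistics.
"""

from itertools import combinations

from mutexbind import MatchParams, confusion_counts, pairwise_match, surface_residues
from mutexbind.motifmatch import cluster_matches
from mutexbind.synthetic import make_two_group_subnetwork, make_worked_example
from mutexbind.validation import ExclusivityGroups, summary_statistics

ex = make_worked_example()
groups = ExclusivityGroups(ex.groups)
print("worked example (7 nodes, groups A1-A3 / B1-B3 / C1):")
for i, cluster in enumerate(ex.clusters, 1):
    c = confusion_counts(cluster, groups)
    print(f"  cluster {i} {sorted(cluster)}: TP={c.tp} FP={c.fp} "
          f"TN={c.tn} FN={c.fn}")
# e.g. cluster 1 {A1,A2,A3,B1,C1} is judged against the A-group: the
# three As are TP, B1 and C1 are FP, B2/B3 are TN, nothing is missed.

tg = make_two_group_subnetwork(seed=5)
surfaces = {c.chain_id: surface_residues(c) for c in tg.chains}
matches = []
for a, b in combinations(sorted(surfaces), 2):
    matches.extend(pairwise_match(surfaces[a], surfaces[b], MatchParams()))
clusters = cluster_matches(matches)
counts = [confusion_counts(frozenset(c.chains), ExclusivityGroups(tg.groups))
          for c in clusters]
stats = summary_statistics(counts, mode="pooled")
print("\nsynthetic two-group study (zero noise):")
print(f"  predicted clusters: {[c.chains for c in clusters]}")
print(f"  pooled Sp={stats.specificity:.1f}% Sn={stats.sensitivity:.1f}% "
      f"Acc={stats.accuracy:.1f}%")
# With clean planted groups the detector separates them perfectly:
# specificity = sensitivity = 100%.
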
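"""Ground truth, confusion counting, and summary statistics.

Two interactors of a hub are mutually exclusive when they engage
overlapping regions of the hub surface. Ground truth therefore comes from
hub-side interface residues of solved hub-node complexes: nodes whose hub
interfaces overlap are grouped together, and a predicted cluster is scored
against the best-overlapping group -- nodes of the cluster inside the
group are true positives, outside it false positives, group members the
cluster missed are false negatives, and the rest of the sub-network true
negatives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .structures import ComplexStructure, compute_sasa

logger = logging.getLogger(__name__)

DEFAULT_DASA_MIN = 0.1  # A^2 of buried area that makes a residue interfacial


def interface_residues(complex_: ComplexStructure, chain_x: str, chain_y: str,
                       dasa_min: float = DEFAULT_DASA_MIN,
                       n_points: int = 960) -> tuple[frozenset[int], frozenset[int]]:
    """Interface residues of both chains by the delta-ASA criterion.

    A residue is interfacial when its accessible surface area on the
    isolated chain exceeds its area in the two-chain context by more than
    ``dasa_min`` A^2.
    """
    for c in (chain_x, chain_y):
        if c not in complex_:
            raise KeyError(f"chain {c!r} not present in complex")
    out = []
    for this, other in ((chain_x, chain_y), (chain_y, chain_x)):
        chain = complex_[this]
        isolated = compute_sasa(chain, n_points=n_points)
        in_context = compute_sasa(chain, n_points=n_points,
                                  context=[complex_[other]])
        out.append(frozenset(
            i for i in isolated if isolated[i] - in_context[i] > dasa_min))
    return out[0], out[1]


@dataclass
class ExclusivityGroups:
    """Partition of a sub-network's nodes by overlapping hub interfaces."""

    groups: list[frozenset[str]]
    unknown: frozenset[str] = frozenset()

    def __post_init__(self):
        all_nodes = [n for g in self.groups for n in g]
        if len(all_nodes) != len(set(all_nodes)):
            raise ValueError("exclusivity groups must be disjoint")

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(n for g in self.groups for n in g)


def ground_truth_groups(hub_interfaces: dict[str, frozenset | set | None],
                        overlap_min: int = 1) -> ExclusivityGroups:
    """Group nodes whose hub-side interfaces overlap.

    ``hub_interfaces`` maps each node to the set of hub residues it
    contacts (in a common hub numbering); nodes mapped to None lack a
    solved complex, become flagged singletons in ``unknown`` and are
    excluded from confusion counting.
    """
    labelled = {n: frozenset(s) for n, s in hub_interfaces.items() if s is not None}
    unknown = frozenset(n for n, s in hub_interfaces.items() if s is None)
    graph = nx.Graph()
    graph.add_nodes_from(labelled)
    for a, b in combinations(sorted(labelled), 2):
        if len(labelled[a] & labelled[b]) >= overlap_min:
            graph.add_edge(a, b)
    groups = sorted((frozenset(c) for c in nx.connected_components(graph)),
                    key=lambda g: sorted(g))
    return ExclusivityGroups(groups, unknown)


@dataclass
class ConfusionCounts:
    """Per-cluster confusion outcome against its reference group."""

    tp: int
    fp: int
    tn: int
    fn: int
    reference_group: frozenset[str]
    tp_set: frozenset[str]
    fp_set: frozenset[str]
    tn_set: frozenset[str]
    fn_set: frozenset[str]

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(cluster: frozenset[str] | set[str],
                     groups: ExclusivityGroups) -> ConfusionCounts:
    """Score one predicted cluster against the exclusivity groups.

    The reference group is the one overlapping the cluster most (ties:
    larger group, then the group with the lexicographically smallest
    member). TP = cluster inside the reference, FP = cluster outside it,
    FN = reference members missed, TN = everything else in the sub-network.
    """
    cluster = frozenset(cluster)
    if not cluster:
        raise ValueError("cluster is empty")
    universe = groups.universe
    if not cluster <= universe:
        raise ValueError(f"cluster nodes outside sub-network: "
                         f"{sorted(cluster - universe)}")
    reference = min(groups.groups,
                    key=lambda g: (-len(cluster & g), -len(g), min(g)))
    tp_set = cluster & reference
    fp_set = cluster - reference
    fn_set = reference - cluster
    tn_set = universe - cluster - reference
    return ConfusionCounts(len(tp_set), len(fp_set), len(tn_set), len(fn_set),
                           reference, tp_set, fp_set, tn_set, fn_set)


@dataclass
class SummaryStats:
    """Specificity / sensitivity / PPV / NPV / accuracy, in percent."""

    specificity: float
    sensitivity: float
    ppv: float
    npv: float
    accuracy: float

    def as_dict(self) -> dict[str, float]:
        return {
            "specificity": self.specificity,
            "sensitivity": self.sensitivity,
            "ppv": self.ppv,
            "npv": self.npv,
            "accuracy": self.accuracy,
        }


def _stats_from_counts(tp: int, fp: int, tn: int, fn: int) -> dict[str, float | None]:
    def ratio(num, den):
        return 100.0 * num / den if den else None

    return {
        "specificity": ratio(tn, tn + fp),
        "sensitivity": ratio(tp, tp + fn),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": ratio(tp + tn, tp + fp + tn + fn),
    }


def summary_statistics(counts: list[ConfusionCounts] | list[tuple[int, int, int, int]],
                       mode: str = "pooled") -> SummaryStats:
    """Summary statistics over many confusion records.

    pooled: sum the counts, then apply the formulas (the default -- the
    printed reference statistics are consistent with summed counts);
    macro: apply the formulas per record and average the defined values.
    """
    if not counts:
        raise ValueError("need at least one confusion record")
    records = [
        (c.tp, c.fp, c.tn, c.fn) if isinstance(c, ConfusionCounts) else tuple(c)
        for c in counts
    ]
    if mode == "pooled":
        tp, fp, tn, fn = (sum(r[i] for r in records) for i in range(4))
        stats = _stats_from_counts(tp, fp, tn, fn)
        return SummaryStats(**{k: (v if v is not None else float("nan"))
                               for k, v in stats.items()})
    if mode == "macro":
        acc: dict[str, list[float]] = {k: [] for k in
                                       ("specificity", "sensitivity", "ppv",
                                        "npv", "accuracy")}
        for r in records:
            stats = _stats_from_counts(*r)
            for k, v in stats.items():
                if v is None:
                    logger.info("macro averaging: %s undefined for record %s", k, r)
                else:
                    acc[k].append(v)
        return SummaryStats(**{
            k: (sum(v) / len(v) if v else float("nan")) for k, v in acc.items()})
    raise ValueError(f"unknown averaging mode {mode!r}")


@dataclass
class InterfaceRecovery:
    """How much of a node's true interface a predicted motif recovers."""

    n_interface: int
    n_correct: int
    hit_at_1: bool
    hit_at_3: bool


def interface_recovery(cluster, node: str,
                       true_interface: frozenset[int] | set[int]) -> InterfaceRecovery:
    """Overlap between a cluster's motif residues on ``node`` and the
    node's true interface; hits at >= 1 and >= 3 recovered residues are
    both reported since either convention appears in practice."""
    if node not in cluster.chains:
        raise KeyError(f"node {node!r} not in cluster")
    predicted = set(cluster.residue_sets[node])
    true_set = set(true_interface)
    n_correct = len(predicted & true_set)
    return InterfaceRecovery(
        n_interface=len(true_set),
        n_correct=n_correct,
        hit_at_1=n_correct >= 1,
        hit_at_3=n_correct >= 3,
    )


def read_group_labels(stream) -> ExclusivityGroups:
    """Read pre-labelled ground truth TSV: node, group_id."""
    by_group: dict[str, set[str]] = {}
    for raw in stream:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        node, group_id = line.split("\t")[:2]
        by_group.setdefault(group_id, set()).add(node)
    groups = sorted((frozenset(g) for g in by_group.values()),
                    key=lambda g: sorted(g))
    return ExclusivityGroups(groups)
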
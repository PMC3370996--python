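"""Ground truth, confusion counting, summary statistics, interface recovery."""

import io

import numpy as np
import pytest

from mutexbind.structures import surface_residues
from mutexbind.synthetic import (
    FixtureSpec,
    make_toy_chain,
    make_toy_complex,
    make_worked_example,
)
from mutexbind.validation import (
    ExclusivityGroups,
    confusion_counts,
    ground_truth_groups,
    interface_recovery,
    interface_residues,
    read_group_labels,
    summary_statistics,
)

from conftest import match_subnetwork, planted_trio


@pytest.fixture(scope="module")
def hub_chain():
    return make_toy_chain(FixtureSpec(seed=90, n_residues=24, scaffold="helix"),
                          chain_id="H")


@pytest.fixture(scope="module")
def node_chain():
    return make_toy_chain(FixtureSpec(seed=91, n_residues=8, scaffold="strand"),
                          chain_id="N")


class TestInterfaceResidues:
    def test_distant_chains_have_no_interface(self, hub_chain, node_chain):
        from mutexbind.structures import ComplexStructure

        far = node_chain.transformed(np.eye(3), np.array([80.0, 0.0, 0.0]))
        cplx = ComplexStructure({"H": hub_chain, "N": far})
        on_h, on_n = interface_residues(cplx, "H", "N")
        assert on_h == frozenset() and on_n == frozenset()

    def test_contact_complex_interface_within_patch(self, hub_chain, node_chain):
        surf = surface_residues(hub_chain)
        center = surf.members[len(surf.members) // 2]
        toy = make_toy_complex(hub_chain, node_chain, center, seed=5)
        on_h, on_n = interface_residues(toy.complex, "H", "N")
        assert on_h and on_n
        assert on_h <= set(toy.hub_patch)

    def test_swapping_chains_swaps_sets(self, hub_chain, node_chain):
        surf = surface_residues(hub_chain)
        center = surf.members[len(surf.members) // 2]
        toy = make_toy_complex(hub_chain, node_chain, center, seed=5)
        on_h, on_n = interface_residues(toy.complex, "H", "N")
        on_n2, on_h2 = interface_residues(toy.complex, "N", "H")
        assert on_h == on_h2 and on_n == on_n2

    def test_missing_chain_rejected(self, hub_chain):
        from mutexbind.structures import ComplexStructure

        cplx = ComplexStructure({"H": hub_chain})
        with pytest.raises(KeyError):
            interface_residues(cplx, "H", "Z")


class TestGroundTruthGroups:
    def test_three_patches_make_three_groups(self):
        interfaces = {
            "A1": frozenset({1, 2, 3}), "A2": frozenset({2, 3, 4}),
            "A3": frozenset({1, 4}),
            "B1": frozenset({10, 11}), "B2": frozenset({11, 12}),
            "B3": frozenset({10, 12}),
            "C1": frozenset({20, 21}),
        }
        groups = ground_truth_groups(interfaces)
        assert set(groups.groups) == {
            frozenset({"A1", "A2", "A3"}),
            frozenset({"B1", "B2", "B3"}),
            frozenset({"C1"}),
        }

    def test_single_patch_single_group(self):
        interfaces = {n: frozenset({5, 6}) for n in ("X", "Y", "Z")}
        groups = ground_truth_groups(interfaces)
        assert groups.groups == [frozenset({"X", "Y", "Z"})]

    def test_chain_of_overlaps_closes_transitively(self):
        interfaces = {
            "A": frozenset({1, 2}),
            "B": frozenset({2, 3}),
            "C": frozenset({3, 4}),
        }
        groups = ground_truth_groups(interfaces)
        assert groups.groups == [frozenset({"A", "B", "C"})]

    def test_unknown_nodes_are_flagged_not_grouped(self):
        interfaces = {"A": frozenset({1}), "B": frozenset({1}), "C": None}
        groups = ground_truth_groups(interfaces)
        assert groups.unknown == frozenset({"C"})
        assert "C" not in groups.universe

    def test_node_order_invariance(self):
        rng = np.random.default_rng(12)
        nodes = [f"n{i}" for i in range(8)]
        interfaces = {n: frozenset(rng.choice(12, size=3, replace=False))
                      for n in nodes}
        base = ground_truth_groups(interfaces)
        shuffled = dict(reversed(list(interfaces.items())))
        again = ground_truth_groups(shuffled)
        assert set(base.groups) == set(again.groups)


class TestConfusionCounts:
    """The seven-node worked example: every assignment checked verbatim."""

    def setup_method(self):
        self.example = make_worked_example()
        self.groups = ExclusivityGroups(self.example.groups)

    def test_cluster_one(self):
        c = confusion_counts(self.example.clusters[0], self.groups)
        assert c.tp_set == {"A1", "A2", "A3"}
        assert c.fp_set == {"B1", "C1"}
        assert c.tn_set == {"B2", "B3"}
        assert c.fn_set == frozenset()
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 2, 0)

    def test_cluster_two(self):
        c = confusion_counts(self.example.clusters[1], self.groups)
        assert c.tp_set == {"B2", "B3"}
        assert c.fp_set == {"A1"}
        assert c.tn_set == {"A2", "A3", "C1"}
        assert c.fn_set == {"B1"}
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 3, 1)

    def test_cluster_three(self):
        c = confusion_counts(self.example.clusters[2], self.groups)
        assert c.tp_set == {"A1", "A3"}
        assert c.fp_set == {"C1"}
        assert c.tn_set == {"B1", "B2", "B3"}
        assert c.fn_set == {"A2"}
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 3, 1)

    def test_counts_partition_the_subnetwork(self):
        for cluster in self.example.clusters:
            c = confusion_counts(cluster, self.groups)
            assert c.total == 7

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(frozenset(), self.groups)

    def test_foreign_node_rejected(self):
        with pytest.raises(ValueError, match="Z9"):
            confusion_counts(frozenset({"Z9"}), self.groups)


class TestSummaryStatistics:
    def test_perfect_single_record(self):
        stats = summary_statistics([(3, 0, 4, 0)])
        for v in stats.as_dict().values():
            assert v == pytest.approx(100.0)

    def test_pooled_equals_macro_for_identical_records(self):
        records = [(2, 1, 3, 1)] * 5
        pooled = summary_statistics(records, "pooled").as_dict()
        macro = summary_statistics(records, "macro").as_dict()
        for k in pooled:
            assert pooled[k] == pytest.approx(macro[k])

    def test_macro_skips_undefined_denominators(self):
        # second record has no positives at all: sensitivity undefined
        stats = summary_statistics([(2, 0, 2, 0), (0, 0, 4, 0)], "macro")
        assert stats.sensitivity == pytest.approx(100.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summary_statistics([])


class TestInterfaceRecovery:
    def test_motif_inside_interface_counts_fully(self, planted_clusters):
        _, clusters, _ = planted_clusters
        cluster = clusters[0]
        truth = frozenset(cluster.residue_sets["A"])
        rec = interface_recovery(cluster, "A", truth)
        assert rec.n_correct == cluster.n_residues
        assert rec.hit_at_1 and rec.hit_at_3

    def test_disjoint_sets_miss(self, planted_clusters):
        _, clusters, _ = planted_clusters
        cluster = clusters[0]
        free = frozenset(range(100, 105))
        rec = interface_recovery(cluster, "A", free)
        assert rec.n_correct == 0 and not rec.hit_at_1 and not rec.hit_at_3

    def test_single_overlap_boundary(self, planted_clusters):
        _, clusters, _ = planted_clusters
        cluster = clusters[0]
        one = frozenset({sorted(cluster.residue_sets["A"])[0], 999})
        rec = interface_recovery(cluster, "A", one)
        assert rec.n_correct == 1 and rec.hit_at_1 and not rec.hit_at_3

    def test_node_outside_cluster_rejected(self, planted_clusters):
        _, clusters, _ = planted_clusters
        with pytest.raises(KeyError):
            interface_recovery(clusters[0], "Q", frozenset({1}))


def test_read_group_labels_round_trip():
    text = "A1\tg1\nA2\tg1\nB1\tg2\n# comment\nC1\tg3\n"
    groups = read_group_labels(io.StringIO(text))
    assert set(groups.groups) == {
        frozenset({"A1", "A2"}), frozenset({"B1"}), frozenset({"C1"})}


def test_end_to_end_two_planted_groups_perfect_recovery():
    """Two exclusivity groups, zero noise: pooled Sp = Sn = 100%."""
    from mutexbind.synthetic import make_two_group_subnetwork

    tg = make_two_group_subnetwork(seed=7)
    clusters, _ = match_subnetwork(tg.chains)
    groups = ExclusivityGroups(tg.groups)
    counts = [confusion_counts(frozenset(c.chains), groups) for c in clusters]
    assert {frozenset(c.chains) for c in clusters} == set(tg.groups)
    stats = summary_statistics(counts, "pooled")
    assert stats.specificity == pytest.approx(100.0)
    assert stats.sensitivity == pytest.approx(100.0)
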
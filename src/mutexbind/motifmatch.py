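"""Surface-motif matching and multi-chain clustering.

The matcher looks for the largest sets of residue pairs between the
surfaces of two chains that are structurally equivalent: sequence-order
independent, mutually close in space, with compatible internal distances,
superposable below an RMSD ceiling, and biochemically similar on average
(PAM250). Pairwise matches across a sub-network are then chained into
clusters of three or more proteins sharing a common surface substructure
-- the candidates for mutually exclusive binding.

Search strategy: candidate residue pairs form a product graph whose edges
encode distance compatibility (both the C-alpha and side-chain-centroid
internal distances must agree within a tolerance) and spatial
neighbourhood on both chains. Maximal cliques are enumerated; a clique
failing the RMSD or mean-PAM acceptance is explored by subset descent, so
on small inputs the accepted set equals an exhaustive subset search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from . import matrices
from .ranking import kabsch_superpose
from .structures import ChainStructure, SurfaceResidueSet


@dataclass
class MatchParams:
    """Thresholds of the matcher.

    rmsd_max:           acceptance ceiling on the joint pseudo-atom RMSD (A)
    pam_min:            minimum mean PAM250 score over the matched pairs
    min_residues:       smallest reportable match
    neighbor_cutoff:    C-alpha distance defining "neighbours in space" (A)
    distance_tolerance: allowed internal-distance disagreement (A)
    clique_cap:         largest clique explored (motifs are small)
    per_pair_pam:       alternative interpretation: require PAM250 >= 2 for
                        every pair instead of thresholding the mean
    """

    rmsd_max: float = 2.1
    pam_min: float = 1.2
    min_residues: int = 3
    neighbor_cutoff: float = 10.0
    distance_tolerance: float = 2.5
    clique_cap: int = 12
    per_pair_pam: bool = False

    def __post_init__(self):
        if min(self.rmsd_max, self.pam_min, self.neighbor_cutoff,
               self.distance_tolerance) <= 0:
            raise ValueError("thresholds must be strictly positive")
        if self.min_residues < 3:
            raise ValueError("min_residues must be >= 3")


@dataclass
class PairwiseMatch:
    """A residue correspondence between two chains.

    ``pairs`` maps residue indices of chain A onto chain B, one-to-one;
    ``rmsd`` is over the 2k pseudo-atoms (C-alpha + side-chain centroid of
    every paired residue, jointly superposed).
    """

    chain_a: ChainStructure
    chain_b: ChainStructure
    pairs: tuple[tuple[int, int], ...]
    rmsd: float
    mean_pam: float

    @property
    def residues_a(self) -> frozenset[int]:
        return frozenset(a for a, _ in self.pairs)

    @property
    def residues_b(self) -> frozenset[int]:
        return frozenset(b for _, b in self.pairs)

    def side(self, chain_id: str) -> frozenset[int]:
        if chain_id == self.chain_a.chain_id:
            return self.residues_a
        if chain_id == self.chain_b.chain_id:
            return self.residues_b
        raise KeyError(chain_id)


def pam250_similarity(res_a: str, res_b: str) -> int:
    """PAM250 log-odds score of two one-letter residues (X scores 0)."""
    return matrices.score(matrices.pam250(), res_a, res_b)


def _pseudo_atoms(chain: ChainStructure, indices) -> np.ndarray:
    pts = []
    for i in indices:
        r = chain.residues[i]
        pts.append(r.ca)
        pts.append(r.sc_centroid)
    return np.asarray(pts)


def _evaluate(surf_a: SurfaceResidueSet, surf_b: SurfaceResidueSet,
              pairs: tuple[tuple[int, int], ...],
              pam: dict[tuple[int, int], int],
              params: MatchParams) -> PairwiseMatch | None:
    """Superpose a candidate pair set; return a match iff it passes."""
    mean_pam = float(np.mean([pam[p] for p in pairs]))
    if mean_pam < params.pam_min:
        return None
    coords_a = _pseudo_atoms(surf_a.chain, [a for a, _ in pairs])
    coords_b = _pseudo_atoms(surf_b.chain, [b for _, b in pairs])
    rmsd = kabsch_superpose(coords_a, coords_b).rmsd
    if rmsd >= params.rmsd_max:
        return None
    return PairwiseMatch(surf_a.chain, surf_b.chain, pairs, rmsd, mean_pam)


def pairwise_match(surf_a: SurfaceResidueSet, surf_b: SurfaceResidueSet,
                   params: MatchParams | None = None) -> list[PairwiseMatch]:
    """All maximal accepted residue correspondences between two surfaces.

    Returns matches sorted by size (descending) then RMSD; every returned
    match satisfies the acceptance thresholds and no match's pair set is a
    subset of another's.
    """
    params = params or MatchParams()
    mem_a, mem_b = surf_a.members, surf_b.members
    if len(mem_a) < params.min_residues or len(mem_b) < params.min_residues:
        return []
    seq_a = surf_a.chain.sequence
    seq_b = surf_b.chain.sequence

    # candidate pairs: non-negative PAM250 (or >= 2 in per-pair mode)
    pam_floor = 2 if params.per_pair_pam else 0
    candidates = []
    pam: dict[tuple[int, int], int] = {}
    for a in mem_a:
        for b in mem_b:
            s = pam250_similarity(seq_a[a], seq_b[b])
            if s >= pam_floor:
                candidates.append((a, b))
                pam[(a, b)] = s
    if len(candidates) < params.min_residues:
        return []

    ca_a = surf_a.chain.ca_coords()
    ca_b = surf_b.chain.ca_coords()
    cen_a = np.array([r.sc_centroid for r in surf_a.chain.residues])
    cen_b = np.array([r.sc_centroid for r in surf_b.chain.residues])

    def dist(x, i, j):
        return float(np.linalg.norm(x[i] - x[j]))

    graph = nx.Graph()
    graph.add_nodes_from(range(len(candidates)))
    for i, j in combinations(range(len(candidates)), 2):
        a1, b1 = candidates[i]
        a2, b2 = candidates[j]
        if a1 == a2 or b1 == b2:
            continue  # enforce one-to-one mapping
        d_ca_a = dist(ca_a, a1, a2)
        d_ca_b = dist(ca_b, b1, b2)
        if d_ca_a > params.neighbor_cutoff or d_ca_b > params.neighbor_cutoff:
            continue
        if abs(d_ca_a - d_ca_b) > params.distance_tolerance:
            continue
        if abs(dist(cen_a, a1, a2) - dist(cen_b, b1, b2)) > params.distance_tolerance:
            continue
        graph.add_edge(i, j)

    cliques = [tuple(sorted(c)) for c in nx.find_cliques(graph)
               if len(c) >= params.min_residues]
    cliques.sort(key=lambda c: (-len(c), [candidates[i] for i in c]))

    accepted: list[PairwiseMatch] = []
    accepted_sets: list[frozenset] = []
    seen: set[frozenset] = set()

    def explore(vertex_set: frozenset) -> None:
        if vertex_set in seen or len(vertex_set) < params.min_residues:
            return
        seen.add(vertex_set)
        if any(vertex_set <= acc for acc in accepted_sets):
            return
        pairs = tuple(sorted(candidates[i] for i in vertex_set))
        match = _evaluate(surf_a, surf_b, pairs, pam, params)
        if match is not None:
            accepted.append(match)
            accepted_sets.append(vertex_set)
            return
        for v in sorted(vertex_set):
            explore(vertex_set - {v})

    for clique in cliques:
        if len(clique) > params.clique_cap:
            clique = clique[:params.clique_cap]
        explore(frozenset(clique))

    # cross-clique domination: drop matches contained in a larger accepted one
    final = []
    pair_sets = [frozenset(m.pairs) for m in accepted]
    for i, m in enumerate(accepted):
        if any(i != j and pair_sets[i] < pair_sets[j] for j in range(len(accepted))):
            continue
        if any(frozenset(f.pairs) == pair_sets[i] for f in final):
            continue
        final.append(m)
    final.sort(key=lambda m: (-len(m.pairs), m.rmsd, m.pairs))
    return final


@dataclass
class MotifCluster:
    """Three or more chains sharing a common surface substructure."""

    chains: tuple[str, ...]
    chain_structures: dict[str, ChainStructure]
    residue_sets: dict[str, frozenset[int]]
    positions: list[dict[str, int]]  # aligned motif positions, one per residue
    members: list[PairwiseMatch]
    cluster_id: int = 0

    @property
    def n_residues(self) -> int:
        return len(self.positions)

    @property
    def score(self) -> int:
        """Size-times-support significance score."""
        return self.n_residues * len(self.chains)

    def motif_pseudo_atoms(self, chain_id: str) -> np.ndarray:
        indices = [pos[chain_id] for pos in self.positions]
        return _pseudo_atoms(self.chain_structures[chain_id], indices)


def cluster_score(cluster: MotifCluster) -> int:
    """Number of motif residues x number of chains in the cluster."""
    return cluster.score


def cluster_matches(matches: list[PairwiseMatch], min_chains: int = 3,
                    overlap_min: int = 3) -> list[MotifCluster]:
    """Chain pairwise matches into multi-chain motif clusters.

    Matches are vertices; two matches are connected when they share a chain
    and their residue sets on that chain overlap in >= ``overlap_min``
    residues. Within every connected component touching >= ``min_chains``
    chains, a consensus group similarity is built by propagating residue
    correspondences (best match per chain pair) into equivalence classes;
    each maximal chain subset supported by >= 3 consistent classes becomes
    one cluster, so one over-merged component can still yield several
    clean clusters.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(len(matches)))
    for i, j in combinations(range(len(matches)), 2):
        mi, mj = matches[i], matches[j]
        shared = ({mi.chain_a.chain_id, mi.chain_b.chain_id}
                  & {mj.chain_a.chain_id, mj.chain_b.chain_id})
        if any(len(mi.side(c) & mj.side(c)) >= overlap_min for c in shared):
            graph.add_edge(i, j)

    clusters: list[MotifCluster] = []
    for component in nx.connected_components(graph):
        comp = sorted(component)
        chain_structs: dict[str, ChainStructure] = {}
        for idx in comp:
            m = matches[idx]
            chain_structs[m.chain_a.chain_id] = m.chain_a
            chain_structs[m.chain_b.chain_id] = m.chain_b
        if len(chain_structs) < min_chains:
            continue
        comp_matches = [matches[i] for i in comp]
        classes = _correspondence_classes(comp_matches)
        for chains, positions in _qualifying_chain_sets(
                classes, tuple(sorted(chain_structs)), min_chains):
            residue_sets = {
                c: frozenset(pos[c] for pos in positions) for c in chains}
            clusters.append(MotifCluster(
                chains, {c: chain_structs[c] for c in chains},
                residue_sets, positions,
                [m for m in comp_matches
                 if {m.chain_a.chain_id, m.chain_b.chain_id} <= set(chains)]))
    clusters.sort(key=lambda c: (-c.score, c.chains))
    for cid, c in enumerate(clusters, start=1):
        c.cluster_id = cid
    return clusters


def _correspondence_classes(matches: list[PairwiseMatch]) -> list[dict[str, int]]:
    """Consistent equivalence classes of (chain, residue) correspondences.

    Only the best match per chain pair (largest, then lowest RMSD)
    contributes links; residues joined transitively form a class, and a
    class survives only while it holds at most one residue per chain --
    conflicting assignments are discarded rather than guessed at.
    """
    best: dict[frozenset[str], PairwiseMatch] = {}
    for m in matches:
        key = frozenset((m.chain_a.chain_id, m.chain_b.chain_id))
        cur = best.get(key)
        if cur is None or (-len(m.pairs), m.rmsd, m.pairs) < \
                (-len(cur.pairs), cur.rmsd, cur.pairs):
            best[key] = m
    rgraph = nx.Graph()
    for m in best.values():
        ca, cb = m.chain_a.chain_id, m.chain_b.chain_id
        for a, b in m.pairs:
            rgraph.add_edge((ca, a), (cb, b))
    classes = []
    for cls in nx.connected_components(rgraph):
        per_chain: dict[str, list[int]] = {}
        for chain_id, idx in cls:
            per_chain.setdefault(chain_id, []).append(idx)
        if all(len(v) == 1 for v in per_chain.values()):
            classes.append({c: v[0] for c, v in per_chain.items()})
    return classes


def _qualifying_chain_sets(classes: list[dict[str, int]],
                           chains: tuple[str, ...], min_chains: int,
                           min_positions: int = 3):
    """Maximal chain subsets supported by >= ``min_positions`` classes.

    A chain set S qualifies when at least ``min_positions`` classes cover
    every chain of S; only qualifying sets not contained in a larger
    qualifying set are reported (with their positions restricted to S).
    Exhaustive over subsets -- components span few chains in practice.
    """
    qualifying: list[tuple[tuple[str, ...], list[dict[str, int]]]] = []
    for size in range(len(chains), min_chains - 1, -1):
        for subset in combinations(chains, size):
            if any(set(subset) <= set(q) for q, _ in qualifying):
                continue
            covered = [cls for cls in classes if set(subset) <= set(cls)]
            if len(covered) >= min_positions:
                positions = [{c: cls[c] for c in subset} for cls in covered]
                positions.sort(key=lambda pos: pos[subset[0]])
                qualifying.append((subset, positions))
    qualifying.sort(key=lambda item: item[0])
    return qualifying


def clusters_table(clusters: list[MotifCluster]) -> str:
    """Cluster report TSV, one row per (cluster, chain)."""
    lines = ["cluster_id\tchain\tresidue_list\tn_residues\tn_chains"
             "\tcluster_score\trmsd"]
    for c in clusters:
        rmsd = max(m.rmsd for m in c.members)
        for chain in c.chains:
            res_list = ",".join(
                c.chain_structures[chain].residues[i].seq_id
                for i in sorted(c.residue_sets[chain]))
            lines.append(f"{c.cluster_id}\t{chain}\t{res_list}\t{c.n_residues}"
                         f"\t{len(c.chains)}\t{c.score}\t{rmsd:.3f}")
    return "\n".join(lines) + "\n"
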
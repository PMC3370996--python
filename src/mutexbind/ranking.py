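"""Superposition, GDT_TS, conservation, and cluster ranking.

Clusters keep their size-times-support score as the primary ranking key;
BLOSUM30 conservation of the motif positions and the mean pairwise GDT_TS
of the superposed motifs break ties. ``rank_clusters`` can alternatively
sort by conservation first (``key='conservation'``) for users who prefer
the re-sorted view.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import matrices

GDT_CUTOFFS = (1.0, 2.0, 4.0, 8.0)


@dataclass
class SuperpositionResult:
    """Least-squares rigid superposition of B onto A."""

    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    gdt_ts: float | None = None


def kabsch_superpose(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Optimal rigid superposition (Kabsch, SVD with reflection correction).

    Returns the rotation R and translation t minimising
    ``|| A - (B R^T + t) ||``; reflections are never used, so chirality is
    preserved even for mirror-image inputs.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must both be k x 3")
    if len(a) < 3:
        raise ValueError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    h = b0.T @ a0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    fitted = b0 @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((a0 - fitted) ** 2, axis=1))))
    translation = ca - rot @ cb
    return SuperpositionResult(rot, translation, rmsd)


def superposed_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    return kabsch_superpose(coords_a, coords_b).rmsd


def _fraction_within(a: np.ndarray, b: np.ndarray, subset: tuple[int, ...],
                     cutoff: float) -> tuple[float, tuple[int, ...]]:
    """Superpose on ``subset``, return fraction of all points within cutoff."""
    res = kabsch_superpose(a[list(subset)], b[list(subset)])
    fitted = b @ res.rotation.T + res.translation
    dist = np.linalg.norm(a - fitted, axis=1)
    within = tuple(int(i) for i in np.nonzero(dist <= cutoff)[0])
    return len(within) / len(a), within


def _gdt_seeds(k: int, exhaustive_max: int = 6) -> list[tuple[int, ...]]:
    if k <= exhaustive_max:
        seeds: list[tuple[int, ...]] = []
        for size in range(3, k + 1):
            seeds.extend(combinations(range(k), size))
        return seeds
    seeds = [tuple(range(i, i + 3)) for i in range(k - 2)]
    seeds.append(tuple(range(k)))
    return seeds


def gdt_ts(coords_a: np.ndarray, coords_b: np.ndarray,
           cutoffs: tuple[float, ...] = GDT_CUTOFFS,
           max_iter: int = 10) -> float:
    """Global distance test (total score), percent.

    For each cutoff d the best achievable fraction of point pairs within
    d A under some superposition is sought: every seed subset is superposed,
    the pairs within d are kept and re-superposed until a fixed point, and
    the best fraction seen at any stage wins. For k <= 6 points the seed set
    is every subset of size >= 3, which makes the search exhaustive; larger
    inputs use contiguous triples plus the full set.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need two equal k x 3 arrays with k >= 3")
    k = len(a)
    seeds = _gdt_seeds(k)
    percentages = []
    for cutoff in cutoffs:
        best = 0.0
        for seed in seeds:
            subset = seed
            seen: set[tuple[int, ...]] = set()
            for _ in range(max_iter):
                frac, within = _fraction_within(a, b, subset, cutoff)
                best = max(best, frac)
                if len(within) < 3 or within == subset or within in seen:
                    break
                seen.add(subset)
                subset = within
        percentages.append(100.0 * best)
    return float(np.mean(percentages))


def conservation_score(cluster, matrix: dict | None = None) -> float:
    """Sum over motif positions of the mean pairwise BLOSUM30 score.

    Positions come from the cluster's aligned group similarity; a cluster
    without aligned positions cannot be scored.
    """
    if matrix is None:
        matrix = matrices.blosum30()
    positions = getattr(cluster, "positions", None)
    if not positions:
        raise ValueError("cluster has no aligned motif positions")
    total = 0.0
    for pos in positions:
        letters = [
            cluster.chain_structures[chain].residues[idx].one_letter
            for chain, idx in sorted(pos.items())
        ]
        pair_scores = [matrices.score(matrix, x, y)
                       for x, y in combinations(letters, 2)]
        total += float(np.mean(pair_scores))
    return total


def mean_pairwise_gdt(cluster) -> float:
    """Mean GDT_TS over all chain pairs of the cluster's motif pseudo-atoms."""
    chains = sorted(cluster.chains)
    values = []
    for x, y in combinations(chains, 2):
        a = cluster.motif_pseudo_atoms(x)
        b = cluster.motif_pseudo_atoms(y)
        values.append(gdt_ts(a, b))
    return float(np.mean(values))


@dataclass
class RankedCluster:
    cluster: object
    score: int
    conservation: float
    gdt_ts: float
    rank: int = 0


def rank_clusters(clusters: list, key: str = "score") -> list[RankedCluster]:
    """Order clusters for reporting.

    Default: score (n_residues x n_chains) descending, conservation then
    mean pairwise GDT_TS as tiebreakers, cluster id last for determinism.
    ``key='conservation'`` swaps conservation ahead of the score.
    """
    entries = [
        RankedCluster(c, c.score, conservation_score(c), mean_pairwise_gdt(c))
        for c in clusters
    ]
    if key == "score":
        entries.sort(key=lambda e: (-e.score, -e.conservation, -e.gdt_ts,
                                    e.cluster.cluster_id))
    elif key == "conservation":
        entries.sort(key=lambda e: (-e.conservation, -e.score, -e.gdt_ts,
                                    e.cluster.cluster_id))
    else:
        raise ValueError(f"unknown ranking key {key!r}")
    for i, e in enumerate(entries, start=1):
        e.rank = i
    return entries
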
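"""Independent brute-force oracles used by the test suite.

These re-derive the quantities under test from their definitions with
naive exhaustive algorithms, sharing no search code with the package:
the matcher oracle enumerates every injective residue pairing, the GDT
oracle superposes every subset, and the SASA oracle is a dense
quadratic-time sphere-point count.
"""

from __future__ import annotations

import math
from itertools import combinations, permutations

import numpy as np

from mutexbind.matrices import pam250, score
from mutexbind.ranking import kabsch_superpose


def _pseudo(chain, indices):
    pts = []
    for i in indices:
        r = chain.residues[i]
        pts.append(r.ca)
        pts.append(r.sc_centroid)
    return np.asarray(pts)


def brute_force_matches(surf_a, surf_b, params):
    """Every maximal accepted correspondence, by exhaustive enumeration.

    All injective pairings of >= min_residues surface residues are
    generated; a pairing is accepted when every pair has non-negative
    PAM250, every two pairs are spatial neighbours on both chains with
    compatible internal distances, the mean PAM clears the threshold and
    the joint pseudo-atom RMSD is under the ceiling. Accepted pairings
    that are subsets of other accepted pairings are discarded.
    """
    mat = pam250()
    seq_a, seq_b = surf_a.chain.sequence, surf_b.chain.sequence
    ca_a, ca_b = surf_a.chain.ca_coords(), surf_b.chain.ca_coords()
    cen_a = np.array([r.sc_centroid for r in surf_a.chain.residues])
    cen_b = np.array([r.sc_centroid for r in surf_b.chain.residues])

    def pam(a, b):
        return score(mat, seq_a[a], seq_b[b])

    def compatible(p, q):
        (a1, b1), (a2, b2) = p, q
        if a1 == a2 or b1 == b2:
            return False
        daa = np.linalg.norm(ca_a[a1] - ca_a[a2])
        dbb = np.linalg.norm(ca_b[b1] - ca_b[b2])
        if daa > params.neighbor_cutoff or dbb > params.neighbor_cutoff:
            return False
        if abs(daa - dbb) > params.distance_tolerance:
            return False
        caa = np.linalg.norm(cen_a[a1] - cen_a[a2])
        cbb = np.linalg.norm(cen_b[b1] - cen_b[b2])
        return abs(caa - cbb) <= params.distance_tolerance

    mem_a, mem_b = list(surf_a.members), list(surf_b.members)
    accepted = []
    max_k = min(len(mem_a), len(mem_b), params.clique_cap)
    pam_floor = 2 if params.per_pair_pam else 0
    for k in range(params.min_residues, max_k + 1):
        for sub_a in combinations(mem_a, k):
            for sub_b in combinations(mem_b, k):
                for perm in permutations(sub_b):
                    pairs = tuple(zip(sub_a, perm))
                    if any(pam(a, b) < pam_floor for a, b in pairs):
                        continue
                    if not all(compatible(p, q)
                               for p, q in combinations(pairs, 2)):
                        continue
                    mean_pam = np.mean([pam(a, b) for a, b in pairs])
                    if mean_pam < params.pam_min:
                        continue
                    rmsd = kabsch_superpose(
                        _pseudo(surf_a.chain, [a for a, _ in pairs]),
                        _pseudo(surf_b.chain, [b for _, b in pairs])).rmsd
                    if rmsd < params.rmsd_max:
                        accepted.append(frozenset(tuple(sorted(pairs))))
    return {s for s in accepted
            if not any(s < t for t in accepted)}


def brute_force_gdt(coords_a, coords_b, cutoffs=(1.0, 2.0, 4.0, 8.0)):
    """GDT_TS by superposing every subset of >= 3 points."""
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    k = len(a)
    percentages = []
    for cutoff in cutoffs:
        best = 0
        for size in range(3, k + 1):
            for subset in combinations(range(k), size):
                res = kabsch_superpose(a[list(subset)], b[list(subset)])
                fitted = b @ res.rotation.T + res.translation
                within = int(np.sum(np.linalg.norm(a - fitted, axis=1) <= cutoff))
                best = max(best, within)
        percentages.append(100.0 * best / k)
    return float(np.mean(percentages))


def brute_force_sasa(coords, radii, probe=1.4, n_points=9600):
    """Per-atom ASA by a dense direct sphere-point count (no tree pruning).

    Uses its own spherical Fibonacci point set and a plain quadratic
    all-against-all occlusion test.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    golden = (1 + math.sqrt(5)) / 2
    i = np.arange(n_points)
    theta = 2 * math.pi * i / golden
    z = 1 - (2 * i + 1) / n_points
    r = np.sqrt(1 - z * z)
    unit = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    expanded = radii + probe
    out = np.zeros(len(coords))
    for idx in range(len(coords)):
        pts = coords[idx] + expanded[idx] * unit
        free = np.ones(n_points, dtype=bool)
        for jdx in range(len(coords)):
            if jdx == idx:
                continue
            free &= np.sum((pts - coords[jdx]) ** 2, axis=1) > expanded[jdx] ** 2
        out[idx] = free.mean() * 4 * math.pi * expanded[idx] ** 2
    return out


def random_rotation_rmsd(coords_a, coords_b, n_draws, seed):
    """Best RMSD over random rotations after centroid alignment."""
    rng = np.random.default_rng(seed)
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    q = rng.normal(size=(n_draws, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    rots = np.empty((n_draws, 3, 3))
    rots[:, 0, 0] = 1 - 2 * (y * y + z * z)
    rots[:, 0, 1] = 2 * (x * y - z * w)
    rots[:, 0, 2] = 2 * (x * z + y * w)
    rots[:, 1, 0] = 2 * (x * y + z * w)
    rots[:, 1, 1] = 1 - 2 * (x * x + z * z)
    rots[:, 1, 2] = 2 * (y * z - x * w)
    rots[:, 2, 0] = 2 * (x * z - y * w)
    rots[:, 2, 1] = 2 * (y * z + x * w)
    rots[:, 2, 2] = 1 - 2 * (x * x + y * y)
    fitted = np.einsum("nij,kj->nki", rots, b0)
    rmsds = np.sqrt(np.mean(np.sum((fitted - a0) ** 2, axis=2), axis=1))
    return float(rmsds.min())
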
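"""Reduced-representation chain geometry.

Toy chains used throughout the package carry a C-alpha trace plus 0-3
side-chain pseudo-atoms per residue, graded by side-chain size.  This is
deliberately minimal: the motif matcher consumes only the C-alpha position
and the side-chain geometric centroid, and the solvent-accessibility layer
only needs heavy-atom spheres.  The same builder produces the extended
Ala-X-Ala tripeptides behind the relative-accessibility reference table, so
surface definitions stay internally consistent.

Scaffold parameterisations (ideal geometry, Angstrom units):

* helix  -- 1.5 A rise and 100 degrees of twist per residue on a 2.28 A
  radius cylinder, giving the canonical 3.8 A consecutive C-alpha spacing;
* strand -- extended zigzag with 3.3 A rise per residue;
* coil   -- seeded self-avoiding random walk with fixed 3.8 A steps.
"""

from __future__ import annotations

import numpy as np

CA_CA = 3.8  # consecutive C-alpha distance, A

HELIX_RISE = 1.5
HELIX_TWIST = np.deg2rad(100.0)
# radius so that consecutive C-alpha atoms sit 3.8 A apart
HELIX_RADIUS = float(np.sqrt((CA_CA**2 - HELIX_RISE**2) / (2 * (1 - np.cos(HELIX_TWIST)))))

STRAND_RISE = 3.3
STRAND_AMP = float(np.sqrt(CA_CA**2 - STRAND_RISE**2) / 2)

# number of side-chain pseudo-atoms per residue type (CB, CG, CD along an
# outward direction); glycine has none and its centroid falls back to CA
SIDE_CHAIN_SIZE = {
    "GLY": 0,
    "ALA": 1, "SER": 1, "CYS": 1, "THR": 1, "VAL": 1, "PRO": 1,
    "ASP": 2, "ASN": 2, "LEU": 2, "ILE": 2,
    "GLU": 3, "GLN": 3, "MET": 3, "LYS": 3, "ARG": 3,
    "PHE": 3, "TYR": 3, "TRP": 3, "HIS": 3,
}

SIDE_CHAIN_NAMES = ("CB", "CG", "CD")
CB_LENGTH = 1.53
SC_STEP = 1.50

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items() if k != "MSE"}


def helix_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        HELIX_RADIUS * np.cos(i * HELIX_TWIST),
        HELIX_RADIUS * np.sin(i * HELIX_TWIST),
        HELIX_RISE * i,
    ])


def strand_trace(n: int) -> np.ndarray:
    i = np.arange(n)
    return np.column_stack([
        STRAND_RISE * i,
        np.zeros(n),
        STRAND_AMP * np.where(i % 2 == 0, 1.0, -1.0),
    ])


def coil_trace(n: int, rng: np.random.Generator, min_separation: float = 4.0,
               max_tries: int = 200) -> np.ndarray:
    """Self-avoiding random walk with fixed-length steps and gentle turns."""
    pts = [np.zeros(3), np.array([CA_CA, 0.0, 0.0])]
    while len(pts) < n:
        prev_dir = (pts[-1] - pts[-2]) / CA_CA
        for _ in range(max_tries):
            # bias towards the previous direction to avoid hairpins
            step = prev_dir + 0.8 * rng.normal(size=3)
            step *= CA_CA / np.linalg.norm(step)
            cand = pts[-1] + step
            d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
            if np.all(d >= min_separation):
                pts.append(cand)
                break
        else:
            # restart the walk from scratch rather than fail
            pts = [np.zeros(3), np.array([CA_CA, 0.0, 0.0])]
    return np.asarray(pts[:n])


def outward_directions(trace: np.ndarray, scaffold: str) -> np.ndarray:
    """Unit vectors pointing away from the chain body, one per residue.

    Side-chain pseudo-atoms are stacked along these so they end up solvent
    facing, mirroring real secondary structure.
    """
    n = len(trace)
    if scaffold == "helix":
        radial = trace.copy()
        radial[:, 2] = 0.0
        norms = np.linalg.norm(radial, axis=1, keepdims=True)
        return radial / np.where(norms == 0, 1.0, norms)
    if scaffold == "strand":
        signs = np.where(np.arange(n) % 2 == 0, 1.0, -1.0)
        out = np.zeros((n, 3))
        out[:, 2] = signs
        return out
    # coil: away from the chain centroid, orthogonalised against the tangent
    centroid = trace.mean(axis=0)
    out = np.zeros((n, 3))
    for i in range(n):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        tangent = trace[hi] - trace[lo]
        tangent /= np.linalg.norm(tangent)
        v = trace[i] - centroid
        v = v - np.dot(v, tangent) * tangent
        nv = np.linalg.norm(v)
        if nv < 1e-6:
            v = np.cross(tangent, [0.0, 0.0, 1.0])
            nv = np.linalg.norm(v)
        out[i] = v / nv
    return out


def side_chain_atoms(resname: str, ca: np.ndarray, outward: np.ndarray,
                     tangent: np.ndarray) -> list[tuple[str, np.ndarray]]:
    """Pseudo side chain: CB at 1.53 A, further atoms zigzag outward."""
    size = SIDE_CHAIN_SIZE[resname]
    atoms: list[tuple[str, np.ndarray]] = []
    pos = np.asarray(ca, dtype=float)
    for k in range(size):
        step = CB_LENGTH if k == 0 else SC_STEP
        # alternate a slight tangent tilt so chains are not collinear
        direction = outward + (0.35 if k % 2 else -0.35) * tangent
        direction = direction / np.linalg.norm(direction)
        pos = pos + step * direction
        atoms.append((SIDE_CHAIN_NAMES[k], pos.copy()))
    return atoms


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via quaternion sampling."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])
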
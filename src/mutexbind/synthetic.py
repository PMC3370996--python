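"""Deterministic synthetic fixtures.

Everything the pipeline consumes can be generated here without any
download: toy chains on ideal scaffolds, chains with a common surface
motif planted at controlled noise (the matcher's ground truth), toy
hub-node complexes with a known contact patch (the interface ground
truth), and the seven-node labelled scenario used to exercise the
confusion-count scheme.

All generators are pure functions of their seed; the same seed gives
byte-identical PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import geometry
from .geometry import ONE_TO_THREE
from .structures import (
    Atom,
    ChainStructure,
    ComplexStructure,
    Residue,
    surface_residues,
)

SCAFFOLDS = ("helix", "strand", "coil")


@dataclass
class MotifSpec:
    """A local motif: residue one-letter names + C-alpha coordinates."""

    names: str
    ca_coords: np.ndarray  # k x 3, local frame

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.names) != len(self.ca_coords):
            raise ValueError("motif names and coordinates disagree in length")
        if len(self.names) < 3:
            raise ValueError("motif needs at least 3 residues")


@dataclass
class FixtureSpec:
    """Recipe for one toy chain; the seed fully determines the output."""

    seed: int
    n_residues: int
    scaffold: str = "helix"
    sequence: str | None = None
    motif: MotifSpec | None = None

    def __post_init__(self):
        if self.scaffold not in SCAFFOLDS:
            raise ValueError(f"unknown scaffold {self.scaffold!r}; "
                             f"choose from {SCAFFOLDS}")
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")


def _build_residues(names3: list[str], trace: np.ndarray,
                    scaffold: str) -> list[Residue]:
    outward = geometry.outward_directions(trace, scaffold)
    residues = []
    n = len(trace)
    for i, name in enumerate(names3):
        lo, hi = max(0, i - 1), min(n - 1, i + 1)
        tangent = trace[hi] - trace[lo]
        tangent = tangent / np.linalg.norm(tangent)
        atoms = [Atom("CA", "C", tuple(np.round(trace[i], 3)))]
        for atom_name, pos in geometry.side_chain_atoms(name, trace[i],
                                                        outward[i], tangent):
            atoms.append(Atom(atom_name, "C", tuple(np.round(pos, 3))))
        residues.append(Residue(name, str(i + 1), atoms))
    return residues


def make_toy_chain(spec: FixtureSpec, chain_id: str = "A") -> ChainStructure:
    """Build a reduced-representation chain on an ideal scaffold."""
    rng = np.random.default_rng(spec.seed)
    if spec.scaffold == "helix":
        trace = geometry.helix_trace(spec.n_residues)
    elif spec.scaffold == "strand":
        trace = geometry.strand_trace(spec.n_residues)
    else:
        trace = geometry.coil_trace(spec.n_residues, rng)
    if spec.sequence is not None:
        if len(spec.sequence) != spec.n_residues:
            raise ValueError("sequence length disagrees with n_residues")
        seq = spec.sequence
    else:
        seq = "".join(rng.choice(list(geometry.ONE_TO_THREE)) for _ in range(spec.n_residues))
    names3 = [ONE_TO_THREE[c] for c in seq]
    return ChainStructure(chain_id, _build_residues(names3, trace, spec.scaffold))


def default_motif(k: int = 4, names: str | None = None,
                  radius: float = 3.5) -> MotifSpec:
    """A compact local motif: k residues on a ring with small z jitter.

    ``radius`` controls all internal distances, so two motifs built with
    clearly different radii are geometrically distinct -- pairwise C-alpha
    distances stay within 2*radius, which must remain inside the matcher's
    spatial-neighbourhood cutoff.
    """
    if names is None:
        names = "HDSWRKFY"[:k]
    angles = 2 * np.pi * np.arange(k) / k
    # rising z breaks the ring's rotational symmetry so the self-match is
    # unique and cross-pair correspondences cannot flip between chains
    coords = np.column_stack([
        radius * np.cos(angles),
        radius * np.sin(angles),
        0.6 * np.arange(k),
    ])
    return MotifSpec(names[:k], coords)


def _motif_atoms(motif: MotifSpec) -> list[list[tuple[str, np.ndarray]]]:
    """Full reduced-atom build of the motif in its local frame."""
    k = len(motif.names)
    ca = motif.ca_coords
    centroid = ca.mean(axis=0)
    per_residue = []
    for i in range(k):
        outward = ca[i] - centroid
        norm = np.linalg.norm(outward)
        outward = outward / norm if norm > 1e-9 else np.array([0.0, 0.0, 1.0])
        tangent = ca[min(i + 1, k - 1)] - ca[max(i - 1, 0)]
        tangent = tangent / np.linalg.norm(tangent)
        name3 = ONE_TO_THREE[motif.names[i]]
        atoms = [("CA", ca[i].copy())]
        atoms += geometry.side_chain_atoms(name3, ca[i], outward, tangent)
        per_residue.append(atoms)
    return per_residue


@dataclass
class PlantedMotif:
    """Chains carrying one common motif plus the planted correspondence."""

    chains: list[ChainStructure]
    positions: list[tuple[int, ...]]  # per chain, residue indices of the motif

    def correspondence(self, i: int, j: int) -> list[tuple[int, int]]:
        """The true residue pairing between chains i and j."""
        return list(zip(self.positions[i], self.positions[j]))


def plant_motif(chains: list[ChainStructure], motif: MotifSpec,
                noise_sigma: float = 0.0, seed: int = 0,
                clearance: float = 2.5,
                avoid: dict[str, set[int]] | None = None) -> PlantedMotif:
    """Graft one motif onto a surface site of every chain.

    The motif is rigidly rotated per chain (seeded), centred over a window
    of surface residues and pushed outward until it clears the scaffold,
    then iid Gaussian noise of ``noise_sigma`` A is added to every atom.
    The returned positions are the oracle answer for the matcher.
    ``avoid`` lists residue indices per chain id that must not be
    overwritten (e.g. a previously planted motif).
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    k = len(motif.names)
    rng = np.random.default_rng(seed)
    motif_atoms = _motif_atoms(motif)  # local frame, rigid unit
    local_centroid = motif.ca_coords.mean(axis=0)
    names3 = [ONE_TO_THREE[c] for c in motif.names]
    out_chains: list[ChainStructure] = []
    positions: list[tuple[int, ...]] = []
    for chain in chains:
        surf = surface_residues(chain)
        blocked = (avoid or {}).get(chain.chain_id, set())
        window = _surface_window(surf.members, k, len(chain), blocked)
        if window is None:
            raise ValueError(
                f"chain {chain.chain_id}: no surface window of {k} residues")
        rot = geometry.random_rotation(rng)
        target = np.mean([chain.residues[i].ca for i in window], axis=0)
        other_atoms = np.array([
            a.coord for idx, r in enumerate(chain.residues) for a in r.atoms
            if idx not in window
        ])
        # push perpendicular to the chain's long axis so the motif leaves
        # the chain body even when the window sits at the chain's centroid
        all_coords = chain.atom_coords()
        centered = all_coords - all_coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        axis = vt[0]
        direction = target - all_coords.mean(axis=0)
        direction = direction - np.dot(direction, axis) * axis
        norm = np.linalg.norm(direction)
        direction = direction / norm if norm > 1e-6 else vt[-1]

        def place(offset: float) -> list[list[np.ndarray]]:
            shift = target + offset * direction
            return [[rot @ (pos - local_centroid) + shift for _, pos in res]
                    for res in motif_atoms]

        def build(placed) -> ChainStructure:
            # noise-free build used only for the exposure check
            new_residues = list(chain.residues)
            for slot, res_idx in enumerate(window):
                atoms = [Atom(atom_name, "C", tuple(pos))
                         for (atom_name, _), pos in zip(motif_atoms[slot],
                                                        placed[slot])]
                old = new_residues[res_idx]
                new_residues[res_idx] = Residue(names3[slot], old.seq_id, atoms)
            return ChainStructure(chain.chain_id, new_residues,
                                  chain.resolution, chain.coverage)

        # push the rigid motif outward until it clears the scaffold AND
        # every planted residue is solvent-exposed (the planting contract)
        offset = 2.0
        chosen = None
        for _ in range(24):
            placed = place(offset)
            flat = np.array([p for res in placed for p in res])
            dmin = np.min(np.linalg.norm(
                other_atoms[:, None, :] - flat[None, :, :], axis=2))
            if dmin >= clearance:
                candidate = build(placed)
                exposed = set(surface_residues(candidate).members)
                if set(window) <= exposed:
                    chosen = placed
                    break
            offset += 1.0
        if chosen is None:
            raise ValueError("could not place motif without clashes")
        new_residues = list(chain.residues)
        for slot, res_idx in enumerate(window):
            atoms = []
            for (atom_name, _), pos in zip(motif_atoms[slot], chosen[slot]):
                noisy = pos + rng.normal(scale=noise_sigma, size=3)
                atoms.append(Atom(atom_name, "C", tuple(noisy)))
            old = new_residues[res_idx]
            new_residues[res_idx] = Residue(names3[slot], old.seq_id, atoms)
        out_chains.append(ChainStructure(chain.chain_id, new_residues,
                                         chain.resolution, chain.coverage))
        positions.append(tuple(window))
    return PlantedMotif(out_chains, positions)


def _surface_window(members: tuple[int, ...], k: int, n: int,
                    blocked: set[int] = frozenset()) -> tuple[int, ...] | None:
    """First run of k consecutive surface residues outside ``blocked``."""
    members_set = set(members) - set(blocked)
    start0 = max(0, (n - k) // 2)
    for start in list(range(start0, n - k + 1)) + list(range(0, start0)):
        window = tuple(range(start, start + k))
        if all(i in members_set for i in window):
            return window
    return None


@dataclass
class ToyComplex:
    """A hub-node complex plus the intended contact patch (oracle)."""

    complex: ComplexStructure
    hub_patch: tuple[int, ...]  # hub residue indices near the node


def make_toy_complex(hub: ChainStructure, node: ChainStructure,
                     patch_center: int, seed: int = 0,
                     contact_min: float = 3.5, contact_max: float = 4.5,
                     max_tries: int = 24) -> ToyComplex:
    """Dock a node chain rigidly against a hub surface patch.

    The node is rotated (seeded) and slid along the outward normal through
    ``patch_center`` until the minimum interatomic distance falls in the
    contact window [contact_min, contact_max] -- touching but not clashing.
    """
    surf = surface_residues(hub)
    if patch_center not in surf.members:
        raise ValueError(f"patch_center {patch_center} is not a surface residue")
    rng = np.random.default_rng(seed)
    hub_atoms = hub.atom_coords()
    anchor = hub.residues[patch_center].ca
    direction = anchor - hub_atoms.mean(axis=0)
    direction = direction / np.linalg.norm(direction)
    node_first_ca = node.residues[0].ca
    for _ in range(max_tries):
        rot = geometry.random_rotation(rng)
        node_r = node.transformed(rot, -rot @ node_first_ca)  # first CA at origin
        node_atoms0 = node_r.atom_coords()
        placed = None
        for d in np.arange(2.0, 20.0, 0.1):
            shift = anchor + d * direction
            dmin = _min_dist(hub_atoms, node_atoms0 + shift)
            if contact_min <= dmin <= contact_max:
                placed = node_r.transformed(np.eye(3), shift)
                break
            if dmin > contact_max:
                break
        if placed is not None:
            cplx = ComplexStructure({hub.chain_id: hub, placed.chain_id: placed})
            placed_atoms = placed.atom_coords()
            patch = tuple(
                i for i in range(len(hub))
                if _min_dist(np.array([a.coord for a in hub.residues[i].atoms]),
                             placed_atoms) < 8.0
            )
            return ToyComplex(cplx, patch)
    raise RuntimeError("could not place node against hub without clashes")


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    return float(cKDTree(a).query(b)[0].min())


@dataclass
class TwoGroupSubNetwork:
    """Six interactors with two planted exclusivity groups (ground truth)."""

    chains: list[ChainStructure]
    groups: list[frozenset[str]]
    positions: dict[str, tuple[int, ...]]  # planted motif site per chain


def make_two_group_subnetwork(seed: int = 0, n_residues: int = 14
                              ) -> TwoGroupSubNetwork:
    """Two groups of three chains, each sharing its own surface motif.

    Designed so the only inter-chain similarities are the planted motifs:
    scaffold compositions rotate through {Trp, Cys, Pro} (mutually negative
    PAM250 scores) and the two motif alphabets (hydrophobic ILVM vs polar
    DEQND) score negatively against each other and against every scaffold,
    so no residue pair outside a shared motif can seed a match. A perfect
    detector therefore reports exactly the two planted groups.
    """
    comps = "WCP"
    scaffolds = ("helix", "strand", "coil")
    chains = []
    for g, (prefix, offset) in enumerate((("A", 0), ("B", 3))):
        for i in range(3):
            comp = comps[i]
            chains.append(make_toy_chain(
                FixtureSpec(seed=seed * 100 + offset + i,
                            n_residues=n_residues,
                            scaffold=scaffolds[(i + g) % 3],
                            sequence=comp * n_residues),
                chain_id=f"{prefix}{i + 1}"))
    motif_a = default_motif(4, names="ILVM", radius=2.5)
    motif_b = default_motif(5, names="DEQND", radius=4.5)
    pl_a = plant_motif(chains[:3], motif_a, noise_sigma=0.0, seed=seed * 2 + 1)
    pl_b = plant_motif(chains[3:], motif_b, noise_sigma=0.0, seed=seed * 2 + 2)
    positions = {}
    for pl in (pl_a, pl_b):
        for ch, pos in zip(pl.chains, pl.positions):
            positions[ch.chain_id] = pos
    return TwoGroupSubNetwork(
        pl_a.chains + pl_b.chains,
        [frozenset({"A1", "A2", "A3"}), frozenset({"B1", "B2", "B3"})],
        positions)


@dataclass
class WorkedExample:
    """Seven-node labelled scenario for the confusion-count scheme.

    Three interactors (A1-A3) bind one hub patch, three (B1-B3) a second
    patch, and C1 a third; the three predicted clusters deliberately mix
    them so every confusion outcome occurs.
    """

    hub: str
    nodes: tuple[str, ...]
    groups: list[frozenset[str]]
    clusters: list[frozenset[str]]


def make_worked_example() -> WorkedExample:
    return WorkedExample(
        hub="HUB",
        nodes=("A1", "A2", "A3", "B1", "B2", "B3", "C1"),
        groups=[
            frozenset({"A1", "A2", "A3"}),
            frozenset({"B1", "B2", "B3"}),
            frozenset({"C1"}),
        ],
        clusters=[
            frozenset({"A1", "A2", "A3", "B1", "C1"}),
            frozenset({"A1", "B2", "B3"}),
            frozenset({"A1", "A3", "C1"}),
        ],
    )
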
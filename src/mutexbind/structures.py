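"""Chain coordinates, solvent accessibility, and surface residues.

A residue's exposure is judged on the isolated chain: its total accessible
surface area (Shrake-Rupley, deterministic golden-spiral point lattice) is
divided by the accessibility of the same residue type in an extended
Ala-X-Ala tripeptide, and residues above a 50% relative-accessibility
cutoff form the surface set handed to the motif matcher.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .geometry import THREE_TO_ONE

logger = logging.getLogger(__name__)

DEFAULT_PROBE = 1.4  # water probe radius, A
DEFAULT_N_POINTS = 960
DEFAULT_EXPOSURE_CUTOFF = 0.5

# van der Waals radii by element, A (standard protein values; unknown -> 1.70)
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "SE": 1.90, "P": 1.80, "H": 1.20, "F": 1.47,
    "CL": 1.75, "BR": 1.85, "I": 1.98,
}
DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    xyz: tuple[float, float, float]

    @property
    def coord(self) -> np.ndarray:
        return np.asarray(self.xyz, dtype=float)

    @property
    def radius(self) -> float:
        return VDW_RADII.get(self.element.upper(), DEFAULT_RADIUS)


@dataclass
class Residue:
    """One residue: 3-letter name, author seq id, and heavy atoms.

    ``ca`` and ``sc_centroid`` are the two pseudo-atoms the matcher uses;
    the centroid is the unweighted mean of side-chain heavy atoms, falling
    back to CA for glycine or when no side-chain atoms are present.
    """

    name: str
    seq_id: str
    atoms: list[Atom]

    @property
    def ca(self) -> np.ndarray:
        for a in self.atoms:
            if a.name == "CA":
                return a.coord
        raise ValueError(f"residue {self.name} {self.seq_id} has no CA atom")

    @property
    def sc_centroid(self) -> np.ndarray:
        side = [a.coord for a in self.atoms
                if a.name not in ("N", "CA", "C", "O", "OXT")]
        if not side:
            return self.ca
        return np.mean(side, axis=0)

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")


@dataclass
class ChainStructure:
    """An ordered protein chain with optional selection metadata."""

    chain_id: str
    residues: list[Residue]
    resolution: float | None = None
    coverage: float | None = None

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def atom_coords(self) -> np.ndarray:
        return np.array([a.coord for r in self.residues for a in r.atoms])

    def atom_radii(self) -> np.ndarray:
        return np.array([a.radius for r in self.residues for a in r.atoms])

    def atom_residue_index(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.residues) for _ in r.atoms])

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ChainStructure":
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new_res = []
        for r in self.residues:
            atoms = [Atom(a.name, a.element, tuple(rot @ a.coord + t)) for a in r.atoms]
            new_res.append(Residue(r.name, r.seq_id, atoms))
        return ChainStructure(self.chain_id, new_res, self.resolution, self.coverage)


@dataclass
class ComplexStructure:
    """Two or more chains in a common frame (for interface analysis)."""

    chains: dict[str, ChainStructure]

    def __getitem__(self, chain_id: str) -> ChainStructure:
        return self.chains[chain_id]

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains


@dataclass
class SurfaceResidueSet:
    """Surface residues of one chain with their relative accessibilities."""

    chain: ChainStructure
    members: tuple[int, ...]
    rel_acc: dict[int, float]


class MissingChainError(KeyError):
    pass


def read_structure(path: str | Path, chain: str, model: int = 1) -> ChainStructure:
    """Read one chain from a PDB file into a ChainStructure.

    Heavy atoms only; the highest-occupancy altloc is kept (ties resolved
    'A' before blank before the rest); HETATM residues are dropped except
    selenomethionine, which maps to Met; waters are removed; residues
    without a CA atom are skipped with a warning.
    """
    import gemmi

    st = gemmi.read_structure(str(path))
    st.remove_hydrogens()
    st.remove_waters()
    models = {m.num: m for m in st}
    if model not in models:
        model_obj = st[0]
    else:
        model_obj = models[model]
    chain_obj = None
    for ch in model_obj:
        if ch.name == chain:
            chain_obj = ch
            break
    if chain_obj is None:
        available = sorted(ch.name for ch in model_obj)
        raise MissingChainError(
            f"chain {chain!r} not in {path}; available: {available}")

    residues: list[Residue] = []
    for res in chain_obj:
        het = res.het_flag == "H"
        if het and res.name != "MSE":
            continue
        name = "MET" if res.name == "MSE" else res.name
        # altloc resolution: per atom name keep max occupancy, tie 'A' < '' < rest
        by_name: dict[str, list] = {}
        for atom in res:
            if atom.element.name.upper() == "H":
                continue
            by_name.setdefault(atom.name, []).append(atom)
        atoms: list[Atom] = []
        for atom_name, group in by_name.items():
            def altloc_rank(a):
                if a.altloc == "A":
                    return 0
                if a.altloc in ("", "\x00"):
                    return 1
                return 2 + ord(a.altloc)
            best = min(group, key=lambda a: (-a.occ, altloc_rank(a)))
            element = best.element.name
            atoms.append(Atom(atom_name, element,
                              (best.pos.x, best.pos.y, best.pos.z)))
        seq_id = f"{res.seqid.num}{res.seqid.icode}".strip()
        if not any(a.name == "CA" for a in atoms):
            warnings.warn(
                f"residue {name} {seq_id} in {path}:{chain} lacks CA; skipped")
            continue
        residues.append(Residue(name, seq_id, atoms))
    res_field = st.resolution if st.resolution and st.resolution > 0 else None
    return ChainStructure(chain, residues, resolution=res_field)


def write_pdb(chains: list[ChainStructure] | ChainStructure, path: str | Path) -> None:
    """Write chains as a minimal standard PDB file (ATOM/TER/END)."""
    if isinstance(chains, ChainStructure):
        chains = [chains]
    serial = 0
    lines = []
    for ch in chains:
        for res in ch.residues:
            for atom in res.atoms:
                serial += 1
                x, y, z = atom.xyz
                lines.append(
                    f"ATOM  {serial:5d} {atom.name:^4s}{res.name:>4s} "
                    f"{ch.chain_id:1s}{int(res.seq_id):4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {atom.element:>2s}"
                )
        lines.append(f"TER   {serial + 1:5d}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class StructureCandidate:
    """Metadata for one deposited structure of a protein."""

    identifier: str
    coverage: float
    resolution: float | None = None


def select_best_structure(candidates: list[StructureCandidate]) -> StructureCandidate:
    """Pick the candidate with best coverage, then best resolution.

    Entries without a resolution (e.g. NMR) sort as worst resolution;
    remaining ties fall back to the lexicographically smallest identifier.
    """
    if not candidates:
        raise ValueError("no structure candidates to select from")
    return min(candidates, key=lambda c: (
        -c.coverage,
        c.resolution if c.resolution is not None else math.inf,
        c.identifier,
    ))


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral lattice of n points on the unit sphere."""
    i = np.arange(n, dtype=float)
    phi = math.pi * (3.0 - math.sqrt(5.0))  # golden angle
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    theta = phi * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Deterministic molecule-fixed frame from the coordinate covariance.

    Orienting the sphere lattice in this frame makes the point sample (and
    hence the computed ASA) invariant under rigid motion of the molecule,
    up to principal-axis degeneracy. Eigenvectors are ordered by descending
    eigenvalue and sign-fixed on their largest component.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 3:
        return np.eye(3)
    cov = centered.T @ centered
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    frame = eigvec[:, order]
    for k in range(3):
        idx = int(np.argmax(np.abs(frame[:, k])))
        if frame[idx, k] < 0:
            frame[:, k] = -frame[:, k]
    if np.linalg.det(frame) < 0:
        frame[:, 2] = -frame[:, 2]
    return frame


def atom_sasa(coords: np.ndarray, radii: np.ndarray, probe: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS,
              frame_coords: np.ndarray | None = None) -> np.ndarray:
    """Shrake-Rupley accessible surface area per atom, A^2.

    Each atom is wrapped in a golden-spiral lattice on its solvent-expanded
    sphere; a point is accessible when it lies outside every other atom's
    expanded sphere. ASA = accessible fraction x 4 pi (r+probe)^2. The
    lattice is oriented in the principal-axes frame of ``frame_coords``
    (default: ``coords``) so the result does not depend on the lab frame.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n_atoms = len(coords)
    frame_src = coords if frame_coords is None else np.asarray(frame_coords, float)
    unit = _sphere_points(n_points) @ _principal_frame(frame_src).T
    expanded = radii + probe
    out = np.zeros(n_atoms)
    if n_atoms == 0:
        return out
    tree = cKDTree(coords)
    max_reach = expanded.max() * 2.0
    for i in range(n_atoms):
        pts = coords[i] + expanded[i] * unit
        neighbors = [j for j in tree.query_ball_point(coords[i], expanded[i] + max_reach)
                     if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
            if not accessible.any():
                break
        out[i] = accessible.mean() * 4.0 * math.pi * expanded[i] ** 2
    return out


def compute_sasa(chain: ChainStructure, probe: float = DEFAULT_PROBE,
                 n_points: int = DEFAULT_N_POINTS,
                 context: list[ChainStructure] | None = None) -> dict[int, float]:
    """Per-residue solvent accessible surface area of a chain, A^2.

    ``context`` chains occlude the surface without contributing area of
    their own -- used for interface detection (isolated vs in-complex ASA).
    Surface definition for motif matching always runs on the isolated chain.
    """
    if len(chain) == 0:
        raise ValueError("chain has no residues")
    own_coords = chain.atom_coords()
    coords = own_coords
    radii = chain.atom_radii()
    n_own = len(coords)
    if context:
        extra_coords = np.concatenate([c.atom_coords() for c in context])
        extra_radii = np.concatenate([c.atom_radii() for c in context])
        coords = np.concatenate([coords, extra_coords])
        radii = np.concatenate([radii, extra_radii])
    per_atom = atom_sasa(coords, radii, probe=probe, n_points=n_points,
                         frame_coords=own_coords)[:n_own]
    res_index = chain.atom_residue_index()
    out = {i: 0.0 for i in range(len(chain))}
    for asa, idx in zip(per_atom, res_index):
        out[int(idx)] += float(asa)
    return out


_REFERENCE_FILE = "axa_reference.json"


def _load_reference() -> dict[str, float]:
    text = resources.files(__package__).joinpath("data", _REFERENCE_FILE).read_text()
    return json.loads(text)


_reference_cache: dict[str, float] | None = None


def reference_asa() -> dict[str, float]:
    """Extended Ala-X-Ala accessibility of the central residue, by type."""
    global _reference_cache
    if _reference_cache is None:
        _reference_cache = _load_reference()
    return _reference_cache


def relative_accessibility(residue_asa: float, residue_name: str) -> float:
    """ASA divided by the residue type's extended-tripeptide reference."""
    ref = reference_asa()
    if residue_name not in ref:
        raise KeyError(f"no reference accessibility for residue type {residue_name!r}")
    return residue_asa / ref[residue_name]


def surface_residues(chain: ChainStructure,
                     cutoff: float = DEFAULT_EXPOSURE_CUTOFF,
                     probe: float = DEFAULT_PROBE,
                     n_points: int = DEFAULT_N_POINTS) -> SurfaceResidueSet:
    """Residues with relative accessibility strictly above ``cutoff``."""
    asa = compute_sasa(chain, probe=probe, n_points=n_points)
    rel = {i: relative_accessibility(asa[i], chain.residues[i].name)
           for i in range(len(chain))}
    members = tuple(i for i in range(len(chain)) if rel[i] > cutoff)
    if not members:
        logger.info("chain %s has no surface residues at cutoff %.2f",
                    chain.chain_id, cutoff)
    return SurfaceResidueSet(chain, members, rel)


def build_reference_table(n_points: int = 9600) -> dict[str, float]:
    """Recompute the Ala-X-Ala reference accessibilities from scratch.

    Builds an extended (strand-scaffold) Ala-X-Ala tripeptide for each
    residue type with the package's reduced side-chain representation and
    measures the central residue's ASA. Used once to freeze the packaged
    reference file, and by tests to confirm self-consistency.
    """
    from .synthetic import FixtureSpec, make_toy_chain

    table = {}
    for three, one in sorted(THREE_TO_ONE.items()):
        if three == "MSE":
            continue
        spec = FixtureSpec(seed=0, n_residues=3, scaffold="strand",
                           sequence=f"A{one}A")
        chain = make_toy_chain(spec)
        asa = compute_sasa(chain, n_points=n_points)
        table[three] = round(float(asa[1]), 4)
    return table


def accessibility_table(chain: ChainStructure,
                        cutoff: float = DEFAULT_EXPOSURE_CUTOFF) -> str:
    """Per-residue accessibility report as TSV text."""
    surf = surface_residues(chain, cutoff=cutoff)
    asa = compute_sasa(chain)
    lines = ["chain\tresnum\tresname\tasa\trel_acc\tis_surface"]
    for i, res in enumerate(chain.residues):
        lines.append("\t".join([
            chain.chain_id, res.seq_id, res.name,
            f"{asa[i]:.2f}", f"{surf.rel_acc[i]:.3f}",
            "1" if i in surf.members else "0",
        ]))
    return "\n".join(lines) + "\n"
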
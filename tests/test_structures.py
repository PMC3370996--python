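"""Structure reading, solvent accessibility, surface definition."""

import math
import warnings

import numpy as np
import pytest

from mutexbind.structures import (
    Atom,
    ChainStructure,
    MissingChainError,
    Residue,
    StructureCandidate,
    atom_sasa,
    build_reference_table,
    compute_sasa,
    read_structure,
    reference_asa,
    relative_accessibility,
    select_best_structure,
    surface_residues,
    write_pdb,
)
from mutexbind.synthetic import FixtureSpec, make_toy_chain

from oracles import brute_force_sasa


class TestReadStructure:
    def test_round_trips_synthetic_chain(self, tmp_path, helix12):
        path = tmp_path / "helix.pdb"
        write_pdb(helix12, path)
        back = read_structure(path, "A")
        assert back.sequence == helix12.sequence
        assert len(back) == 12
        np.testing.assert_allclose(back.ca_coords(), helix12.ca_coords(),
                                   atol=1e-3)

    def test_missing_chain_lists_available(self, tmp_path, helix12):
        path = tmp_path / "helix.pdb"
        write_pdb(helix12, path)
        with pytest.raises(MissingChainError, match="'A'"):
            read_structure(path, "Z")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.60  0.00           C",
            "ATOM      3  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb + "\n")
        chain = read_structure(path, "A")
        assert len(chain.residues[0].atoms) == 1
        assert chain.residues[0].ca[0] == pytest.approx(5.0)

    def test_altloc_tie_prefers_a(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  CA BALA A   1       5.000   0.000   0.000  0.50  0.00           C",
            "ATOM      2  CA AALA A   1       0.000   0.000   0.000  0.50  0.00           C",
            "END",
        ])
        path = tmp_path / "tie.pdb"
        path.write_text(pdb + "\n")
        chain = read_structure(path, "A")
        assert chain.residues[0].ca[0] == pytest.approx(0.0)

    def test_ca_less_residue_skipped_with_warning(self, tmp_path):
        lines = []
        serial = 0
        for i in range(10):
            serial += 1
            name = "CB" if i == 4 else "CA"
            lines.append(
                f"ATOM  {serial:5d}  {name:<3s} ALA A{i + 1:4d}    "
                f"{3.8 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C")
        path = tmp_path / "noca.pdb"
        path.write_text("\n".join(lines) + "\nEND\n")
        with pytest.warns(UserWarning, match="lacks CA"):
            chain = read_structure(path, "A")
        assert len(chain) == 9

    def test_selenomethionine_maps_to_met(self, tmp_path):
        pdb = "\n".join([
            "HETATM    1  CA  MSE A   1       0.000   0.000   0.000  1.00  0.00           C",
            "HETATM    2 SE   MSE A   1       1.500   0.000   0.000  1.00  0.00          SE",
            "HETATM    3  O   HOH A  90       9.000   9.000   9.000  1.00  0.00           O",
            "END",
        ])
        path = tmp_path / "mse.pdb"
        path.write_text(pdb + "\n")
        chain = read_structure(path, "A")
        assert chain.sequence == "M"


class TestSelectBestStructure:
    def test_resolution_breaks_coverage_tie(self):
        a = StructureCandidate("1abc", 0.9, 2.0)
        b = StructureCandidate("2def", 0.9, 1.5)
        assert select_best_structure([a, b]) is b

    def test_coverage_dominates_resolution(self):
        a = StructureCandidate("1abc", 0.5, 1.0)
        b = StructureCandidate("2def", 0.95, 2.8)
        assert select_best_structure([a, b]) is b

    def test_missing_resolution_is_worst(self):
        nmr = StructureCandidate("1nmr", 0.9, None)
        xray = StructureCandidate("2xry", 0.9, 3.5)
        assert select_best_structure([nmr, xray]) is xray

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_structure([])


def _bare_residue(name, atoms):
    return Residue(name, "1", [Atom(n, "C", tuple(x)) for n, x in atoms])


class TestComputeSasa:
    def test_isolated_residue_is_exposed(self):
        chain = ChainStructure("A", [
            _bare_residue("GLY", [("CA", (0.0, 0.0, 0.0))])])
        asa = compute_sasa(chain)
        bare_sphere = 4 * math.pi * (1.70 + 1.4) ** 2
        assert asa[0] == pytest.approx(bare_sphere, rel=1e-6)

    def test_enclosed_residue_is_buried(self):
        # central atom caged by a dense shell of dummy residues
        shell = []
        golden = math.pi * (3 - math.sqrt(5))
        n = 60
        for i in range(n):
            z = 1 - 2 * (i + 0.5) / n
            r = math.sqrt(1 - z * z)
            t = golden * i
            shell.append((3.0 * r * math.cos(t), 3.0 * r * math.sin(t), 3.0 * z))
        residues = [_bare_residue("GLY", [("CA", (0.0, 0.0, 0.0))])]
        residues += [_bare_residue("GLY", [("CA", p)]) for p in shell]
        asa = compute_sasa(ChainStructure("A", residues))
        assert asa[0] < 1.0

    def test_matches_dense_brute_force(self):
        # refinement oracle: independent dense quadratic implementation
        rng = np.random.default_rng(3)
        for trial in range(3):
            spec = FixtureSpec(seed=int(rng.integers(1000)), n_residues=5,
                               scaffold=("helix", "strand", "coil")[trial])
            chain = make_toy_chain(spec)
            asa = compute_sasa(chain)
            dense = brute_force_sasa(chain.atom_coords(), chain.atom_radii(),
                                     n_points=9600)
            res_idx = chain.atom_residue_index()
            for i in range(len(chain)):
                ref = float(dense[res_idx == i].sum())
                assert asa[i] == pytest.approx(ref, rel=0.02, abs=0.5)

    def test_rigid_transform_invariance(self, strand10):
        from mutexbind.geometry import random_rotation

        rng = np.random.default_rng(8)
        base = compute_sasa(strand10)
        rot = random_rotation(rng)
        moved = strand10.transformed(rot, rng.normal(scale=20, size=3))
        after = compute_sasa(moved)
        for i in base:
            assert abs(base[i] - after[i]) < 0.5

    def test_distant_atom_changes_nothing(self, strand10):
        base = compute_sasa(strand10)
        far = ChainStructure("Z", [
            _bare_residue("GLY", [("CA", (500.0, 500.0, 500.0))])])
        with_far = compute_sasa(strand10, context=[far])
        for i in base:
            assert base[i] == pytest.approx(with_far[i], abs=1e-9)


class TestRelativeAccessibility:
    def test_ratio_identity(self):
        ref = reference_asa()["ALA"]
        assert relative_accessibility(ref, "ALA") == pytest.approx(1.0)

    def test_zero_asa_is_zero(self):
        assert relative_accessibility(0.0, "TRP") == 0.0

    def test_unknown_residue_type_rejected(self):
        with pytest.raises(KeyError):
            relative_accessibility(10.0, "UNK")

    def test_reference_generator_self_consistency(self):
        # rebuilding the extended tripeptides reproduces the packaged table
        fresh = build_reference_table(n_points=960)
        packaged = reference_asa()
        for res, value in fresh.items():
            assert value / packaged[res] == pytest.approx(1.0, abs=0.02)


class TestSurfaceResidues:
    def test_extended_peptide_fully_exposed(self, strand10):
        surf = surface_residues(strand10)
        assert len(surf.members) == len(strand10)

    def test_buried_core_excluded(self):
        # a residue caged between two stacked copies of a dense shell
        golden = math.pi * (3 - math.sqrt(5))
        shell = []
        n = 80
        for i in range(n):
            z = 1 - 2 * (i + 0.5) / n
            r = math.sqrt(1 - z * z)
            t = golden * i
            shell.append((4.0 * r * math.cos(t), 4.0 * r * math.sin(t), 4.0 * z))
        residues = [_bare_residue("ALA", [("CA", (0.0, 0.0, 0.0)),
                                          ("CB", (1.5, 0.0, 0.0))])]
        residues += [_bare_residue("GLY", [("CA", p)]) for p in shell]
        surf = surface_residues(ChainStructure("A", residues))
        assert 0 not in surf.members

    def test_cutoff_is_strict(self, monkeypatch, strand10):
        surf = surface_residues(strand10)
        boundary = surf.rel_acc[3]
        at_boundary = surface_residues(strand10, cutoff=boundary)
        assert 3 not in at_boundary.members

    def test_monotone_in_cutoff(self, strand10):
        loose = surface_residues(strand10, cutoff=0.2)
        tight = surface_residues(strand10, cutoff=0.7)
        assert set(tight.members) <= set(loose.members)


def test_atom_sasa_two_disjoint_atoms_are_bare_spheres():
    coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
    radii = np.array([1.7, 1.52])
    asa = atom_sasa(coords, radii)
    for r, a in zip(radii, asa):
        assert a == pytest.approx(4 * math.pi * (r + 1.4) ** 2, rel=1e-6)
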
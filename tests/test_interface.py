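"""Interface extraction, solvent exposure, point reduction, pharmacophore typing."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from ifacesearch.errors import NoInterfaceError
from ifacesearch.interface import (
    classify_atom,
    compute_solvent_exposure,
    extract_interface,
    model_interface,
    one_sided_interface,
    reduce_points,
)
from ifacesearch.structures import AtomRecord, Structure, transform_structure
from ifacesearch.synthetic import random_rigid_transform


def _atom(name, resname, chain, resseq, xyz, element=None):
    return AtomRecord(
        serial=0,
        atom_name=name,
        element=element or name[0],
        residue_name=resname,
        residue_seq=resseq,
        icode="",
        chain_id=chain,
        coords=np.asarray(xyz, dtype=float),
        is_backbone=name in ("N", "CA", "C", "O", "OXT"),
    )


def _two_atom_structure(gap: float) -> Structure:
    return Structure(
        "pair",
        {
            "A": [_atom("CA", "GLY", "A", 1, (0, 0, 0))],
            "B": [_atom("CA", "GLY", "B", 1, (gap, 0, 0))],
        },
    )


class TestExtractInterface:
    def test_cutoff_boundary(self):
        pair = extract_interface(_two_atom_structure(4.4), "A", "B")
        assert len(pair.side_a.points) == 1 and len(pair.side_b.points) == 1
        with pytest.raises(NoInterfaceError):
            extract_interface(_two_atom_structure(4.6), "A", "B")

    def test_far_apart_chains_raise(self):
        with pytest.raises(NoInterfaceError):
            extract_interface(_two_atom_structure(50.0), "A", "B")

    def test_missing_chain_raises_key_error(self, toy_structure):
        with pytest.raises(KeyError):
            extract_interface(toy_structure, "A", "Z")

    def test_membership_matches_brute_force_all_pairs_oracle(self, toy_structure):
        """Atom-level membership equals an O(n*m) double loop over heavy atoms."""
        pair = extract_interface(toy_structure, "A", "B", cutoff=4.5)
        xa = toy_structure.chain_coords("A")
        xb = toy_structure.chain_coords("B")
        d = cdist(xa, xb)
        expect_a = {i for i in range(len(xa)) if d[i].min() <= 4.5}
        expect_b = {j for j in range(len(xb)) if d[:, j].min() <= 4.5}
        atoms_a = toy_structure.chains["A"]
        got_a = {
            i
            for i, a in enumerate(atoms_a)
            if any(
                p.residue_seq == a.residue_seq and p.atom_name == a.atom_name
                for p in pair.side_a.points
            )
        }
        assert got_a == expect_a
        assert len(pair.side_b.points) == len(expect_b)

    def test_swapping_chain_arguments_swaps_sides(self, toy_structure):
        ab = extract_interface(toy_structure, "A", "B")
        ba = extract_interface(toy_structure, "B", "A")
        assert [p.residue_seq for p in ab.side_a.points] == [
            p.residue_seq for p in ba.side_b.points
        ]
        assert [p.residue_seq for p in ab.side_b.points] == [
            p.residue_seq for p in ba.side_a.points
        ]

    def test_membership_invariant_under_rigid_motion(self, toy_structure, rng):
        moved = transform_structure(toy_structure, random_rigid_transform(rng))
        base = extract_interface(toy_structure, "A", "B")
        after = extract_interface(moved, "A", "B")
        for side in ("side_a", "side_b"):
            assert [
                (p.residue_seq, p.atom_name) for p in getattr(base, side).points
            ] == [(p.residue_seq, p.atom_name) for p in getattr(after, side).points]


class TestOneSided:
    def test_direct_selection(self, toy_structure):
        pair = one_sided_interface(toy_structure, "A", [(1, ""), (2, "")])
        assert pair.side_b is None
        got = {p.residue_seq for p in pair.side_a.points}
        assert got == {1, 2}
        n_atoms = sum(
            1 for a in toy_structure.chains["A"] if a.residue_seq in (1, 2)
        )
        assert len(pair.side_a.points) == n_atoms

    def test_empty_residue_list_raises(self, toy_structure):
        with pytest.raises(NoInterfaceError):
            one_sided_interface(toy_structure, "A", [])

    def test_unknown_residue_raises_key_error_listing_offenders(self, toy_structure):
        with pytest.raises(KeyError, match="999"):
            one_sided_interface(toy_structure, "A", [(1, ""), (999, "")])

    def test_reproduces_extract_interface_residue_set(self, toy_structure):
        two_sided = extract_interface(toy_structure, "A", "B")
        residues = two_sided.side_a.residue_ids()
        one = one_sided_interface(toy_structure, "A", residues)
        assert set(one.side_a.residue_ids()) == set(residues)


class TestSolventExposure:
    def test_single_residue_fully_exposed(self):
        st = Structure(
            "one",
            {
                "A": [
                    _atom("N", "ALA", "A", 1, (0, 0, 0)),
                    _atom("CA", "ALA", "A", 1, (1.46, 0, 0)),
                    _atom("C", "ALA", "A", 1, (2.0, 1.4, 0)),
                    _atom("O", "ALA", "A", 1, (3.2, 1.5, 0)),
                    _atom("CB", "ALA", "A", 1, (1.9, -0.8, 1.2)),
                ]
            },
        )
        table = compute_solvent_exposure(st, "A")
        assert all(table.values())

    def test_enclosed_atom_is_buried(self):
        """An atom caged by 26 neighbours at 3 A has zero accessible surface."""
        atoms = [_atom("CA", "UNK", "A", 1, (0, 0, 0))]
        k = 2
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    if dx == dy == dz == 0:
                        continue
                    v = np.array([dx, dy, dz], dtype=float)
                    v = 3.0 * v / np.linalg.norm(v)
                    atoms.append(_atom("CA", "UNK", "A", k, v))
                    k += 1
        st = Structure("cage", {"A": atoms})
        table = compute_solvent_exposure(st, "A")
        assert table[("A", 1, "", "CA")] is False

    def test_agrees_with_independent_shrake_rupley(self, toy_structure):
        """Exposure flags match Biopython's Shrake-Rupley on the same chain."""
        from Bio.PDB.SASA import ShrakeRupley
        from Bio.PDB.StructureBuilder import StructureBuilder

        chain_id = "A"
        atoms = toy_structure.chains[chain_id]
        builder = StructureBuilder()
        builder.init_structure("x")
        builder.init_model(0)
        builder.init_chain(chain_id)
        builder.init_seg(" ")
        current = None
        for a in atoms:
            if a.residue_seq != current:
                builder.init_residue(a.residue_name, " ", a.residue_seq, " ")
                current = a.residue_seq
            builder.init_atom(a.atom_name, a.coords, 0.0, 1.0, " ", a.atom_name, element=a.element)
        model = builder.get_structure()[0]
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(model, level="A")
        ref = {}
        for res in model[chain_id]:
            for at in res:
                ref[(chain_id, res.id[1], "", at.get_name())] = at.sasa

        from ifacesearch.sasa import shrake_rupley_sasa

        areas = shrake_rupley_sasa(
            np.array([a.coords for a in atoms]), [a.element for a in atoms]
        )
        diffs = [
            abs(area - ref[(chain_id, a.residue_seq, "", a.atom_name)])
            for a, area in zip(atoms, areas)
        ]
        # same radii and probe; the two implementations use different
        # 960-point sphere sets, each test point worth ~0.11 A^2, so
        # boundary atoms may disagree by a handful of points
        assert max(diffs) < 2.0
        # burial verdicts agree wherever the oracle is clearly off-threshold
        ours = compute_solvent_exposure(toy_structure, chain_id)
        for a in atoms:
            key = (chain_id, a.residue_seq, "", a.atom_name)
            if ref[key] > 2.0:
                assert ours[key] is True

    def test_unbound_differs_from_bound_for_buried_interface_atoms(self, toy_structure):
        """Isolated-chain SASA exposes atoms the partner chain would bury."""
        from ifacesearch.sasa import shrake_rupley_sasa

        unbound = compute_solvent_exposure(toy_structure, "A")
        atoms_a = toy_structure.chains["A"]
        all_atoms = atoms_a + toy_structure.chains["B"]
        areas = shrake_rupley_sasa(
            np.array([a.coords for a in all_atoms]), [a.element for a in all_atoms]
        )
        bound_area = {
            ("A", a.residue_seq, a.icode, a.atom_name): ar
            for a, ar in zip(atoms_a, areas[: len(atoms_a)])
        }
        unbound_area = {
            k: ar
            for k, ar in zip(
                bound_area,
                shrake_rupley_sasa(
                    np.array([a.coords for a in atoms_a]), [a.element for a in atoms_a]
                ),
            )
        }
        shrunk = [
            k
            for k in bound_area
            if unbound[k] and bound_area[k] < 0.5 * unbound_area[k] - 1e-9
        ]
        assert shrunk, "complex formation must bury surface area of interface atoms"


class TestReducePoints:
    def test_calpha_mode_one_point_per_residue(self, toy_structure):
        pair = extract_interface(toy_structure, "A", "B")
        reduced = reduce_points(pair, "calpha")
        assert len(reduced.side_a.points) == len(pair.side_a.residue_ids())
        assert all(p.ptype == "Ca" and p.is_calpha for p in reduced.side_a.points)

    def test_phe_contributes_ring_center_not_ring_carbons(self):
        ring = {
            "CG": (0.0, 1.39, 0),
            "CD1": (1.2, 0.7, 0),
            "CD2": (-1.2, 0.7, 0),
            "CE1": (1.2, -0.7, 0),
            "CE2": (-1.2, -0.7, 0),
            "CZ": (0.0, -1.39, 0),
        }
        atoms_a = [
            _atom("CA", "PHE", "A", 1, (0, 3.5, 0)),
            _atom("CB", "PHE", "A", 1, (0, 2.6, 0)),
        ] + [_atom(n, "PHE", "A", 1, xyz) for n, xyz in ring.items()]
        atoms_b = [
            _atom("CA", "SER", "B", 1, (0, 0, 4.0)),
            _atom("CB", "SER", "B", 1, (0, 1.0, 3.6)),
            _atom("OG", "SER", "B", 1, (0, 2.0, 3.2)),
        ]
        st = Structure("phe", {"A": atoms_a, "B": atoms_b})
        pair = extract_interface(st, "A", "B")
        reduced = reduce_points(pair, "restricted")
        names = [p.atom_name for p in reduced.side_a.points]
        assert "RING" in names
        assert not any(n in ring for n in names)
        center = next(p for p in reduced.side_a.points if p.is_ring_center)
        np.testing.assert_allclose(center.coords, np.mean(list(ring.values()), axis=0), atol=1e-12)
        assert center.ptype == "Aro" and center.solvent_exposed

    def test_restricted_mode_equals_rule_table_oracle(self, toy_structure):
        """Independent per-atom rule evaluation reproduces the restricted set."""
        hydrophobic = {
            "ALA": {"CB"},
            "ILE": {"CB", "CG1", "CG2", "CD1"},
            "LEU": {"CB", "CG", "CD1", "CD2"},
            "LYS": {"CB", "CG", "CD"},
            "MET": {"CB", "CG", "CE"},
            "PRO": {"CB", "CG", "CD"},
            "VAL": {"CB", "CG1", "CG2"},
        }
        pair = extract_interface(toy_structure, "A", "B")
        exposure = compute_solvent_exposure(toy_structure, "A")
        exposure.update(compute_solvent_exposure(toy_structure, "B"))
        reduced = reduce_points(pair, "restricted", exposure)
        got = {
            (p.residue_seq, p.atom_name)
            for p in reduced.side_a.points
            if not p.is_ring_center
        }
        expect = set()
        for p in pair.side_a.points:
            rule_ok = p.element in ("O", "N", "S") or (
                p.residue_name in hydrophobic and p.atom_name in hydrophobic[p.residue_name]
            )
            if rule_ok and exposure[("A", p.residue_seq, p.icode, p.atom_name)]:
                expect.add((p.residue_seq, p.atom_name))
        assert got == expect

    def test_all_mode_filters_to_exposed_and_adds_ring_centers(self, toy_structure):
        pair = extract_interface(toy_structure, "A", "B")
        exposure = compute_solvent_exposure(toy_structure, "A")
        exposure.update(compute_solvent_exposure(toy_structure, "B"))
        reduced = reduce_points(pair, "all", exposure)
        for p in reduced.side_a.points:
            assert p.solvent_exposed
        n_buried = sum(
            1
            for p in pair.side_a.points
            if not exposure[("A", p.residue_seq, p.icode, p.atom_name)]
        )
        n_rings = sum(1 for p in reduced.side_a.points if p.is_ring_center)
        assert len(reduced.side_a.points) == len(pair.side_a.points) - n_buried + n_rings

    def test_empty_reduction_raises(self):
        st = _two_atom_structure(4.0)  # lone Gly CA atoms, no side chains
        pair = extract_interface(st, "A", "B")
        with pytest.raises(NoInterfaceError):
            reduce_points(pair, "restricted")


@pytest.mark.parametrize(
    ("resname", "atom", "element", "backbone", "expected"),
    [
        ("LYS", "NZ", "N", False, "Pos/Don"),
        ("ASP", "OD1", "O", False, "Neg/Acc"),
        ("SER", "OG", "O", False, "Acc/Don"),
        ("GLY", "O", "O", True, "Acc"),
        ("GLY", "N", "N", True, "Don"),
        ("LEU", "CD1", "C", False, "HyPhob"),
        ("LEU", "CA", "C", True, "Ca"),
        ("ALA", "C", "C", True, "Other"),
        ("GLU", "OXT", "O", True, "Neg/Acc"),
        ("ARG", "NH1", "N", False, "Pos/Don"),
        ("HIS", "ND1", "N", False, "Acc/Don"),
        ("MET", "SD", "S", False, "Acc"),
        ("TRP", "NE1", "N", False, "Don"),
        ("CYS", "SG", "S", False, "Acc/Don"),
        ("PHE", "CD1", "C", False, "Aro"),
        ("UNK", "XO1", "O", False, "Acc"),
        ("UNK", "XN1", "N", False, "Don"),
    ],
)
def test_pharmacophore_decision_table(resname, atom, element, backbone, expected):
    assert classify_atom(resname, atom, element, backbone) == expected


def test_model_interface_pipeline_runs_all_modes(toy_structure):
    for mode in ("calpha", "restricted", "all"):
        pair = model_interface(toy_structure, "A", "B", mode=mode)
        assert pair.side_a.points and pair.side_b.points
        assert pair.side_a.reduction_mode == mode
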
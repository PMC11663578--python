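"""Contact-set rules, structure parsing, residue mapping and ddG classes."""

import numpy as np
import pandas as pd
import pytest

import photoevol as pe
from photoevol.contacts import (
    classify_interface_effect,
    cofactor_binding_residues,
    interface_residues,
    load_packaged_ddg_table,
    map_structure_to_alignment,
)
from photoevol.structures import Atom, Residue, StructureModel, StructureError, chain_sequence
from photoevol.synthetic import ToyStructureSpec, generate_toy_structure


def brute_force_cofactor(structure, cutoff):
    out = set()
    ligand_atoms = [
        a for r in structure.hetero_residues() for a in r.heavy_atoms()
    ]
    for res in structure.polymer_residues():
        for a in res.heavy_atoms():
            for b in ligand_atoms:
                d = np.linalg.norm(np.subtract(a.xyz, b.xyz))
                if d < cutoff:
                    out.add(res.key)
    return out


def brute_force_interface(structure, pair, cutoff):
    out = set()
    ra = [r for r in structure.chains[pair[0]] if not r.hetero]
    rb = [r for r in structure.chains[pair[1]] if not r.hetero]
    for r1 in ra:
        for r2 in rb:
            for a in r1.heavy_atoms():
                for b in r2.heavy_atoms():
                    if np.linalg.norm(np.subtract(a.xyz, b.xyz)) < cutoff:
                        out.add(r1.key)
                        out.add(r2.key)
    return out


def random_structure(rng, n_per_chain=40, box=15.0):
    chains = {}
    serial = 0
    for cname in ("A", "B"):
        residues = []
        for i in range(1, n_per_chain + 1):
            atoms = [
                Atom("CA", "C", *rng.uniform(0, box, 3)),
                Atom("N", "N", *rng.uniform(0, box, 3)),
            ]
            residues.append(Residue(cname, i, "", "ALA", False, atoms))
        chains[cname] = residues
    chains["L"] = [
        Residue("L", 1, "", "LIG", True, [Atom("C1", "C", *rng.uniform(0, box, 3))])
    ]
    return StructureModel("toy", chains)


class TestStructureParsing:
    def test_toy_pdb_round_trip(self):
        spec = ToyStructureSpec(residues_per_chain=3, ligand_distance=3.9)
        st = pe.read_structure(generate_toy_structure(spec))
        assert set(st.chains) == {"A", "B", "L"}
        assert len(st.polymer_residues()) == 6
        (lig,) = st.hetero_residues()
        assert lig.name == "LIG"
        # requested ligand distance is realized exactly
        anchor_ca = [a for a in st.chains["A"][0].atoms if a.name == "CA"][0]
        d = np.linalg.norm(np.subtract(anchor_ca.xyz, lig.atoms[0].xyz))
        assert d == pytest.approx(3.9, abs=1e-3)

    def test_header_only_is_empty_structure_error(self):
        with pytest.raises(StructureError):
            pe.read_structure("HEADER    ONLY\nEND\n")

    def test_chain_sequence_extraction(self):
        spec = ToyStructureSpec(residues_per_chain=4)
        st = pe.read_structure(generate_toy_structure(spec))
        seq, keys = chain_sequence(st, "A")
        assert seq == "AAAA" and keys[0] == ("A", 1, "")


class TestCofactorRule:
    def test_strict_four_angstrom_boundary(self):
        inside = pe.read_structure(
            generate_toy_structure(ToyStructureSpec(ligand_distance=3.9))
        )
        at_cut = pe.read_structure(
            generate_toy_structure(ToyStructureSpec(ligand_distance=4.0))
        )
        assert ("A", 1, "") in cofactor_binding_residues(inside).members
        assert ("A", 1, "") not in cofactor_binding_residues(at_cut).members

    def test_hydrogen_does_not_trigger_contact(self):
        spec = ToyStructureSpec(
            residues_per_chain=4, ligand_distance=30.0, hydrogen_near_ligand=2.0
        )
        st = pe.read_structure(generate_toy_structure(spec))
        assert cofactor_binding_residues(st).members == set()

    def test_empty_selector_warns_and_returns_empty(self):
        st = pe.read_structure(generate_toy_structure(ToyStructureSpec()))
        with pytest.warns(UserWarning):
            cset = cofactor_binding_residues(st, cofactor_names=["XYZ"])
        assert cset.members == set()


class TestInterfaceRule:
    def test_contact_pair_in_set_and_distant_chains_empty(self):
        near = pe.read_structure(
            generate_toy_structure(ToyStructureSpec(contact_pair=(2, 3, 3.5)))
        )
        sets = interface_residues(near, [("A", "B")])
        members = sets[("A", "B")].members
        assert ("A", 2, "") in members and ("B", 3, "") in members
        far = pe.read_structure(generate_toy_structure(ToyStructureSpec()))
        assert interface_residues(far, [("A", "B")])[("A", "B")].members == set()

    def test_unknown_chain_raises(self):
        st = pe.read_structure(generate_toy_structure(ToyStructureSpec()))
        with pytest.raises(KeyError):
            interface_residues(st, [("A", "Z")])

    @pytest.mark.parametrize("seed", range(25))
    def test_tree_search_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        st = random_structure(rng)
        cutoff = rng.uniform(2.0, 6.0)
        assert cofactor_binding_residues(st, cutoff=cutoff).members == (
            brute_force_cofactor(st, cutoff)
        )
        got = interface_residues(st, [("A", "B")], cutoff)[("A", "B")].members
        assert got == brute_force_interface(st, ("A", "B"), cutoff)

    def test_shrinking_cutoff_never_adds_members(self):
        rng = np.random.default_rng(99)
        st = random_structure(rng)
        prev = None
        for cutoff in (6.0, 4.0, 3.0, 2.0):
            members = cofactor_binding_residues(st, cutoff=cutoff).members
            if prev is not None:
                assert members <= prev
            prev = members


class TestResidueMap:
    def test_identity_map(self):
        keys = [("A", i, "") for i in range(1, 11)]
        m = map_structure_to_alignment("MKELVWRTYH", keys, "MKELVWRTYH")
        assert m.mapping == {k: i + 1 for i, k in enumerate(keys)}
        assert m.identity == 1.0 and not m.low_identity

    def test_leading_reference_gap_shifts_columns(self):
        keys = [("A", i, "") for i in range(1, 11)]
        m = map_structure_to_alignment("MKELVWRTYH", keys, "-MKELVWRTYH")
        assert m.mapping[("A", 1, "")] == 2
        assert m.mapping[("A", 10, "")] == 11

    def test_internal_deletion_skips_exact_span(self):
        # structure chain lacks residues 5-7 of the reference
        ref = "MKELVWRTYH"
        chain = "MKEL" + "TYH"
        keys = [("A", i, "") for i in range(1, 8)]
        m = map_structure_to_alignment(chain, keys, ref)
        assert m.mapping[("A", 4, "")] == 4
        assert m.mapping[("A", 5, "")] == 8  # T maps past the deleted VWR
        assert len(m.mapping) == 7

    def test_low_identity_flag(self):
        keys = [("A", i, "") for i in range(1, 11)]
        m = map_structure_to_alignment("AAAAAAAAAA", keys, "WWWWWWWWWW")
        assert m.low_identity


class TestEffectClassification:
    def test_sign_and_threshold_rule(self):
        df = pd.DataFrame(
            {
                "substitution": ["E235A", "M640T", "X1Y", "bad"],
                "interface": ["A:D", "B:A", "A:B", "A:B"],
                "ddg_kcal_mol": [1.43, -6.15, 0.30, np.nan],
            }
        )
        out, counts = classify_interface_effect(df)
        assert list(out["classification"]) == [
            "destabilizing",
            "stabilizing",
            "negligible",
            "rejected",
        ]
        assert counts["destabilizing"] == 1 and counts["stabilizing"] == 1

    def test_threshold_boundary_inclusive(self):
        df = pd.DataFrame({"ddg_kcal_mol": [0.5, -0.5, 0.499, -0.499]})
        out, _ = classify_interface_effect(df)
        assert list(out["classification"]) == [
            "destabilizing",
            "stabilizing",
            "negligible",
            "negligible",
        ]

    def test_packaged_table_all_non_negligible(self):
        table = load_packaged_ddg_table()
        assert len(table) == 19
        out, counts = classify_interface_effect(table)
        assert counts["negligible"] == 0
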
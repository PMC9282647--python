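import numpy as np
import pandas as pd
import pytest

from _oracles import brute_force_fingerprint, brute_force_site
from conftest import random_complex
from hergsift.interaction_fingerprints import (
    INTERACTION_TYPES,
    BindingSite,
    BindingSiteConfig,
    GeometryRules,
    compute_fingerprint,
    define_binding_site,
    fingerprint_matrix,
)
from hergsift.structures_io import (
    Atom,
    ComplexModel,
    LigandAtom,
    LigandPose,
    ReceptorStructure,
    Residue,
)
from hergsift.synthetic_data import (
    LigandPlacement,
    ToyComplexSpec,
    make_toy_complex,
    make_toy_receptor,
)

IDX = {t: i for i, t in enumerate(INTERACTION_TYPES)}


def single_residue_receptor(resname="PHE", atom=("CZ", "C"),
                            atom_xyz=(0.0, 0.0, 0.0)):
    name, elem = atom
    res = Residue("A", 557, resname, (
        Atom("N", "N", (5.0, 5.0, 0.0)),
        Atom("CA", "C", (5.0, 6.4, 0.0)),
        Atom("C", "C", (5.0, 7.9, 0.0)),
        Atom("O", "O", (5.6, 9.0, 0.0)),
        Atom(name, elem, atom_xyz),
    ))
    return ReceptorStructure((res,))


def pose_at(xyz, element="C", charge=0, n_h=0, cid="lig"):
    return LigandPose(cid, (LigandAtom(element, xyz, charge, n_h),), -8.0)


class TestDefineBindingSite:
    def test_boundary_inside_cutoff_included(self):
        receptor = single_residue_receptor()
        site = define_binding_site(receptor, pose_at((8.9, 0.0, 0.0)),
                                   BindingSiteConfig(9.0))
        assert (557, "PHE") in site.residue_keys

    def test_pose_far_outside_is_error(self):
        receptor = single_residue_receptor()
        with pytest.raises(ValueError, match="outside"):
            define_binding_site(receptor, pose_at((50.0, 50.0, 50.0)))

    def test_tetramer_keys_are_monomer_collapsed(self):
        cm = make_toy_complex(ToyComplexSpec(
            residues_per_chain=((656, "PHE"),),
            placements=(LigandPlacement("A", 656, "CZ", 3.0),),
        ))
        site = define_binding_site(cm.receptor, cm.pose)
        assert site.residue_keys.count((656, "PHE")) == 1

    def test_matches_brute_force_site(self, rng):
        for _ in range(20):
            cm = random_complex(rng)
            expected = brute_force_site(cm.receptor, cm.pose, 9.0)
            try:
                site = define_binding_site(cm.receptor, cm.pose)
            except ValueError:
                assert expected == []
                continue
            assert list(site.residue_keys) == expected


class TestComputeFingerprint:
    def test_far_ligand_gives_all_zero_row(self):
        receptor = single_residue_receptor()
        site = BindingSite(((557, "PHE"),))
        fp = compute_fingerprint(
            ComplexModel(receptor, pose_at((8.0, 0.0, 0.0))), site)
        assert fp.bits.sum() == 0

    def test_phe_sidechain_carbon_bit_pattern(self):
        # ligand C at 3.5 A from the PHE ring carbon only
        receptor = single_residue_receptor()
        site = BindingSite(((557, "PHE"),))
        fp = compute_fingerprint(
            ComplexModel(receptor, pose_at((3.5, 0.0, 0.0))), site)
        expected = {"contact": 1, "backbone": 0, "sidechain": 1, "polar": 0,
                    "hydrophobic": 1, "hbond_acceptor": 0, "hbond_donor": 0,
                    "aromatic": 1, "charged": 0}
        assert {t: int(fp.bits[0, IDX[t]]) for t in INTERACTION_TYPES} == expected

    def test_hbond_directionality_acceptor_vs_donor_residue(self):
        # ASP OD1 only accepts; LYS NZ only donates
        for resname, atom, expect in (
            ("ASP", ("OD1", "O"), "hbond_acceptor"),
            ("LYS", ("NZ", "N"), "hbond_donor"),
        ):
            receptor = single_residue_receptor(resname, atom)
            site = BindingSite(((557, resname),))
            # ligand N-H: donor and acceptor
            fp = compute_fingerprint(
                ComplexModel(receptor, pose_at((3.2, 0, 0), "N", 0, 1)), site)
            assert fp.bits[0, IDX[expect]] == 1
            other = ("hbond_donor" if expect == "hbond_acceptor"
                     else "hbond_acceptor")
            assert fp.bits[0, IDX[other]] == 0

    def test_carbon_ligand_atom_makes_no_hbond(self):
        receptor = single_residue_receptor("SER", ("OG", "O"))
        site = BindingSite(((557, "SER"),))
        fp = compute_fingerprint(
            ComplexModel(receptor, pose_at((3.0, 0, 0), "C")), site)
        assert fp.bits[0, IDX["hbond_acceptor"]] == 0
        assert fp.bits[0, IDX["hbond_donor"]] == 0
        assert fp.bits[0, IDX["polar"]] == 1

    def test_or_merge_single_chain_interaction_lights_merged_bit(self):
        cm = make_toy_complex(ToyComplexSpec(
            n_chains=4,
            residues_per_chain=((656, "PHE"),),
            placements=(LigandPlacement("C", 656, "CZ", 3.0),),
        ))
        site = define_binding_site(cm.receptor, cm.pose)
        fp = compute_fingerprint(cm, site)
        row = list(site.residue_keys).index((656, "PHE"))
        assert fp.bits[row, IDX["contact"]] == 1

    def test_or_merge_equals_elementwise_or_of_monomers(self, rng):
        for _ in range(10):
            cm = random_complex(rng)
            try:
                site = define_binding_site(cm.receptor, cm.pose)
            except ValueError:
                continue
            merged = compute_fingerprint(cm, site).bits
            acc = np.zeros_like(merged)
            for chain in cm.receptor.monomer_ids:
                sub = ReceptorStructure(tuple(
                    r for r in cm.receptor.residues if r.chain_id == chain))
                for row, key in enumerate(site.residue_keys):
                    if sub.by_key(key):
                        single = BindingSite((key,))
                        acc[row] |= compute_fingerprint(
                            ComplexModel(sub, cm.pose), single).bits[0]
            np.testing.assert_array_equal(merged, acc)

    def test_rigid_motion_invariance(self, rng):
        cm = make_toy_complex()
        site = define_binding_site(cm.receptor, cm.pose)
        ref = compute_fingerprint(cm, site).bits
        # random proper rotation + translation applied to receptor and pose
        q = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        t = rng.normal(scale=30.0, size=3)

        def move(xyz):
            return tuple(q @ np.asarray(xyz) + t)

        receptor = ReceptorStructure(tuple(
            Residue(r.chain_id, r.residue_number, r.residue_name,
                    tuple(Atom(a.name, a.element, move(a.xyz)) for a in r.atoms))
            for r in cm.receptor.residues))
        pose = LigandPose(cm.pose.compound_id, tuple(
            LigandAtom(a.element, move(a.xyz), a.formal_charge, a.n_attached_h)
            for a in cm.pose.atoms), cm.pose.docking_score)
        moved = compute_fingerprint(ComplexModel(receptor, pose), site).bits
        np.testing.assert_array_equal(ref, moved)

    def test_enlarging_contact_cutoff_only_turns_bits_on(self, rng):
        for _ in range(10):
            cm = random_complex(rng)
            try:
                site = define_binding_site(cm.receptor, cm.pose)
            except ValueError:
                continue
            small = compute_fingerprint(cm, site, GeometryRules(contact_max_A=3.5))
            large = compute_fingerprint(cm, site, GeometryRules(contact_max_A=6.0))
            assert np.all(large.bits >= small.bits)

    def test_specific_bits_imply_contact(self, rng):
        for _ in range(30):
            cm = random_complex(rng)
            try:
                site = define_binding_site(cm.receptor, cm.pose)
            except ValueError:
                continue
            bits = compute_fingerprint(cm, site).bits
            no_contact = bits[:, IDX["contact"]] == 0
            assert bits[no_contact].sum() == 0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            cm = random_complex(rng)
            try:
                site = define_binding_site(cm.receptor, cm.pose)
            except ValueError:
                continue
            got = compute_fingerprint(cm, site).bits
            expected = np.array(brute_force_fingerprint(
                cm.receptor, cm.pose, site.residue_keys))
            np.testing.assert_array_equal(got, expected)

    def test_missing_site_residue_is_error(self):
        receptor = single_residue_receptor()
        with pytest.raises(ValueError, match="absent"):
            compute_fingerprint(
                ComplexModel(receptor, pose_at((3.0, 0, 0))),
                BindingSite(((999, "GLY"),)))


class TestFingerprintMatrix:
    def test_shape_and_column_labels(self):
        cm = make_toy_complex(ToyComplexSpec(
            residues_per_chain=((557, "PHE"), (623, "THR"), (624, "SER")),
            rise_per_residue_A=3.0,
        ))
        site = define_binding_site(cm.receptor, cm.pose)
        assert len(site.residue_keys) == 3
        cm2 = ComplexModel(cm.receptor, LigandPose(
            "other", cm.pose.atoms, -6.5))
        table = fingerprint_matrix([cm, cm2], site)
        assert table.shape == (2, 27)
        assert list(table.columns)[:2] == ["557_contact", "557_backbone"]
        assert "557_aromatic" in table.columns

    def test_identical_pose_gives_identical_rows(self):
        cm = make_toy_complex()
        site = define_binding_site(cm.receptor, cm.pose)
        cm2 = ComplexModel(cm.receptor,
                           LigandPose("copy", cm.pose.atoms, -8.0))
        table = fingerprint_matrix([cm, cm2], site)
        assert (table.iloc[0] == table.iloc[1]).all()

    def test_duplicate_compound_id_is_error(self):
        cm = make_toy_complex()
        site = define_binding_site(cm.receptor, cm.pose)
        with pytest.raises(ValueError, match="duplicate"):
            fingerprint_matrix([cm, cm], site)
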
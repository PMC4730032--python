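"""Metal-site detection, geometry classification, contacts and interfaces."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gapstat import (
    classify_site_geometry,
    detect_bidentate,
    find_metal_sites,
    find_polar_contacts,
    interface_area,
    make_coordination_site,
    shrake_rupley_sasa,
    site_formal_charge,
)
from gapstat.sites import MetalSite, _ideal_templates
from gapstat.structure import Atom, Structure


def atom(name, element, resname, resnum, chain, pos, hetero=False, q=None):
    return Atom(0, name, element, resname, resnum, chain, np.array(pos, float),
                is_hetero=hetero, formal_charge=q)


def make_site(vectors, distance=2.4, names=None):
    """MetalSite with ligand oxygens along given unit vectors."""
    metal = atom("CA", "CA", "CA", 1, "X", [0, 0, 0], hetero=True, q=2.0)
    ligands, dists = [], []
    for i, v in enumerate(vectors):
        v = np.asarray(v, float)
        v = v / np.linalg.norm(v)
        spec = names[i] if names else ("O", "O", "HOH", 100 + i, "A")
        ligands.append(atom(*spec, pos=distance * v))
        dists.append(distance)
    return MetalSite(metal=metal, ligand_atoms=ligands, distances=dists)


class TestFindMetalSites:
    def test_gjc_channel_has_twelve_pentacoordinate_sites(self, gjc_channel):
        sites = find_metal_sites(gjc_channel, {"CA"}, cutoff=2.9)
        assert len(sites) == 12
        for s in sites:
            assert s.cn == 5
            assert s.mean_distance == pytest.approx(2.6, abs=1e-9)
            assert s.formal_charge == -2
            assert s.geometry_class == "square_pyramidal"
            assert len(s.subunits_involved) == 2  # shared between adjacent chains
            names = {(a.residue_name, a.residue_number) for a in s.ligand_atoms}
            assert names == {("GLY", 45), ("GLU", 47), ("GLU", 42)}

    def test_isolated_metal_excluded(self):
        s = Structure(
            [
                atom("CA", "CA", "CA", 1, "X", [0, 0, 0], hetero=True),
                atom("O", "O", "GLY", 2, "A", [10.0, 0, 0]),
            ]
        )
        assert find_metal_sites(s, {"CA"}, cutoff=2.9) == []

    def test_constructed_octahedral_site(self):
        axes = [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
        atoms = [atom("CA", "CA", "CA", 1, "X", [0, 0, 0], hetero=True)]
        atoms += [
            atom("O", "O", "HOH", 100 + i, "A", 2.40 * np.array(v), hetero=True)
            for i, v in enumerate(axes)
        ]
        s = Structure(atoms)
        sites = find_metal_sites(s, {"CA"}, cutoff=2.9, include_water=True)
        assert len(sites) == 1
        assert sites[0].cn == 6
        np.testing.assert_allclose(sites[0].distances, 2.40, atol=1e-12)
        assert sites[0].geometry_class == "octahedral"

    def test_cutoff_monotonicity(self, gjc_channel):
        # enlarging the cutoff never removes a ligand
        prev: dict = {}
        for cutoff in (2.0, 2.7, 2.9, 3.5, 4.5):
            sites = find_metal_sites(gjc_channel, {"CA"}, cutoff)
            current = {
                (s.metal.chain_id, s.metal.residue_number): {
                    (a.chain_id, a.residue_number, a.name) for a in s.ligand_atoms
                }
                for s in sites
            }
            for key, ligs in prev.items():
                assert key in current and ligs <= current[key]
            prev = current


class TestFormalCharge:
    def test_two_glutamates_plus_carbonyl_is_minus_two(self):
        atoms = make_coordination_site(np.zeros(3))
        s = Structure(atoms)
        site = find_metal_sites(s, {"CA"}, 2.9)[0]
        assert site_formal_charge(site) == -2

    def test_all_water_coordination_is_zero(self):
        site = make_site(_ideal_templates(6)["octahedral"])
        assert site_formal_charge(site) == 0

    def test_three_monodentate_aspartates(self):
        names = [("OD1", "O", "ASP", 10 + i, "A") for i in range(3)]
        site = make_site(np.eye(3), names=names)
        assert site_formal_charge(site) == -3

    @settings(deadline=None, derandomize=True)
    @given(st.permutations(range(5)))
    def test_permutation_invariance(self, perm):
        names = [
            ("OE1", "O", "GLU", 47, "A"),
            ("OE2", "O", "GLU", 47, "A"),
            ("OE1", "O", "GLU", 42, "B"),
            ("OE2", "O", "GLU", 42, "B"),
            ("O", "O", "GLY", 45, "A"),
        ]
        vecs = _ideal_templates(5)["square_pyramidal"]
        site = make_site(vecs[list(perm)], names=[names[i] for i in perm])
        assert site_formal_charge(site) == -2

    def test_unknown_residue_warns_and_counts_zero(self):
        names = [("O1", "O", "XYZ", 5, "A"), ("O", "O", "GLY", 6, "A"),
                 ("OE1", "O", "GLU", 7, "A")]
        site = make_site(np.eye(3), names=names)
        with pytest.warns(UserWarning, match="XYZ"):
            assert site_formal_charge(site) == -1


class TestGeometryClassification:
    @pytest.mark.parametrize("cn", [4, 5, 6])
    def test_ideal_templates_self_classify_with_zero_rmsd(self, cn):
        for name, template in _ideal_templates(cn).items():
            site = make_site(template)
            got, rmsd = classify_site_geometry(site)
            assert got == name
            assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_octahedron_minus_vertex_is_square_pyramid(self):
        octa = _ideal_templates(6)["octahedral"]
        site = make_site(octa[:-1])  # delete one vertex
        got, rmsd = classify_site_geometry(site)
        assert got == "square_pyramidal"
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_rotated_template_still_classifies(self, rng):
        from scipy.spatial.transform import Rotation

        rot = Rotation.random(random_state=7).as_matrix()
        tbp = _ideal_templates(5)["trigonal_bipyramidal"] @ rot.T
        got, rmsd = classify_site_geometry(make_site(tbp))
        assert got == "trigonal_bipyramidal"
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_random_directions_are_irregular(self, rng):
        vecs = rng.normal(size=(5, 3))
        vecs[4] = vecs[3] + 0.05 * rng.normal(size=3)  # two nearly parallel ligands
        got, rmsd = classify_site_geometry(make_site(vecs))
        assert got == "irregular"
        assert rmsd > 20.0

    def test_unsupported_cn_rejected(self):
        site = make_site(np.eye(3))
        with pytest.raises(ValueError, match="4..6"):
            classify_site_geometry(site)


class TestBidentate:
    def test_gjc_site_has_two_bidentate_glutamates(self, gjc_channel):
        site = find_metal_sites(gjc_channel, {"CA"}, 2.9)[0]
        found = detect_bidentate(site)
        assert {(b["residue_name"], b["residue_number"]) for b in found} == {
            ("GLU", 42),
            ("GLU", 47),
        }
        for b in found:
            assert b["difference"] == pytest.approx(0.0, abs=1e-12)

    def test_single_oxygen_glutamate_not_bidentate(self):
        names = [("OE1", "O", "GLU", 47, "A"), ("O", "O", "GLY", 45, "A"),
                 ("O", "O", "HOH", 90, "A")]
        site = make_site(np.eye(3), names=names)
        assert detect_bidentate(site) == []

    def test_symmetric_bidentate_reports_zero_difference(self):
        names = [("OD1", "O", "ASP", 12, "A"), ("OD2", "O", "ASP", 12, "A")]
        site = make_site([[1, 0, 0], [0, 1, 0]], distance=2.5, names=names)
        found = detect_bidentate(site)
        assert len(found) == 1
        assert found[0]["distances"] == (2.5, 2.5)
        assert found[0]["difference"] == 0.0


class TestPolarContacts:
    def test_glu_lys_pair_is_salt_bridge(self):
        s = Structure(
            [
                atom("OE1", "O", "GLU", 47, "A", [0, 0, 0]),
                atom("OE2", "O", "GLU", 47, "A", [1.2, 1.2, 0]),
                atom("NZ", "N", "LYS", 188, "A", [3.2, 0, 0]),
            ]
        )
        contacts = find_polar_contacts(s)
        kinds = {c.kind for c in contacts}
        assert "salt_bridge" in kinds
        sb = [c for c in contacts if c.kind == "salt_bridge"][0]
        assert sb.scope == "intrasubunit"
        assert sb.distance == pytest.approx(3.2)

    def test_distant_glycines_have_no_contacts(self):
        s = Structure(
            [
                atom("N", "N", "GLY", 1, "A", [0, 0, 0]),
                atom("O", "O", "GLY", 1, "A", [1.0, 0, 0]),
                atom("N", "N", "GLY", 2, "B", [20.0, 0, 0]),
                atom("O", "O", "GLY", 2, "B", [21.0, 0, 0]),
            ]
        )
        assert find_polar_contacts(s) == []

    def test_hemichannel_scope_labeling(self):
        s = Structure(
            [
                atom("NE2", "N", "GLN", 57, "A", [0, 0, 0]),
                atom("OE1", "O", "GLN", 57, "G", [2.9, 0, 0]),
            ]
        )
        both = find_polar_contacts(s, chain_groups={"A": 0, "G": 1})
        assert both[0].kind == "hydrogen_bond"
        assert both[0].scope == "interhemichannel"
        same = find_polar_contacts(s, chain_groups={"A": 0, "G": 0})
        assert same[0].scope == "intersubunit"


class TestInterfaceArea:
    def test_distant_atoms_bury_nothing(self):
        s = Structure(
            [
                atom("C", "C", "DUM", 1, "A", [0, 0, 0]),
                atom("C", "C", "DUM", 2, "B", [100.0, 0, 0]),
            ]
        )
        area = interface_area(s, [s.atoms[0]], [s.atoms[1]])
        assert area == pytest.approx(0.0, abs=1e-9)

    def test_touching_spheres_match_cap_formula(self):
        # two carbons in exact vdW contact; buried area per the analytic
        # spherical cap on the probe-inflated sphere: 2 pi R (R - d/2)
        r, probe = 1.7, 1.4
        d = 2 * r
        s = Structure(
            [
                atom("C", "C", "DUM", 1, "A", [0, 0, 0]),
                atom("C", "C", "DUM", 2, "B", [d, 0, 0]),
            ]
        )
        area = interface_area(s, [s.atoms[0]], [s.atoms[1]], probe=probe)
        R = r + probe
        expected = 2 * math.pi * R * (R - d / 2)
        assert area == pytest.approx(expected, rel=0.02)

    def test_symmetric_and_nonnegative(self, gjc_channel):
        ga = [a for a in gjc_channel.atoms if a.chain_id == "A" and not a.is_hetero]
        gb = [a for a in gjc_channel.atoms if a.chain_id == "B" and not a.is_hetero]
        ab = interface_area(gjc_channel, ga, gb)
        ba = interface_area(gjc_channel, gb, ga)
        assert ab == pytest.approx(ba, abs=1e-9)
        assert ab >= 0.0

    def test_empty_or_overlapping_selection_rejected(self, gjc_channel):
        ga = [a for a in gjc_channel.atoms if a.chain_id == "A"]
        with pytest.raises(ValueError):
            interface_area(gjc_channel, ga, [])
        with pytest.raises(ValueError):
            interface_area(gjc_channel, ga, ga)

    def test_sasa_of_isolated_sphere_is_exact(self):
        areas = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.7]), probe=1.4)
        assert areas[0] == pytest.approx(4 * math.pi * (1.7 + 1.4) ** 2, rel=1e-12)

    def test_sasa_cross_check_against_biotite(self, rng):
        import biotite.structure as bst

        coords = rng.normal(scale=3.0, size=(20, 3))
        radii = np.full(20, 1.7)
        ours = shrake_rupley_sasa(coords, radii, probe=1.4, n_points=960).sum()
        arr = bst.AtomArray(20)
        arr.coord = coords
        arr.element = np.array(["C"] * 20)
        arr.res_id = np.arange(1, 21)
        arr.res_name = np.array(["DUM"] * 20)
        arr.atom_name = np.array(["C"] * 20)
        arr.chain_id = np.array(["A"] * 20)
        theirs = bst.sasa(arr, probe_radius=1.4, point_number=960,
                          vdw_radii=radii).sum()
        assert ours == pytest.approx(theirs, rel=0.01)
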
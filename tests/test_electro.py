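"""Charge/radius assignment and the finite-difference Poisson solver.

The solver is validated against two closed forms: the Coulomb potential of a
point charge in a uniform dielectric, and the concentric-dielectric ("Born")
sphere, whose exterior potential is exactly Coulombic in the outer dielectric
and whose interior picks up the reaction-field offset
q (1/eps_out - 1/eps_in) / a.
"""

import numpy as np
import pytest

from gapstat import (
    build_charge_radius_model,
    coulomb_constant,
    make_coordination_site,
    make_gjc_like_channel,
    pore_positive_fraction,
    solve_poisson,
    surface_potential_map,
)
from gapstat.electro import ChargeRadiusModel, write_dx
from gapstat.structure import Atom, Structure


def point_model(q, radius=1.0):
    return ChargeRadiusModel(
        np.zeros((1, 3)), np.array([float(q)]), np.array([radius]), ["formal"]
    )


@pytest.fixture(scope="module")
def site_structure():
    return Structure(make_coordination_site(np.zeros(3)))


class TestChargeRadiusModel:
    def test_glycine_only_structure_is_neutral(self):
        atoms = [
            Atom(1, "N", "N", "GLY", 1, "A", [0, 0, 0]),
            Atom(2, "CA", "C", "GLY", 1, "A", [1.5, 0, 0]),
            Atom(3, "C", "C", "GLY", 1, "A", [2.5, 1, 0]),
            Atom(4, "O", "O", "GLY", 1, "A", [3.5, 1, 0]),
        ]
        model = build_charge_radius_model(Structure(atoms))
        assert model.total_charge == pytest.approx(0.0)

    def test_glu_lys_pair_is_neutral_with_split_oxygens(self):
        atoms = [
            Atom(1, "OE1", "O", "GLU", 47, "A", [0, 0, 0]),
            Atom(2, "OE2", "O", "GLU", 47, "A", [2.2, 0, 0]),
            Atom(3, "NZ", "N", "LYS", 188, "A", [5.0, 0, 0]),
        ]
        model = build_charge_radius_model(Structure(atoms))
        assert model.total_charge == pytest.approx(0.0)
        np.testing.assert_allclose(model.charges[:2], -0.5)
        assert model.charges[2] == pytest.approx(1.0)

    def test_metal_toggle_changes_total_by_two_per_site(self, gjc_channel):
        with_ca = build_charge_radius_model(gjc_channel, include_metal_charges=True)
        without = build_charge_radius_model(gjc_channel, include_metal_charges=False)
        assert with_ca.total_charge - without.total_charge == pytest.approx(24.0)

    def test_radius_classes(self):
        atoms = [
            Atom(1, "O", "O", "GLY", 1, "A", [0, 0, 0]),      # carbonyl
            Atom(2, "OG", "O", "SER", 2, "A", [3, 0, 0]),     # hydroxyl
            Atom(3, "SG", "S", "CYS", 3, "A", [6, 0, 0]),     # thiol
            Atom(4, "CA", "CA", "CA", 4, "X", [9, 0, 0], is_hetero=True),
        ]
        model = build_charge_radius_model(Structure(atoms))
        np.testing.assert_allclose(model.radii, [1.542, 1.500, 1.812, 1.650])

    def test_disulfide_detection_shrinks_sulfur(self):
        atoms = [
            Atom(1, "SG", "S", "CYS", 53, "A", [0, 0, 0]),
            Atom(2, "SG", "S", "CYS", 180, "A", [2.05, 0, 0]),
        ]
        model = build_charge_radius_model(Structure(atoms))
        np.testing.assert_allclose(model.radii, [1.491, 1.491])


class TestPoissonSolver:
    def test_zero_charges_give_zero_potential(self):
        model = point_model(0.0)
        grid = solve_poisson(model, spacing=1.0, padding=8.0)
        assert np.abs(grid.phi).max() < 1e-10

    def test_uniform_dielectric_matches_coulomb_within_3pct(self):
        model = point_model(1.0)
        grid = solve_poisson(model, spacing=1.0, padding=20.0,
                             eps_in=78.5, eps_out=78.5)
        C = coulomb_constant()
        for r in (5.0, 8.0, 12.0, 15.0):
            pts = np.array([[r, 0, 0], [0, r, 0], [0, 0, r],
                            [r / np.sqrt(2), r / np.sqrt(2), 0]])
            phi = grid.interpolate(pts)
            exact = C / (78.5 * r)
            assert np.abs(phi / exact - 1).max() < 0.03

    def test_born_sphere_matches_closed_form_within_5pct(self):
        a = 1.65
        model = point_model(2.0, radius=a)
        grid = solve_poisson(model, spacing=0.3, padding=10.0,
                             eps_in=4.0, eps_out=78.5)
        C = coulomb_constant()
        # exterior: pure Coulomb in the outer dielectric
        for r in (3.0, 5.0, 7.0):
            pts = np.array([[r, 0, 0], [0, r, 0], [0, 0, r]])
            phi = grid.interpolate(pts).mean()
            exact = C * 2.0 / (78.5 * r)
            assert abs(phi / exact - 1) < 0.05
        # interior: Coulomb in eps_in plus the constant reaction-field term
        r = 1.0
        pts = np.array([[r, 0, 0], [0, r, 0], [0, 0, r],
                        [-r, 0, 0], [0, -r, 0], [0, 0, -r]])
        phi = grid.interpolate(pts).mean()
        exact = C * 2.0 * (1 / (4.0 * r) - 1 / (4.0 * a) + 1 / (78.5 * a))
        assert abs(phi / exact - 1) < 0.05

    def test_linearity_of_superposed_charge_sets(self, site_structure):
        base = build_charge_radius_model(site_structure, include_metal_charges=True)
        q_metal = np.where(np.abs(base.charges) == 2.0, base.charges, 0.0)
        q_protein = base.charges - q_metal
        kw = dict(spacing=0.8, padding=8.0)
        phi_all = solve_poisson(base, **kw).phi
        phi_m = solve_poisson(
            ChargeRadiusModel(base.coords, q_metal, base.radii, base.provenance), **kw
        ).phi
        phi_p = solve_poisson(
            ChargeRadiusModel(base.coords, q_protein, base.radii, base.provenance), **kw
        ).phi
        scale = np.abs(phi_all).max()
        assert np.abs(phi_all - (phi_m + phi_p)).max() / scale < 1e-4

    def test_grid_refinement_consistency(self):
        # halving the spacing changes the pore-lining mean potential < 10%
        from gapstat import ToyChannelSpec, make_toy_channel

        spec = ToyChannelSpec(
            n_fold=6,
            rings=[(float(z), 10.0) for z in range(-20, 21, 2)],
            site_charges=[(0.0, 60.0 * k, 2.0) for k in range(6)],
            site_radius=8.0,
        )
        model = build_charge_radius_model(make_toy_channel(spec))
        theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        pts = np.vstack(
            [
                np.column_stack(
                    [6.0 * np.cos(theta), 6.0 * np.sin(theta), np.full(10, z)]
                )
                for z in (-10.0, 0.0, 10.0)
            ]
        )
        coarse = solve_poisson(model, spacing=1.2, padding=6.0)
        fine = solve_poisson(model, spacing=0.6, padding=6.0)
        mean_c = coarse.interpolate(pts).mean()
        mean_f = fine.interpolate(pts).mean()
        assert abs(mean_f - mean_c) / abs(mean_f) < 0.10

    def test_metal_charges_raise_potential_near_sites(self):
        channel = make_gjc_like_channel()
        with_ca = build_charge_radius_model(channel, include_metal_charges=True)
        without = build_charge_radius_model(channel, include_metal_charges=False)
        kw = dict(spacing=2.0, padding=6.0)
        g1 = solve_poisson(with_ca, **kw)
        g0 = solve_poisson(without, **kw)
        # pore-lining test points near the upper site ring
        theta = np.linspace(0, 2 * np.pi, 12, endpoint=False)
        pts = np.column_stack(
            [7.0 * np.cos(theta), 7.0 * np.sin(theta), np.full(12, 28.0)]
        )
        dphi = g1.interpolate(pts) - g0.interpolate(pts)
        assert (dphi > 0).all()


class TestSurfacePotential:
    def test_uncharged_channel_surface_is_zero(self):
        channel = make_gjc_like_channel(include_metals=False)
        model = build_charge_radius_model(channel)
        model = ChargeRadiusModel(
            model.coords, np.zeros_like(model.charges), model.radii, model.provenance
        )
        grid = solve_poisson(model, spacing=2.0, padding=6.0)
        sp = surface_potential_map(grid, model, axis=np.array([0, 0, 1.0]),
                                   origin=np.zeros(3), pore_radius=12.0)
        assert np.abs(sp.potential).max() < 1e-8
        stats = pore_positive_fraction(sp)
        assert stats["fraction_positive"] == 0.0  # strict inequality

    def test_single_negative_site_gives_negative_patch(self):
        from gapstat import ToyChannelSpec, make_toy_channel

        spec = ToyChannelSpec(
            n_fold=6,
            rings=[(float(z), 10.0) for z in range(-20, 21, 2)],
            site_charges=[(0.0, 0.0, -1.0)],
            site_radius=8.0,
        )
        channel = make_toy_channel(spec)
        model = build_charge_radius_model(channel)
        grid = solve_poisson(model, spacing=1.5, padding=6.0)
        sp = surface_potential_map(grid, model, axis=np.array([0, 0, 1.0]),
                                   origin=np.zeros(3), pore_radius=10.0,
                                   half_length=20.0)
        near = sp.region == "pore_lining"
        near &= np.abs(sp.points[:, 2]) < 8.0
        frac_pos = float(np.mean(sp.potential[near] > 0))
        assert frac_pos < 0.5

    def test_dx_export_round_trips_shape(self, tmp_path):
        grid = solve_poisson(point_model(1.0), spacing=1.0, padding=5.0)
        out = tmp_path / "phi.dx"
        write_dx(grid, out)
        text = out.read_text().splitlines()
        assert text[0].endswith("counts %d %d %d" % grid.dims)
        n_vals = sum(len(l.split()) for l in text if l and l[0] in "-0123456789")
        assert n_vals >= np.prod(grid.dims)
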
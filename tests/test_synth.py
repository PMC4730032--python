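"""Synthetic generators: toy channels, perturbations, equilibrium trajectories.

The central guarantee checked here is that the Metropolis-mode ion simulator
is exactly Boltzmann-distributed in its 1D potential: bin occupancies of a
long run are compared to exp(-U/kT) with a chi-square goodness-of-fit test at
a fixed seed.
"""

import math

import numpy as np
import pytest
from scipy import stats

from gapstat import (
    LangevinSpec,
    ToyChannelSpec,
    axial_density,
    barrier_from_grid,
    cross_pore_distance,
    gaussian_barrier,
    make_toy_channel,
    perturb_structure,
    pore_occupancy,
    simulate_ion_trajectory,
    solve_poisson,
)
from gapstat.electro import ChargeRadiusModel, build_charge_radius_model


class TestToyChannel:
    def test_hexamer_ring_cross_pore_geometry(self):
        s = make_toy_channel(ToyChannelSpec(n_fold=6, rings=[(0.0, 10.0)]))
        res = cross_pore_distance(
            s, 201, "C", axis=np.array([0, 0, 1.0]), origin=np.zeros(3)
        )
        assert res.opposing == pytest.approx(20.0, abs=1e-9)

    def test_two_hemichannel_axial_extent(self):
        s = make_toy_channel(ToyChannelSpec(half_length=60.0))
        z = s.coords[:, 2]
        assert z.max() - z.min() == pytest.approx(120.0, abs=1e-9)

    def test_exact_n_fold_symmetry(self):
        s = make_toy_channel(ToyChannelSpec(n_fold=5, rings=[(0.0, 9.0), (4.0, 9.0)]))
        t = 2 * math.pi / 5
        rot = np.array(
            [[math.cos(t), -math.sin(t), 0], [math.sin(t), math.cos(t), 0], [0, 0, 1]]
        )
        coords = s.coords
        rotated = coords @ rot.T
        # the rotated atom set coincides with the original set
        d = np.linalg.norm(rotated[:, None] - coords[None, :], axis=-1)
        assert d.min(axis=1).max() < 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ToyChannelSpec(n_fold=2)
        with pytest.raises(ValueError):
            ToyChannelSpec(rings=[(0.0, -1.0)])


class TestPerturbStructure:
    def test_empty_edit_list_is_identity(self, gjc_channel):
        out = perturb_structure(gjc_channel, [])
        assert (out.coords == gjc_channel.coords).all()

    def test_translation_moves_only_selection(self, gjc_channel):
        out = perturb_structure(
            gjc_channel,
            [({"chain_id": "A", "residue_number": 41}, {"translate": (1.0, 2.0, 3.0)})],
        )
        moved = out.find_atom("A", 41, "NZ").position
        orig = gjc_channel.find_atom("A", 41, "NZ").position
        np.testing.assert_allclose(moved - orig, [1.0, 2.0, 3.0])
        untouched_new = [a for a in out.atoms if a.chain_id == "B"]
        untouched_old = [a for a in gjc_channel.atoms if a.chain_id == "B"]
        for a, b in zip(untouched_new, untouched_old):
            assert (a.position == b.position).all()

    def test_unresolved_selection_rejected(self, gjc_channel):
        with pytest.raises(ValueError, match="matched no atoms"):
            perturb_structure(gjc_channel, [({"chain_id": "Z9"}, {"translate": (1, 0, 0)})])


class TestTrajectorySimulation:
    def test_same_seed_is_bitwise_reproducible(self):
        spec = LangevinSpec(potential=gaussian_barrier(2.0), n_steps=2000,
                            record_interval=100, seed=7)
        t1 = simulate_ion_trajectory(spec)
        t2 = simulate_ion_trajectory(spec)
        for f1, f2 in zip(t1.frames, t2.frames):
            for sp in f1:
                assert (f1[sp] == f2[sp]).all()

    def test_flat_potential_is_uniform(self):
        spec = LangevinSpec(
            potential=lambda z: np.zeros_like(np.asarray(z, dtype=float)),
            n_steps=20000, record_interval=50, seed=3,
            species={"K": (80, 1.0)}, half_length=80.0,
        )
        traj = simulate_ion_trajectory(spec)
        prof = axial_density(traj, "K", radius=7.0, dz=10.0, z_range=(-80, 80))
        n_exp = prof.counts.mean()
        # correlated frames: allow a generous multiple of the Poisson scale
        assert np.abs(prof.counts - n_exp).max() < 10 * math.sqrt(n_exp)

    def test_metropolis_matches_boltzmann_chi_square(self):
        # frames must be nearly independent for the chi-square statistic to be
        # calibrated: record intervals are chosen so the rms displacement per
        # interval spans most of the cylinder, and the first frames (uniform
        # initialisation) are discarded as burn-in
        u = gaussian_barrier(3.0)
        spec = LangevinSpec(potential=u, n_steps=160000, record_interval=4000,
                            seed=1, species={"K": (120, 1.0)}, half_length=82.5)
        traj = simulate_ion_trajectory(spec)
        from gapstat import IonTrajectory

        settled = IonTrajectory(traj.frames[5:], frame_interval=traj.frame_interval)
        prof = axial_density(settled, "K", radius=7.0, dz=5.0, z_range=(-82.5, 82.5))
        z = prof.z_bin_centers
        # expected occupancy from the bin-averaged Boltzmann weight
        fine = np.linspace(-82.5, 82.5, 33 * 200, endpoint=False)
        w = np.exp(-u(fine))
        weights = w.reshape(33, 200).mean(axis=1)
        expected = prof.counts.sum() * weights / weights.sum()
        # merge low-expectation bins into one class to keep the test valid
        low = expected < 8
        if low.any():
            obs = np.concatenate([prof.counts[~low], [prof.counts[low].sum()]])
            exp = np.concatenate([expected[~low], [expected[low].sum()]])
        else:
            obs, exp = prof.counts, expected
        chi2 = float(np.sum((obs - exp) ** 2 / exp))
        p = 1 - stats.chi2.cdf(chi2, df=len(obs) - 1)
        assert p > 0.01

    def test_chloride_inverts_the_barrier(self):
        u = gaussian_barrier(3.0)
        spec = LangevinSpec(potential=u, seed=2, n_steps=20000, record_interval=50,
                            half_length=82.5)
        traj = simulate_ion_trajectory(spec)
        occ_k, _ = pore_occupancy(traj, "K", radius=7.0, z_range=(-7.5, 7.5))
        occ_cl, _ = pore_occupancy(traj, "CL", radius=7.0, z_range=(-7.5, 7.5))
        assert occ_cl > occ_k  # anions are attracted where cations are repelled

    def test_oversized_step_warns(self):
        spec = LangevinSpec(potential=gaussian_barrier(1.0), step_scale=40.0,
                            n_steps=200, record_interval=50, seed=0)
        with pytest.warns(UserWarning, match="acceptance"):
            simulate_ion_trajectory(spec)

    def test_euler_mode_runs_and_stays_in_cylinder(self):
        spec = LangevinSpec(potential=gaussian_barrier(1.0), mode="euler",
                            n_steps=2000, record_interval=100, seed=5)
        traj = simulate_ion_trajectory(spec)
        for f in traj.frames:
            for xyz in f.values():
                r = np.hypot(xyz[:, 0], xyz[:, 1])
                assert (r <= spec.cylinder_radius + 1e-9).all()
                assert (np.abs(xyz[:, 2]) <= spec.half_length + 1e-9).all()


def IonTrajectory_thin(traj, stride):
    from gapstat import IonTrajectory

    return IonTrajectory(traj.frames[::stride], frame_interval=traj.frame_interval)


class TestBarrierFromGrid:
    def test_zero_grid_gives_zero_barrier(self):
        model = ChargeRadiusModel(
            np.zeros((1, 3)), np.array([0.0]), np.array([1.0]), ["neutral"]
        )
        grid = solve_poisson(model, spacing=1.0, padding=6.0)
        _, u = barrier_from_grid(grid, +1.0, radius=3.0)
        assert np.abs(u).max() < 1e-10

    def test_sign_symmetry_between_probe_charges(self):
        spec = ToyChannelSpec(
            n_fold=6,
            rings=[(float(z), 10.0) for z in range(-10, 11, 2)],
            site_charges=[(0.0, 60.0 * k, 2.0) for k in range(6)],
            site_radius=8.0,
        )
        model = build_charge_radius_model(make_toy_channel(spec))
        grid = solve_poisson(model, spacing=1.0, padding=8.0)
        z, u_pos = barrier_from_grid(grid, +1.0, radius=6.0)
        _, u_neg = barrier_from_grid(grid, -1.0, radius=6.0)
        np.testing.assert_allclose(u_neg, -u_pos, atol=1e-12)
        assert u_pos[np.argmin(np.abs(z))] == pytest.approx(u_pos.max())
        assert u_pos.max() > 0
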
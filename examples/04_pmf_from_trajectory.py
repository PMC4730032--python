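"""Recover a potential of mean force by Boltzmann inversion.

Simulates non-interacting K+ ions in a cylinder with a known 3 kT Gaussian
barrier using the Metropolis-adjusted sampler (whose stationary density is
exactly Boltzmann), bins the axial density in 5 A slabs inside a 7 A
cylinder, and inverts PMF(Z) = -kT ln(rho(Z)/rho_bulk).
"""

import numpy as np

import gapstat as g

true_barrier = g.gaussian_barrier(3.0, sigma=5.0)
spec = g.LangevinSpec(
    potential=true_barrier,
    species={"K": (100, 1.0)},
    half_length=82.5,
    n_steps=40000,
    record_interval=50,
    seed=1,
)
traj = g.simulate_ion_trajectory(spec)
print(f"simulated {traj.n_frames} frames of {spec.species['K'][0]} K+ ions")

density = g.axial_density(traj, "K", radius=7.0, dz=5.0, z_range=(-82.5, 82.5))
pmf = g.pmf_from_density(density, bulk_half_length=60.0)

print(f"{'z (A)':>7} {'count':>7} {'PMF (kT)':>9} {'true U (kT)':>12}")
for z, c, p in zip(pmf.z_bin_centers, pmf.counts, pmf.pmf):
    if abs(z) <= 20:
        print(f"{z:7.1f} {int(c):7d} {p:9.2f} {true_barrier(z):12.2f}")

recovered = float(np.nanmax(pmf.pmf))
print(f"\nrecovered barrier height: {recovered:.2f} kT (true 3.00 kT)")
print("The inversion reproduces the input potential to within sampling "
      "noise; in the full pipeline the barrier comes from the channel's own "
      "electrostatic field instead of a prescribed function.")
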
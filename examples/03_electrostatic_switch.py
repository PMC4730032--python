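"""The electrostatic switch: surface potential with and without bound Ca2+.

Solves the two-dielectric Poisson equation (protein eps = 4, solvent
eps = 78.5, formal charges only) for the toy channel in both charge states
and maps the potential onto the pore-lining surface.  With the +2 metals the
pore lining turns almost entirely positive; without them the acidic site
rings dominate and the lining is negative there.
"""

import numpy as np

import gapstat as g

channel = g.make_gjc_like_channel()
axis, origin = g.determine_axis(channel)

for label, with_ca in (("Ca2+-bound", True), ("Ca2+-free ", False)):
    model = g.build_charge_radius_model(channel, include_metal_charges=with_ca)
    grid = g.solve_poisson(model, spacing=1.5, padding=8.0)
    surface = g.surface_potential_map(grid, model, axis=axis, origin=origin,
                                      pore_radius=12.0)
    stats = g.pore_positive_fraction(surface)
    print(f"{label}: net charge {model.total_charge:+5.0f} e | "
          f"pore-lining positive fraction {stats['fraction_positive']:.2f} | "
          f"mean potential {stats['mean']:+.1f} kT/e")

    zb, ub = g.barrier_from_grid(grid, probe_charge=+1.0, radius=7.0)
    print(f"            peak cation barrier along the axis: {ub.max():.1f} kT")

print()
print("Binding +2 ions at the twelve sites flips the pore lining from "
      "negative to almost entirely positive — a barrier for cations without "
      "any change in pore radius.")
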
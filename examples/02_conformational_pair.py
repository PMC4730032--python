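"""Quantify conformational differences between two channel states.

Creates a metal-free copy of the toy channel whose E47-like side chains are
swung 100 degrees away from the coordinating pose and whose wall near the
channel centre is pushed 0.8 A outward, then recovers exactly those numbers
with the superposition machinery — the same operations one would run on a
Ca2+-bound / Ca2+-free crystal-structure pair.
"""

import gapstat as g

bound = g.make_gjc_like_channel()
free = g.perturb_structure(
    g.make_gjc_like_channel(include_metals=False),
    [
        (
            {"chain_id": c, "residue_number": 47, "atom_name": ["CD", "OE1", "OE2"]},
            {"rotate": {"about": (c, 47, "CB"), "axis": (0, 0, 1), "angle_deg": 100}},
        )
        for c in "ABCDEFGHIJKL"
    ]
    + [({"residue_number": [229, 230, 231]}, {"radial": 0.8})],
)

sup = g.superpose(free, bound, selection=None)
print(f"global RMSD:            {sup.rmsd:.2f} A over {sup.n_pairs} matched atoms")

dev = g.per_residue_deviation(sup)
worst = dev.loc[dev["deviation"].idxmax()]
print(f"largest deviation:      {worst['deviation']:.2f} A at "
      f"{worst['chain_id']}/{worst['residue_name']}{worst['residue_number']} "
      f"(the swung glutamate)")

disp, ang = g.sidechain_displacement(sup, free, bound, "A", 47, "CD")
print(f"E47-like CD:            moves {disp:.2f} A, swings {ang:.0f} deg")

axis, origin = g.determine_axis(bound)
shift = g.radial_backbone_shift(sup, free, bound, axis, origin, (229, 231))
print(f"radial backbone shift:  {shift:+.2f} A (positive = away from the pore)")
print()
print("The global structure is nearly unchanged while the binding-site side "
      "chains rearrange locally — the signature of a non-steric mechanism.")
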
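# gapstat

Structural and computational analysis of gap junction channels — the
machinery needed to establish an *electrostatic* (rather than steric)
mechanism for divalent-cation block of an intercellular channel.

Gap junction channels are dodecamers: two hexameric hemichannels (connexons)
from apposed cells dock to form a continuous aqueous pore ~120 Å long.
Elevated Ca²⁺ — the hallmark of tissue injury — closes these channels, yet
crystal structures of the Ca²⁺-bound and Ca²⁺-free states are nearly
identical, with the same ~15 Å limiting pore diameter.  The resolution of
this paradox is electrostatic: Ca²⁺ ions chelated at inter-subunit sites
flip the pore-lining surface potential to strongly positive, erecting a
free-energy barrier that excludes cations without ever constricting the
pore.  `gapstat` implements every quantitative step of that argument:

- **metal-site analysis** — geometric detection of coordination sites,
  coordination number, formal site charge, bidentate carboxylates, and
  classification against ideal polyhedra (square pyramid, octahedron, …) by
  exhaustive vertex assignment;
- **pore geometry** — symmetry-axis determination from the inertia tensor,
  slab-wise radius profiles *r*(Z), limiting diameter, cross-lumen atom-pair
  distances, site-ring metrics (adjacent separation / rotation), and
  hydrated-ion clearance checks;
- **paired-structure comparison** — least-squares (Kabsch) superposition,
  per-residue deviations, side-chain displacement/swing angles, and signed
  radial backbone shifts;
- **continuum electrostatics** — a finite-difference variable-dielectric
  Poisson solver, −∇·(ε(r)∇φ(r)) = ρ(r) with ε = 4 inside the protein's
  van der Waals envelope and 78.5 in solvent, formal charges only
  (Glu/Asp −1, Lys/Arg +1, Ca²⁺ +2), validated against the Coulomb and
  dielectric-sphere closed forms;
- **ion statistics** — axial densities in a fixed-radius cylinder
  (7 Å, ΔZ = 5 Å), potentials of mean force by Boltzmann inversion
  PMF(Z) = −kT ln(⟨ρ(Z)⟩/ρ_bulk) zeroed in bulk, pore occupancy time
  series, and metal-coordination time series under a strict < 2.6 Å
  criterion;
- **synthetic data** — deterministic generators for ring channels with
  chelated sites, perturbed structure pairs with known ground truth, and
  Metropolis-sampled ion trajectories whose stationary density is *exactly*
  Boltzmann in a prescribed 1D potential — the oracle against which the PMF
  machinery is tested.

Structures are read from PDB or mmCIF via [gemmi]; everything downstream
works equally on deposited coordinates or on the synthetic systems.

## Worked example

```sh
python examples/01_metal_sites_and_pore.py
```

prints, for the synthetic two-hemichannel channel:

```
metal sites found:          12  (6 per hemichannel ring)
coordination number:        5
mean metal-O distance:      2.60 A
site formal charge:         -2 e  (two carboxylates)
geometry class:             square_pyramidal (angular RMSD 0.00 deg)
bidentate carboxylates:     ['GLU47', 'GLU42']
ring at z =  -28.0 A: 6 sites, adjacent separation 11.5 A at 60 deg
ring at z =  +28.0 A: 6 sites, adjacent separation 11.5 A at 60 deg
cross-lumen site distance:  23.0 A
opposing NZ-NZ distance:    15.0 A  (limiting constriction)
limiting pore diameter:     12.1 A at z = -40 A
hydrated-ion clearance:     pass (margin 5.5 A vs a 6.6 A hydrated K+)
```

Each site is a Ca²⁺ ion held by five oxygens — a glycine backbone carbonyl
and two bidentate glutamate carboxylates contributed by *adjacent* subunits
— in square-pyramidal geometry with a −2 formal site charge.  The narrowest
point of the pore (15 Å between opposing lysine NZ atoms) comfortably passes
a fully hydrated K⁺ ion (6.6 Å), so any conduction block must come from
something other than geometry.  `examples/03_electrostatic_switch.py` shows
what: adding the +2 metal charges flips the pore-lining surface potential
from 7% to 93% positive and raises the cation barrier from 3.6 to 10.2 kT,
and `examples/04_pmf_from_trajectory.py` closes the loop by recovering a
known 3 kT barrier from simulated ion densities (2.79 kT at this sampling).

The same analyses are scriptable from a shell (`gapstat info|sites|pore|
compare|electro|synth|run`) and as one orchestrated pipeline:

```sh
gapstat run --seed 1        # writes report.json + per-stage CSVs
```

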
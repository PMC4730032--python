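# Methods

This note records the models, conventions and numerical choices behind each
analysis stage, what the synthetic systems do and do not emulate, and the
known limitations.

## Structure model and crystallographic conventions

Structures are parsed with gemmi and held as a flat, ordered list of atoms
(author residue numbering, coordinates in the deposited orthogonal Å frame —
nothing is re-originated on read; pore-axis alignment is an explicit step).
Alternate locations are resolved at parse time: the highest-occupancy
conformer wins, ties broken by altloc letter order.  Biological assemblies
are generated only from operators found in the file's assembly records or
supplied by the caller — never inferred from the space group — and each
operator is checked to be a proper rotation (det = +1).

The Matthews coefficient is V_cell/(Z·n·MW) and the solvent fraction
1 − 1.230/V_m, using the conventional 1.230 Å³/Da protein partial specific
volume (recorded in the output metadata).

## Metal sites

Site discovery is geometric: every protein O/N atom (optionally water O)
within a cutoff of a metal is a ligand.  Two cutoffs coexist deliberately:

- **2.9 Å** (default) for crystal-structure *discovery* — a refined
  coordination sphere with a ~2.6 Å mean distance would be truncated by a
  tighter radius;
- **2.6 Å, strict `<`** for *trajectory* coordination analysis
  (`coordination_timeseries`), where the criterion defines a per-frame
  event, not a search radius.  The comparator (strict/inclusive) is exposed
  because crystallographic geometry can sit exactly at the cutoff.

Formal site charge sums group charges of the coordinating moieties —
carboxylate −1 counted once per residue even when bidentate, carbonyls,
amides and waters 0 — and excludes the metal itself.  Geometry is classified
by assigning the observed metal→ligand unit vectors to the vertices of each
ideal polyhedron of matching CN (tetrahedron; square pyramid and trigonal
bipyramid; octahedron), minimising the RMS angular deviation over all vertex
permutations with an optimal rotation (Kabsch on unit vectors) per
permutation; CN ≤ 6 keeps the enumeration exact.  Sites whose best RMSD
exceeds 20° are "irregular" — the threshold cleanly separates
ideal-minus-one-vertex cases (RMSD 0) from random arrangements.

Buried interface areas use an in-package Shrake–Rupley sampler: 960
golden-spiral points per atom on the probe-inflated sphere (probe 1.4 Å),
buried area = (SASA(A) + SASA(B) − SASA(A∪B))/2.  It is cross-checked in the
tests against the analytic two-sphere cap formula and against biotite's
independent implementation.

Polar contacts are distance-only (salt bridge ≤ 4.0 Å between charged-group
heavy atoms, hydrogen bond ≤ 3.5 Å between N/O pairs): crystallographic
models at modest resolution carry no hydrogens, so no angular term is
defensible.

## Pore geometry

The pore axis is the non-degenerate principal axis of the Cα (or all-atom)
inertia tensor — for an n-fold symmetric ring (n ≥ 3) two principal moments
are equal and the symmetry axis carries the third — oriented deterministically
toward the terminal reference atom of the first chain.  The origin is the
centre of mass, which for a docked two-hemichannel channel lies on the
inter-hemichannel midplane.

The radius profile is slab-wise: at each ΔZ = 1 Å slab (half-open
membership, with 10⁻⁹ Å epsilon guards so rigid-body transforms cannot flip
bin assignments), radius = min(distance from axis − vdW radius), floored
at 0; atom-free slabs are "open" (NaN) and excluded from the limiting-diameter
search.  This is deliberately *not* a rolling-sphere (HOLE-style) search: the
headline limiting diameter of a channel is an atom-pair distance, which
`cross_pore_distance` reproduces exactly (opposing pairs = those whose
azimuthal separation is closest to 180°); the slab minimum is reported
separately.  vdW radii come from the electrostatics class table for
consistency.  Clearance checks span |Z| ≤ 60 Å, half the 120 Å
cytoplasm-to-cytoplasm channel length.

## Paired-structure comparison

Atoms are paired by identity — same (chain, residue number, atom name) in
both states, i.e. the intersection of modelled ranges — and superposed by the
least-squares Kabsch rotation (SVD with a determinant correction).  The
global figure is the RMSD over all matched Cα; "average RMSD" is ambiguous
between that and a mean of per-chain RMSDs, so the per-residue table is
returned alongside and either statistic can be formed.  Side-chain swings are
measured as the angle between pivot→atom vectors of the two states (pivot CB,
falling back to CA), displacement as the post-superposition distance.  Radial
backbone shifts are signed (positive = away from the pore axis), averaged
over N/CA/C/O in the requested residue range.

## Electrostatics

The model is the classical two-dielectric continuum: ε = 4 at grid nodes
inside any atom's vdW sphere, ε = 78.5 outside; charges are *formal* only —
Glu/Asp −1 split over the two carboxylate oxygens, Lys +1 on NZ, Arg +1
split over NH1/NH2, Ca²⁺ +2 — spread trilinearly onto nodes.  Zero ionic
strength: the equation solved is pure Poisson, −∇·(ε∇φ) = ρ, with no
screening term.  Full force-field partial charges are intentionally omitted:
the ionizable groups carry the signal the analysis rests on, and the
qualitative pore-potential contrast is the scientific surface.

Discretisation: 7-point finite differences with harmonic averaging of ε on
faces; Dirichlet boundary values from the Coulomb monopole sum in ε_out;
Jacobi-preconditioned conjugate gradients to a 10⁻⁶ relative residual
(non-convergence raises, reporting the residual).  Defaults: spacing 1.0 Å
(1.5 Å in the pipeline, chosen as the coarsest grid whose pore-lining mean
potential is converged to within the refinement-test tolerance), padding
15 Å, T = 298.15 K for the kT/e conversion.  φ is reported in kT/e, so a
unit charge in a uniform dielectric gives φ = C·q/(εr) with
C = e²/(4πε₀k_BT) ≈ 560.3 Å at 298.15 K.  Validation: Coulomb to < 3%
(5–15 grid spacings from the charge) and the dielectric-sphere (Born)
closed form to < 5% exterior and interior.

The radius table is class-based: C 1.700, N 1.447 (nitro 1.763, never
triggered by standard residues), carbonyl O 1.542, hydroxyl O 1.500,
disulfide S 1.491 (detected by SG–SG pairs < 2.3 Å), thiol S 1.812,
Ca²⁺ 1.650 Å.  Oxygens outside the listed classes default to carbonyl,
nitrogens to plain N.  Waters are excluded by default (including them was
reported not to change surface potentials in this system class; the flag
exists).

Surface potentials are sampled on the vdW envelope (points on each atom's
sphere kept when outside every other atom's sphere — an approximation of the
solvent-excluded surface adequate for fraction/mean statistics), φ
interpolated trilinearly.  Points are `pore_lining` when within the pore
envelope (local pore radius + 2 Å) and |Z| ≤ 60 Å.  A finite-difference grid
replaces boundary-element solvers here; grid and boundary-element surfaces
are known to agree essentially exactly for this model class, and the
linearity, sign-flip and refinement invariants are enforced by tests instead.

## Ion statistics

Ions are counted in a fixed-radius cylinder (default 7 Å, the minimum
channel radius at the constriction) in non-overlapping ΔZ = 5 Å bins
(half-open).  Density is counts/(n_frames·πr²ΔZ) — an exact integer
identity enforced by test.  The PMF is the Boltzmann inversion
−kT ln(⟨ρ(Z)⟩/ρ_bulk) with ρ_bulk the mean over bulk bins (|Z| > 60 Å by
default) and the profile re-zeroed over those bins.  Zero-count bins get a
censored lower bound from a half-count pseudo-count and are flagged — never
an infinite value.  Trajectories are plain extended XYZ
(`<species> <x> <y> <z>` per ion, count + `t=<ns>` headers) so any engine's
output can be converted; the simulation default temperature is 310 K.

## Synthetic systems: what they emulate, what they do not

`make_gjc_like_channel` builds a docked two-hemichannel pseudo-atom channel:
120 Å long, six-fold symmetric, with six chelated Ca²⁺ sites per hemichannel
on a circle of radius 11.5 Å at Z = ±28 Å (each site shared between adjacent
subunit chains: G45 carbonyl + bidentate E47 from one chain, bidentate E42
from the next, all at 2.6 Å in ideal square-pyramidal geometry, site charge
−2), plus a lysine-like NZ ring of radius 7.5 Å marking the 15 Å limiting
constriction.  These defaults *are* the study conditions — coordination
distance, site placement and ring symmetry are fixed by the system the
package analyses, not tuned.  Two caveats are intrinsic to the idealisation:
the in-ring site separation equals the ring radius (11.5 Å here, since a
hexagon chord at 60° equals the circle radius), and the equatorial O–O
spacing of an ideal square pyramid is wider than a real carboxylate bite;
neither affects any operation's contract.

The ion simulator is non-interacting particles in a prescribed 1D potential
U(Z) (per unit charge; each species feels q·U) inside a hard reflective
cylinder.  Metropolis mode — Gaussian proposals (1.5 Å), acceptance
min(1, e^(−ΔU/kT)), wall moves rejected — has *exactly* the Boltzmann
stationary law, which is the module's central guarantee and is verified by a
chi-square goodness-of-fit test on near-independent frames.  Euler–Maruyama
mode exists for overdamped-dynamics realism but is not used for acceptance
statistics.  What the generator does not emulate: explicit solvent,
ion–ion interactions, 3D forces, finite ion size, electrodiffusion.  Passing
tests therefore demonstrate the correctness of the *statistical machinery*
(densities, inversion, occupancy bookkeeping) and the *self-consistency* of
the electrostatics→barrier→exclusion chain, not force-field-level realism of
any particular channel.

Two equilibration considerations surfaced during development and are worth
knowing.  First, ions are initialised uniformly, not from the Boltzmann law,
so analyses discard an initial burn-in block of frames.  Second, the full
two-ring channel's paired ~10 kT barriers enclose a metastable pocket:
initially uniform ions inside it cannot reach equilibrium in feasible wall
time (escape time ~e^(10)).  The ion-exclusion demonstration therefore uses a
single-site-ring channel, whose lone central barrier equilibrates by simple
repulsion; the two-ring channel is retained for all geometric and
surface-potential quantities.  With the full-domain partition-function
normalisation included in the prediction, the simulated K⁺ occupancy
reduction brackets the Boltzmann expectation within ~±30% across seeds.

## Problem sizes and reproducibility

The pipeline and acceptance script run on the synthetic systems at: grid
spacing 1.0–1.5 Å (10⁵–10⁶ nodes per solve), 80–200 ions per species,
3–8·10⁴ Metropolis steps recorded every 50, 5 Å PMF bins over a ±82.5 Å
cylinder.  All randomness flows from a single integer seed
(`numpy.random.default_rng`); fixed seeds make trajectories bitwise
reproducible and pipeline CSVs byte-identical across reruns.  The pipeline
report is validated against a JSON schema shipped with the package.

## Known limitations

- The slab-based radius profile underestimates the radius in slabs whose
  nearest atom is off-plane; the atom-pair constriction distance is the
  canonical figure.
- The vdW-surface point sampling is not a true solvent-excluded surface;
  crevice points unreachable by a 1.4 Å probe can be included.
- Pure Poisson (no ionic screening) overstates long-range tails at
  physiological ionic strength; the monopole tail of the charged toy channel
  is visible in its barrier profiles.
- The Poisson solver's accuracy degrades within ~1 grid spacing of the
  dielectric boundary; closed-form agreement is asserted away from it.
- Real deposited structures carry disorder, partial occupancies and missing
  loops that the synthetic systems do not reproduce; operations that depend
  on modelled-range intersections (superposition pairing) handle this by
  construction, but the numerical agreement shown on synthetic pairs does
  not certify values on any particular deposited model.
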
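"""Synthetic study systems with known ground truth.

Three generators cover every analysis stage without any external input:

* :func:`make_toy_channel` — pseudo-atom ring channels with exact n-fold
  symmetry about Z, emulating a docked two-hemichannel architecture
  (default: 120 A end to end, charged sites at +-28 A on the pore axis);
* :func:`perturb_structure` — structure pairs differing by prescribed
  side-chain/backbone displacements, the ground truth for superposition
  metrics;
* :func:`simulate_ion_trajectory` — equilibrium ion trajectories in a known
  1D potential confined to a cylinder.  In Metropolis mode the stationary
  density is exactly proportional to exp(-q U(z)/kT), which is the module's
  central guarantee and what the Boltzmann-inversion PMF machinery is tested
  against.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .ionstats import IonTrajectory
from .structure import Atom, Structure

__all__ = [
    "ToyChannelSpec",
    "LangevinSpec",
    "make_toy_channel",
    "make_coordination_site",
    "make_gjc_like_channel",
    "perturb_structure",
    "simulate_ion_trajectory",
    "barrier_from_grid",
    "gaussian_barrier",
]

_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWX"


@dataclass
class ToyChannelSpec:
    """Blueprint of an n-fold symmetric pseudo-atom channel.

    ``rings`` is a list of (z, radius) wall rings; each ring carries
    ``n_fold`` carbon pseudo-atoms, one per subunit chain.  ``site_charges``
    places hetero calcium-like sites at (z, azimuth_deg, charge) on a circle
    of ``site_radius``.  Defaults mimic a gap junction channel: half-length
    60 A and site rings at +-28 A.
    """

    n_fold: int = 6
    rings: Sequence[tuple[float, float]] = ()
    site_charges: Sequence[tuple[float, float, float]] = ()
    site_radius: float = 11.5
    half_length: float = 60.0
    element: str = "C"
    azimuth_offset_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.n_fold < 3:
            raise ValueError("n_fold must be >= 3")
        if not self.rings:
            # a plain cylindrical wall: rings every 2 A along the full length,
            # radius tapering from 25 A at the mouths to 10 A mid-channel
            zz = np.arange(-self.half_length, self.half_length + 1e-9, 2.0)
            self.rings = [
                (float(z), 10.0 + 15.0 * (abs(z) / self.half_length) ** 2) for z in zz
            ]
        if any(r <= 0 for _, r in self.rings):
            raise ValueError("ring radii must be positive")


def default_gjc_spec() -> ToyChannelSpec:
    """A docked two-hemichannel toy: 120 A long, six +2 sites at z = +-28 A."""
    sites = [(z, 60.0 * k, 2.0) for z in (-28.0, 28.0) for k in range(6)]
    return ToyChannelSpec(site_charges=sites)


def make_toy_channel(spec: ToyChannelSpec) -> Structure:
    """Build the pseudo-atom channel described by ``spec`` (deterministic)."""
    atoms: list[Atom] = []
    serial = 0
    for ring_idx, (z, radius) in enumerate(spec.rings):
        for k in range(spec.n_fold):
            phi = math.radians(spec.azimuth_offset_deg + 360.0 * k / spec.n_fold)
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name="C",
                    element=spec.element,
                    residue_name="DUM",
                    residue_number=201 + ring_idx,
                    chain_id=_CHAIN_LETTERS[k % len(_CHAIN_LETTERS)],
                    position=np.array(
                        [radius * math.cos(phi), radius * math.sin(phi), z]
                    ),
                )
            )
    for site_idx, (z, azim, charge) in enumerate(spec.site_charges):
        phi = math.radians(azim)
        serial += 1
        atoms.append(
            Atom(
                serial=serial,
                name="CA",
                element="CA",
                residue_name="CA",
                residue_number=1000 + site_idx,
                chain_id="X",
                position=np.array(
                    [spec.site_radius * math.cos(phi), spec.site_radius * math.sin(phi), z]
                ),
                is_hetero=True,
                formal_charge=charge,
            )
        )
    return Structure(atoms, id="toy_channel")


def make_coordination_site(
    center: np.ndarray,
    distance: float = 2.6,
    apical: np.ndarray = (0.0, 0.0, 1.0),
    equatorial_ref: np.ndarray = (1.0, 0.0, 0.0),
    chain_a: str = "A",
    chain_b: str = "B",
    serial_start: int = 1,
    metal_resnum: int = 1001,
    with_carbons: bool = True,
) -> list[Atom]:
    """A chelated five-coordinate metal site with ideal square-pyramidal geometry.

    The metal is a Ca2+ hetero atom at ``center``; the five oxygen ligands sit
    at ``distance`` from it: a glycine backbone carbonyl (G45 O of ``chain_a``)
    on the apical vertex and two bidentate glutamate carboxylates on the four
    equatorial vertices — E47 OE1/OE2 of ``chain_a`` and E42 OE1/OE2 of the
    adjacent subunit ``chain_b``.  The formal site charge is therefore -2 and
    both carboxylates are bidentate with identical metal-oxygen distances,
    emulating an inter-subunit calcium site of a connexin channel.
    """
    c = np.asarray(center, dtype=float)
    n = np.asarray(apical, dtype=float)
    n = n / np.linalg.norm(n)
    e1 = np.asarray(equatorial_ref, dtype=float)
    e1 = e1 - (e1 @ n) * n
    if np.linalg.norm(e1) < 1e-9:
        e1 = np.array([0.0, 1.0, 0.0]) - (np.array([0.0, 1.0, 0.0]) @ n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    d = distance
    serial = serial_start
    atoms: list[Atom] = []

    def add(name, element, resname, resnum, chain, pos, hetero=False, q=None):
        nonlocal serial
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_number=resnum,
                chain_id=chain,
                position=np.asarray(pos, dtype=float),
                is_hetero=hetero,
                formal_charge=q,
            )
        )
        serial += 1

    add("CA", "CA", "CA", metal_resnum, "X", c, hetero=True, q=2.0)
    add("O", "O", "GLY", 45, chain_a, c + d * n)
    add("OE1", "O", "GLU", 47, chain_a, c + d * e1)
    add("OE2", "O", "GLU", 47, chain_a, c + d * e2)
    add("OE1", "O", "GLU", 42, chain_b, c - d * e1)
    add("OE2", "O", "GLU", 42, chain_b, c - d * e2)
    if with_carbons:
        u47 = (e1 + e2) / np.linalg.norm(e1 + e2)
        u42 = -u47
        cd47 = c + (d + 0.8) * u47
        cd42 = c + (d + 0.8) * u42
        add("CD", "C", "GLU", 47, chain_a, cd47)
        add("CB", "C", "GLU", 47, chain_a, cd47 + 1.5 * u47)
        add("CD", "C", "GLU", 42, chain_b, cd42)
        add("CB", "C", "GLU", 42, chain_b, cd42 + 1.5 * u42)
    return atoms


def make_gjc_like_channel(
    n_fold: int = 6,
    site_radius: float = 11.5,
    site_z: Sequence[float] = (-28.0, 28.0),
    coordination_distance: float = 2.6,
    include_metals: bool = True,
    wall: bool = True,
    half_length: float = 60.0,
    lysine_ring_radius: float = 7.5,
    lysine_ring_z: Sequence[float] = (-40.0, 40.0),
) -> Structure:
    """A docked two-hemichannel toy channel with chelated Ca2+ site rings.

    Each hemichannel carries ``n_fold`` square-pyramidal coordination sites on
    a circle of ``site_radius`` at the given axial positions, every site
    shared between adjacent subunit chains (upper hemichannel chains A..,
    lower chains continue the alphabet).  With the default six-fold symmetry
    the in-ring chord between adjacent sites equals ``site_radius`` and the
    cross-lumen diameter is ``2 * site_radius``.  A lysine-like NZ ring at
    ``lysine_ring_radius`` marks the limiting constriction: opposing NZ-NZ
    distance is ``2 * lysine_ring_radius``.
    """
    atoms: list[Atom] = []
    if wall:
        base = make_toy_channel(ToyChannelSpec(n_fold=n_fold, half_length=half_length))
        atoms.extend(base.atoms)
        # lower hemichannel wall gets its own chain letters
        for a in atoms:
            if a.position[2] < 0:
                a.chain_id = _CHAIN_LETTERS[
                    n_fold + _CHAIN_LETTERS.index(a.chain_id)
                ]
    serial = len(atoms) + 1
    for z in lysine_ring_z:
        offset = 0 if z >= 0 else n_fold
        for k in range(n_fold):
            phi = math.radians(360.0 * k / n_fold)
            atoms.append(
                Atom(
                    serial=serial,
                    name="NZ",
                    element="N",
                    residue_name="LYS",
                    residue_number=41,
                    chain_id=_CHAIN_LETTERS[offset + k],
                    position=np.array(
                        [
                            lysine_ring_radius * math.cos(phi),
                            lysine_ring_radius * math.sin(phi),
                            z,
                        ]
                    ),
                )
            )
            serial += 1
    for ring_idx, z in enumerate(site_z):
        offset = 0 if z >= 0 else n_fold
        apical = np.array([0.0, 0.0, 1.0 if z >= 0 else -1.0])
        for k in range(n_fold):
            phi = math.radians(360.0 * k / n_fold)
            center = np.array(
                [site_radius * math.cos(phi), site_radius * math.sin(phi), z]
            )
            radial = np.array([math.cos(phi), math.sin(phi), 0.0])
            site_atoms = make_coordination_site(
                center,
                distance=coordination_distance,
                apical=apical,
                equatorial_ref=radial,
                chain_a=_CHAIN_LETTERS[offset + k],
                chain_b=_CHAIN_LETTERS[offset + (k + 1) % n_fold],
                serial_start=serial,
                metal_resnum=1001 + ring_idx * n_fold + k,
            )
            if not include_metals:
                site_atoms = [a for a in site_atoms if not a.is_hetero]
            serial += len(site_atoms)
            atoms.extend(site_atoms)
    # renumber serials to keep them unique and ordered
    for i, a in enumerate(atoms, start=1):
        a.serial = i
    return Structure(atoms, id="gjc_toy")


def perturb_structure(s: Structure, edits: Sequence[tuple[dict, dict]]) -> Structure:
    """Return an edited copy of ``s``; untouched atoms are bitwise unchanged.

    Each edit is ``(selection, action)``.  ``selection`` is a keyword dict for
    :meth:`Structure.select`; ``action`` is one of
    ``{"translate": (dx, dy, dz)}``,
    ``{"rotate": {"about": (chain, resnum, atom_name), "axis": v, "angle_deg": a}}``
    or ``{"radial": dr}`` which pushes each selected atom ``dr`` Angstrom away
    from the laboratory Z axis (negative values pull inward).
    """
    out = s.copy()
    for selection, action in edits:
        targets = out.select(**selection)
        if not targets:
            raise ValueError(f"selection {selection!r} matched no atoms")
        if "translate" in action:
            vec = np.asarray(action["translate"], dtype=float)
            for a in targets:
                a.position = a.position + vec
        elif "radial" in action:
            dr = float(action["radial"])
            for a in targets:
                rho = math.hypot(a.position[0], a.position[1])
                if rho < 1e-12:
                    raise ValueError("radial edit undefined for on-axis atom")
                scale = (rho + dr) / rho
                a.position = np.array(
                    [a.position[0] * scale, a.position[1] * scale, a.position[2]]
                )
        elif "rotate" in action:
            rot_spec = action["rotate"]
            pivot = out.find_atom(*rot_spec["about"]).position.copy()
            axis = np.asarray(rot_spec["axis"], dtype=float)
            axis = axis / np.linalg.norm(axis)
            theta = math.radians(rot_spec["angle_deg"])
            k = axis
            kmat = np.array(
                [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
            )
            rot = np.eye(3) + math.sin(theta) * kmat + (1 - math.cos(theta)) * kmat @ kmat
            for a in targets:
                a.position = rot @ (a.position - pivot) + pivot
        else:
            raise ValueError(f"unknown edit action {action!r}")
    return out


def gaussian_barrier(height_kt: float, sigma: float = 5.0, center: float = 0.0) -> Callable:
    """A Gaussian potential barrier U(z) in kT for a +1 test charge."""

    def u(z):
        z = np.asarray(z, dtype=float)
        return height_kt * np.exp(-0.5 * ((z - center) / sigma) ** 2)

    return u


@dataclass
class LangevinSpec:
    """Conditions for an equilibrium ion simulation in a 1D potential.

    ``potential`` maps z (A) to the energy in kT of a *unit positive* charge;
    each species feels ``charge * potential``.  The volume is a cylinder of
    ``cylinder_radius`` with reflective walls and |z| <= ``half_length``.
    ``species`` maps a name to (n_ions, charge).  In ``metropolis`` mode the
    move set is a Gaussian proposal accepted by the Metropolis rule, so the
    stationary law is exactly Boltzmann; ``euler`` mode is plain overdamped
    Euler-Maruyama.
    """

    potential: Callable
    cylinder_radius: float = 7.0
    half_length: float = 80.0
    species: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"K": (60, 1.0), "CL": (60, -1.0)}
    )
    step_scale: float = 1.5  # A, proposal/diffusion step
    n_steps: int = 20000
    record_interval: int = 50
    seed: int = 0
    temperature: float = 310.0
    mode: str = "metropolis"


def simulate_ion_trajectory(spec: LangevinSpec) -> IonTrajectory:
    """Simulate non-interacting ions in U(z) inside a reflective cylinder.

    Returns recorded frames every ``record_interval`` steps.  Warns when the
    Metropolis acceptance rate drops below 50% (step too large).
    """
    rng = np.random.default_rng(spec.seed)
    R, L = spec.cylinder_radius, spec.half_length
    frames: list[dict[str, np.ndarray]] = []
    state: dict[str, np.ndarray] = {}
    charges: dict[str, float] = {}
    for name, (n, q) in spec.species.items():
        # uniform initial fill of the cylinder
        r = R * np.sqrt(rng.random(n))
        phi = 2 * math.pi * rng.random(n)
        z = rng.uniform(-L, L, n)
        state[name] = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
        charges[name] = q

    def energy(name: str, xyz: np.ndarray) -> np.ndarray:
        return charges[name] * np.asarray(spec.potential(xyz[:, 2]), dtype=float)

    accepted = 0
    proposed = 0
    for step in range(spec.n_steps):
        for name, xyz in state.items():
            if spec.mode == "metropolis":
                trial = xyz + rng.normal(scale=spec.step_scale, size=xyz.shape)
                inside = (np.hypot(trial[:, 0], trial[:, 1]) <= R) & (
                    np.abs(trial[:, 2]) <= L
                )
                du = energy(name, trial) - energy(name, xyz)
                accept = inside & (np.log(rng.random(len(xyz))) < -du)
                xyz[accept] = trial[accept]
                accepted += int(accept.sum())
                proposed += len(xyz)
            elif spec.mode == "euler":
                # overdamped Euler-Maruyama with numerical gradient of U
                h = 1e-3
                z = xyz[:, 2]
                grad = (
                    charges[name]
                    * (np.asarray(spec.potential(z + h)) - np.asarray(spec.potential(z - h)))
                    / (2 * h)
                )
                dt = spec.step_scale**2 / 2.0  # so sqrt(2 D dt) = step_scale, D = 1
                disp = rng.normal(scale=spec.step_scale, size=xyz.shape)
                disp[:, 2] -= grad * dt
                trial = xyz + disp
                # reflective boundaries
                trial[:, 2] = np.clip(trial[:, 2], -2 * L, 2 * L)
                over = np.abs(trial[:, 2]) > L
                trial[over, 2] = np.sign(trial[over, 2]) * (2 * L) - trial[over, 2]
                rho = np.hypot(trial[:, 0], trial[:, 1])
                out = rho > R
                if out.any():
                    scale = (2 * R - rho[out]) / rho[out]
                    trial[out, 0] *= scale
                    trial[out, 1] *= scale
                xyz[:] = trial
            else:
                raise ValueError(f"unknown mode {spec.mode!r}")
        if (step + 1) % spec.record_interval == 0:
            frames.append({name: xyz.copy() for name, xyz in state.items()})
    if spec.mode == "metropolis" and proposed and accepted / proposed < 0.5:
        warnings.warn(
            f"Metropolis acceptance {accepted / proposed:.2f} < 0.5; "
            "consider a smaller step_scale",
            stacklevel=2,
        )
    return IonTrajectory(frames, frame_interval=0.1)


def barrier_from_grid(grid, probe_charge: float, radius: float = 7.0,
                      dz: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Axial potential energy U(z) (kT) of a probe ion from a solved grid.

    U(z) = probe_charge x mean phi over the in-cylinder disc at each z plane
    (grid z axis = channel axis).  Links the Poisson stage to the ion
    simulation: solve the channel's field, extract the barrier, then simulate
    permeation in it.
    """
    if grid.phi is None:
        raise RuntimeError("grid not solved")
    ax, ay, az = grid.axes()
    # channel frame: x/y centred on the grid centre
    cx, cy = ax.mean(), ay.mean()
    xx, yy = np.meshgrid(ax - cx, ay - cy, indexing="ij")
    disc = np.hypot(xx, yy) <= radius
    phi_z = np.array([grid.phi[:, :, k][disc].mean() for k in range(grid.dims[2])])
    zc = az - az.mean()
    # coarse-grain to dz bins for a smooth table
    n = max(1, int(round(dz / grid.spacing)))
    m = len(zc) // n
    z_table = zc[: m * n].reshape(m, n).mean(axis=1)
    u_table = probe_charge * phi_z[: m * n].reshape(m, n).mean(axis=1)
    return z_table, u_table
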
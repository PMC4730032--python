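"""Pore axis determination, radius profiles and binding-site ring metrics.

The pore radius at an axial slab is defined as the smallest (distance from
axis minus van der Waals radius) over the atoms in the slab — a fast,
deterministic definition.  The headline "limiting diameter" of a channel is
an atom-pair distance (e.g. between NZ atoms of an opposing lysine ring),
which :func:`cross_pore_distance` reproduces exactly; the slab-profile
minimum is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure import Atom, Structure
from .params import vdw_radius

__all__ = [
    "PoreProfile",
    "determine_axis",
    "radius_profile",
    "limiting_diameter",
    "cross_pore_distance",
    "site_ring_metrics",
    "clearance_check",
]

#: default half-length of the channel used for clearance checks, Angstrom
CHANNEL_HALF_LENGTH = 60.0


@dataclass
class PoreProfile:
    """Axial grid of pore radii; ``nan`` marks open (atom-free) slabs."""

    z: np.ndarray
    radius: np.ndarray
    axis: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("z grid must be strictly increasing")
        if np.nanmin(self.radius) < 0:
            raise ValueError("radii must be non-negative")


def _axis_frame(axis: np.ndarray) -> np.ndarray:
    """Orthonormal frame with the given axis as its third row."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return np.stack([e1, e2, axis])


def to_axis_frame(coords: np.ndarray, axis: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Coordinates in a frame where the pore axis is +z through the origin."""
    frame = _axis_frame(axis)
    return (np.asarray(coords, dtype=float) - np.asarray(origin)) @ frame.T


def determine_axis(s: Structure) -> tuple[np.ndarray, np.ndarray]:
    """Pore axis and origin of an assembled ring channel.

    The axis is the unique (non-degenerate) principal axis of the inertia
    tensor of the channel's reference atoms — for an n-fold symmetric ring
    (n >= 3) two principal moments are equal and the symmetry axis carries
    the remaining one.  CA atoms are used when present, all atoms otherwise.
    The origin is the centre of mass, which for a docked two-hemichannel
    channel lies on the inter-hemichannel midplane.
    """
    if len(s.chain_ids) < 2:
        raise ValueError("structure must be an assembled channel (>= 2 chains)")
    ref = s.select(atom_name="CA", hetero=False)
    if len(ref) < 10:
        ref = [a for a in s.atoms if not a.is_hetero]
    if len(ref) < 10:
        raise ValueError("fewer than 10 reference atoms; insufficient structure")
    coords = np.stack([a.position for a in ref])
    com = coords.mean(axis=0)
    x = coords - com
    inertia = np.eye(3) * np.sum(x**2) - x.T @ x
    evals, evecs = np.linalg.eigh(inertia)
    # pick the eigenvalue most separated from the other two (symmetry axis)
    sep = [min(abs(evals[i] - evals[j]) for j in range(3) if j != i) for i in range(3)]
    k = int(np.argmax(sep))
    axis = evecs[:, k]
    # deterministic orientation: point towards the terminal CA of the first chain
    first_chain = ref[0].chain_id
    chain_atoms = [a for a in ref if a.chain_id == first_chain]
    pointer = chain_atoms[-1].position - com
    d = float(axis @ pointer)
    if abs(d) > 1e-9:
        axis = axis * math.copysign(1.0, d)
    elif axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    return axis, com


def radius_profile(
    s: Structure,
    axis: np.ndarray,
    origin: np.ndarray,
    dz: float = 1.0,
    include_hetero: bool = False,
) -> PoreProfile:
    """Slab-wise pore radius profile along the axis.

    Radius at a slab is ``min(axial distance - vdW radius)`` over atoms whose
    z lies in the half-open slab ``[z - dz/2, z + dz/2)``, floored at zero.
    Atom-free slabs are open and carry ``nan``.
    """
    if dz <= 0:
        raise ValueError("dz must be positive")
    atoms = [a for a in s.atoms if include_hetero or not a.is_hetero]
    local = to_axis_frame(np.stack([a.position for a in atoms]), axis, origin)
    rads = np.array([vdw_radius(a.element, a.name, a.residue_name) for a in atoms])
    rho = np.hypot(local[:, 0], local[:, 1]) - rads
    zmin, zmax = local[:, 2].min(), local[:, 2].max()
    # small epsilon guards keep the slab count and bin assignment stable
    # under floating-point jitter from rigid-body transforms
    n = max(1, int(math.ceil((zmax - zmin) / dz - 1e-9)))
    centers = zmin + dz * (np.arange(n) + 0.5)
    idx = np.floor((local[:, 2] - zmin) / dz + 1e-9).astype(int)
    idx = np.clip(idx, 0, n - 1)
    radius = np.full(n, np.nan)
    for i, r in zip(idx, rho):
        if np.isnan(radius[i]) or r < radius[i]:
            radius[i] = r
    radius = np.where(np.isnan(radius), np.nan, np.maximum(radius, 0.0))
    axis = np.asarray(axis, dtype=float)
    return PoreProfile(centers, radius, axis / np.linalg.norm(axis), np.asarray(origin, float))


def limiting_diameter(
    profile: PoreProfile, z_range: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Minimum pore diameter ``2*r`` and its axial location within ``z_range``."""
    if z_range is None:
        mask = np.ones_like(profile.z, dtype=bool)
    else:
        lo, hi = z_range
        mask = (profile.z >= lo) & (profile.z <= hi)
    mask &= ~np.isnan(profile.radius)
    if not mask.any():
        raise ValueError("no closed slabs in the requested z range")
    sub_r, sub_z = profile.radius[mask], profile.z[mask]
    k = int(np.argmin(sub_r))
    return 2.0 * float(sub_r[k]), float(sub_z[k])


@dataclass
class CrossPoreDistances:
    distances: np.ndarray  # all pairwise distances
    min: float
    max: float
    opposing: float  # mean distance over most-nearly-antiparallel pairs
    n_atoms: int


def cross_pore_distance(
    s: Structure,
    residue_number: int,
    atom_name: str,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    chain_ids: list[str] | None = None,
    element: str | None = None,
    z_range: tuple[float, float] | None = None,
) -> CrossPoreDistances:
    """Pairwise distances between copies of a named atom around the ring.

    Reports min/max over all pairs and the mean over "opposing" pairs —
    those whose azimuthal separation about the pore axis is closest to 180
    degrees.  Works equally for hetero atoms (pass ``element`` to select e.g.
    all Ca ions regardless of residue numbering); ``z_range`` (axis frame)
    restricts the selection to one ring of a multi-ring assembly.
    """
    if element is not None:
        atoms = s.select(element=element)
    else:
        atoms = s.select(residue_number=residue_number, atom_name=atom_name)
    if chain_ids is not None:
        atoms = [a for a in atoms if a.chain_id in chain_ids]
    if len(atoms) < 2:
        raise ValueError("named atom present in fewer than 2 chains")
    if axis is None or origin is None:
        axis, origin = determine_axis(s)
    coords = np.stack([a.position for a in atoms])
    local = to_axis_frame(coords, axis, origin)
    if z_range is not None:
        keep = (local[:, 2] >= z_range[0]) & (local[:, 2] <= z_range[1])
        if keep.sum() < 2:
            raise ValueError("fewer than 2 selected atoms in z_range")
        atoms = [a for a, k in zip(atoms, keep) if k]
        coords, local = coords[keep], local[keep]
    azim = np.arctan2(local[:, 1], local[:, 0])
    n = len(atoms)
    dists, gaps = [], []
    for i in range(n):
        for j in range(i + 1, n):
            dists.append(float(np.linalg.norm(coords[i] - coords[j])))
            dphi = abs((azim[i] - azim[j] + math.pi) % (2 * math.pi) - math.pi)
            gaps.append(abs(dphi - math.pi))
    dists, gaps = np.array(dists), np.array(gaps)
    opp = dists[gaps <= gaps.min() + 1e-9]
    return CrossPoreDistances(
        distances=dists,
        min=float(dists.min()),
        max=float(dists.max()),
        opposing=float(opp.mean()),
        n_atoms=n,
    )


def site_ring_metrics(
    sites: list,
    axis: np.ndarray,
    origin: np.ndarray,
    ring_gap: float = 10.0,
) -> list[dict]:
    """Group metal sites into axial rings and report in-ring geometry.

    Sites whose axial coordinates differ by less than ``ring_gap`` belong to
    the same ring.  Within a ring, sites are sorted by azimuth; adjacent
    separation is the Euclidean metal-metal distance between consecutive
    sites (wrapping), rotation is the azimuthal increment in degrees.
    """
    if not sites:
        return []
    metals = np.stack([st.metal.position for st in sites])
    local = to_axis_frame(metals, axis, origin)
    order = np.argsort(local[:, 2])
    rings: list[list[int]] = [[int(order[0])]]
    for k in order[1:]:
        if local[k, 2] - local[rings[-1][-1], 2] < ring_gap:
            rings[-1].append(int(k))
        else:
            rings.append([int(k)])
    out = []
    for members in rings:
        sub = local[members]
        azim = np.degrees(np.arctan2(sub[:, 1], sub[:, 0]))
        ring_order = np.argsort(azim)
        members = [members[i] for i in ring_order]
        azim = azim[ring_order]
        seps, rots = [], []
        m = len(members)
        if m >= 2:
            for i in range(m):
                j = (i + 1) % m
                seps.append(float(np.linalg.norm(metals[members[i]] - metals[members[j]])))
                rots.append(float((azim[j] - azim[i]) % 360.0))
        out.append(
            {
                "site_indices": members,
                "n_sites": m,
                "axial_position": float(local[members, 2].mean()),
                "adjacent_separation": seps,
                "adjacent_rotation_deg": rots,
                "mean_separation": float(np.mean(seps)) if seps else float("nan"),
                "mean_rotation_deg": float(np.mean(rots)) if rots else float("nan"),
            }
        )
    return out


def clearance_check(
    profile: PoreProfile,
    probe_diameter: float,
    z_range: tuple[float, float] = (-CHANNEL_HALF_LENGTH, CHANNEL_HALF_LENGTH),
) -> tuple[bool, float]:
    """Whether a probe of the given diameter clears the channel everywhere.

    Returns ``(passes, margin)`` with ``margin = min(2*radius) - probe`` over
    closed slabs within ``z_range``.
    """
    if probe_diameter <= 0:
        raise ValueError("probe_diameter must be positive")
    dmin, _ = limiting_diameter(profile, z_range)
    margin = dmin - probe_diameter
    return margin >= 0.0, margin
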
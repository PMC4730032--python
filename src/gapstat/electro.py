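"""Two-dielectric Poisson electrostatics on a regular grid.

The physical model is the classical continuum picture: the protein interior
is a low-dielectric region (eps = 4) bounded by its van der Waals envelope,
bulk solvent is high-dielectric (eps = 78.5), and the potential solves

    -div( eps(r) grad phi(r) ) = 4 pi C rho(r)

with formal charges only (carboxylates -1, Lys/Arg +1, Ca2+ +2) spread
trilinearly onto grid nodes.  ``C = e^2 / (4 pi eps0 kB T)`` expressed in
Angstrom converts the solution to units of kT/e: a unit charge in a uniform
dielectric then produces ``phi = C q / (eps r)``.  Zero ionic strength —
pure Poisson, no screening term.

The discretisation is a 7-point finite-difference stencil with harmonic
averaging of eps on cell faces, Dirichlet boundary values from the Coulomb
monopole sum in the solvent dielectric, and a conjugate-gradient solve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import cg
from scipy.ndimage import map_coordinates
from scipy.spatial import cKDTree

from .params import formal_charge_of_atom, vdw_radius
from .structure import Structure

__all__ = [
    "ChargeRadiusModel",
    "PotentialGrid",
    "SurfacePotential",
    "build_charge_radius_model",
    "solve_poisson",
    "surface_potential_map",
    "pore_positive_fraction",
    "coulomb_constant",
    "write_dx",
]

EPS_IN_DEFAULT = 4.0
EPS_OUT_DEFAULT = 78.5
TEMPERATURE_DEFAULT = 298.15

# e^2 / (4 pi eps0 kB) in Angstrom * Kelvin
_COULOMB_ANGSTROM_KELVIN = 1.671009e5


def coulomb_constant(temperature: float = TEMPERATURE_DEFAULT) -> float:
    """``e^2/(4 pi eps0 kB T)`` in Angstrom; ~560.3 A at 298.15 K."""
    return _COULOMB_ANGSTROM_KELVIN / temperature


@dataclass
class ChargeRadiusModel:
    """Per-atom formal charges (e) and class-based vdW radii (A)."""

    coords: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    provenance: list[str]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())


def build_charge_radius_model(
    s: Structure,
    include_metal_charges: bool = True,
    include_waters: bool = False,
) -> ChargeRadiusModel:
    """Assign formal charges and class radii to every heavy atom.

    Glu/Asp carboxylates carry -1 split over the two oxygens, Lys +1 on NZ,
    Arg +1 split over NH1/NH2, Ca2+ ions +2 when ``include_metal_charges``.
    Waters are excluded by default; hydrogens are never expected (heavy-atom
    crystallographic models).  Disulfide sulfurs are detected by SG-SG pairs
    within 2.3 A and get the smaller disulfide radius.
    """
    water = {"HOH", "WAT", "H2O"}
    atoms = [
        a
        for a in s.atoms
        if a.element.upper() != "H"
        and (include_waters or a.residue_name.upper() not in water)
    ]
    # disulfide detection
    sg = [i for i, a in enumerate(atoms) if a.name.upper() == "SG"]
    disulfide: set[int] = set()
    if len(sg) > 1:
        pos = np.stack([atoms[i].position for i in sg])
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(2.3):
            disulfide.update((sg[i], sg[j]))
    coords, charges, radii, prov = [], [], [], []
    for i, a in enumerate(atoms):
        q = formal_charge_of_atom(a, include_metal_charges)
        r = vdw_radius(a.element, a.name, a.residue_name, disulfide=i in disulfide)
        coords.append(a.position)
        charges.append(q)
        radii.append(r)
        prov.append("formal" if q else "neutral")
    return ChargeRadiusModel(np.stack(coords), np.array(charges), np.array(radii), prov)


@dataclass
class PotentialGrid:
    """Regular grid holding eps(r), charge and the solved potential phi(r).

    ``phi`` is node-centred, in kT/e at the solve temperature; ``epsilon`` is
    node-centred too (face values are the harmonic means of the nodes they
    join).
    """

    origin: np.ndarray
    spacing: float
    dims: tuple[int, int, int]
    epsilon: np.ndarray
    charge: np.ndarray
    phi: np.ndarray | None = None
    temperature: float = TEMPERATURE_DEFAULT
    eps_out: float = EPS_OUT_DEFAULT
    metadata: dict = field(default_factory=dict)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        )

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation of phi at Cartesian points."""
        if self.phi is None:
            raise RuntimeError("grid not solved yet")
        pts = (np.asarray(points, dtype=float) - self.origin) / self.spacing
        return map_coordinates(self.phi, pts.T, order=1, mode="nearest")


class ConvergenceError(RuntimeError):
    pass


def _spread_charges(model: ChargeRadiusModel, origin, spacing, dims) -> np.ndarray:
    grid = np.zeros(dims)
    frac = (model.coords - origin) / spacing
    base = np.floor(frac).astype(int)
    t = frac - base
    for (i, j, k), (tx, ty, tz), q in zip(base, t, model.charges):
        if q == 0.0:
            continue
        for di, wx in ((0, 1 - tx), (1, tx)):
            for dj, wy in ((0, 1 - ty), (1, ty)):
                for dk, wz in ((0, 1 - tz), (1, tz)):
                    ii, jj, kk = i + di, j + dj, k + dk
                    if 0 <= ii < dims[0] and 0 <= jj < dims[1] and 0 <= kk < dims[2]:
                        grid[ii, jj, kk] += q * wx * wy * wz
    return grid


def solve_poisson(
    model: ChargeRadiusModel,
    spacing: float = 1.0,
    padding: float = 15.0,
    eps_in: float = EPS_IN_DEFAULT,
    eps_out: float = EPS_OUT_DEFAULT,
    temperature: float = TEMPERATURE_DEFAULT,
    rtol: float = 1e-6,
    max_iter: int = 20000,
) -> PotentialGrid:
    """Solve the variable-dielectric Poisson equation on a regular grid.

    Nodes inside any atom's vdW sphere take ``eps_in``; everything else is
    ``eps_out``.  Boundary nodes are Dirichlet-pinned to the Coulomb monopole
    sum in the outer dielectric.  Raises :class:`ConvergenceError` if the CG
    iteration fails to reach the residual tolerance.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    lo = model.coords.min(axis=0) - padding
    hi = model.coords.max(axis=0) + padding
    dims = tuple(int(math.ceil((hi[k] - lo[k]) / spacing)) + 1 for k in range(3))
    origin = lo

    # dielectric map: nodes inside any vdW sphere get eps_in; each atom stamps
    # its own bounding box, which is fast and exact for node-in-sphere tests
    eps = np.full(dims, eps_out)
    axes = [origin[k] + spacing * np.arange(dims[k]) for k in range(3)]
    inside = np.zeros(dims, dtype=bool)
    for pos, rad in zip(model.coords, model.radii):
        lo_idx = np.maximum(0, np.ceil((pos - rad - origin) / spacing).astype(int))
        hi_idx = np.minimum(
            np.array(dims) - 1, np.floor((pos + rad - origin) / spacing).astype(int)
        )
        if np.any(lo_idx > hi_idx):
            continue
        ax = axes[0][lo_idx[0] : hi_idx[0] + 1] - pos[0]
        ay = axes[1][lo_idx[1] : hi_idx[1] + 1] - pos[1]
        az = axes[2][lo_idx[2] : hi_idx[2] + 1] - pos[2]
        d2 = ax[:, None, None] ** 2 + ay[None, :, None] ** 2 + az[None, None, :] ** 2
        inside[
            lo_idx[0] : hi_idx[0] + 1,
            lo_idx[1] : hi_idx[1] + 1,
            lo_idx[2] : hi_idx[2] + 1,
        ] |= d2 <= rad * rad
    eps[inside] = eps_in

    q_grid = _spread_charges(model, origin, spacing, dims)
    C = coulomb_constant(temperature)

    # Dirichlet boundary: Coulomb sum in eps_out
    phi = np.zeros(dims)
    boundary = np.zeros(dims, dtype=bool)
    boundary[0, :, :] = boundary[-1, :, :] = True
    boundary[:, 0, :] = boundary[:, -1, :] = True
    boundary[:, :, 0] = boundary[:, :, -1] = True
    b_idx = np.argwhere(boundary)
    bpts = origin[None, :] + spacing * b_idx
    charged = model.charges != 0
    if charged.any():
        qc = model.charges[charged]
        pc = model.coords[charged]
        d = np.sqrt(np.maximum(1e-6, ((bpts[:, None, :] - pc[None, :, :]) ** 2).sum(-1)))
        phi[boundary] = (C / eps_out) * (qc[None, :] / d).sum(axis=1)

    nx, ny, nz = dims
    idx = np.arange(nx * ny * nz).reshape(dims)
    interior = ~boundary
    n_int = int(interior.sum())
    renum = -np.ones(nx * ny * nz, dtype=int)
    renum[idx[interior]] = np.arange(n_int)

    def harm(e1, e2):
        return 2.0 * e1 * e2 / (e1 + e2)

    rows, cols, vals = [], [], []
    b = np.zeros(n_int)
    ii, jj, kk = np.nonzero(interior)
    diag = np.zeros(n_int)
    b += 4.0 * math.pi * C * q_grid[interior] / spacing
    neighbours = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]
    eq = np.arange(n_int)
    for di, dj, dk in neighbours:
        ni, nj, nk = ii + di, jj + dj, kk + dk
        ef = harm(eps[ii, jj, kk], eps[ni, nj, nk])
        diag += ef
        nb_flat = idx[ni, nj, nk]
        nb_renum = renum[nb_flat]
        is_int = nb_renum >= 0
        rows.extend(eq[is_int])
        cols.extend(nb_renum[is_int])
        vals.extend(-ef[is_int])
        # boundary neighbour: move known phi to the right-hand side
        bmask = ~is_int
        if bmask.any():
            b[eq[bmask]] += ef[bmask] * phi[ni[bmask], nj[bmask], nk[bmask]]
    rows.extend(eq)
    cols.extend(eq)
    vals.extend(diag)
    a_mat = sparse.csr_matrix((vals, (rows, cols)), shape=(n_int, n_int))

    inv_diag = 1.0 / diag
    precon = sparse.diags(inv_diag)
    x0 = np.full(n_int, float(np.mean(phi[boundary])))
    sol, info = cg(a_mat, b, x0=x0, rtol=rtol, maxiter=max_iter, M=precon)
    if info != 0:
        resid = np.linalg.norm(a_mat @ sol - b) / max(np.linalg.norm(b), 1e-30)
        raise ConvergenceError(
            f"Poisson CG failed to converge (info={info}, rel residual={resid:.2e})"
        )
    phi[interior] = sol
    return PotentialGrid(
        origin=np.asarray(origin, float),
        spacing=spacing,
        dims=dims,
        epsilon=eps,
        charge=q_grid,
        phi=phi,
        temperature=temperature,
        eps_out=eps_out,
        metadata={
            "eps_in": eps_in,
            "eps_out": eps_out,
            "temperature_K": temperature,
            "coulomb_constant_A": C,
            "units": "kT/e",
        },
    )


@dataclass
class SurfacePotential:
    points: np.ndarray  # (N, 3)
    potential: np.ndarray  # kT/e
    region: np.ndarray  # array of {pore_lining, exterior, gap}

    def __post_init__(self) -> None:
        if len(self.points) != len(self.potential) or len(self.points) != len(self.region):
            raise ValueError("points, potential and region must be parallel")


def surface_potential_map(
    grid: PotentialGrid,
    model: ChargeRadiusModel,
    probe: float = 1.4,
    n_points: int = 120,
    axis: np.ndarray | None = None,
    origin: np.ndarray | None = None,
    pore_radius: float | None = None,
    half_length: float = 60.0,
    gap_half_width: float = 10.0,
) -> SurfacePotential:
    """Sample phi on the molecular envelope and label pore-lining points.

    Surface points are taken on each atom's vdW sphere and kept when exposed
    (outside every other atom's vdW-plus-probe shell shrunk back to vdW) —
    a vdW-surface approximation of the solvent-excluded envelope.  A point is
    ``pore_lining`` when its radial distance from the axis is within the pore
    envelope (``pore_radius`` + 2 A) and |z| <= ``half_length``; exterior
    points within the extracellular-gap band are labelled ``gap``.
    """
    if grid.phi is None:
        raise RuntimeError("grid must be solved before surface mapping")
    from .params import golden_spiral_points

    sphere = golden_spiral_points(n_points)
    tree = cKDTree(model.coords)
    rmax = model.radii.max()
    pts_out = []
    for i in range(len(model.coords)):
        pts = model.coords[i] + model.radii[i] * sphere
        nbrs = [j for j in tree.query_ball_point(model.coords[i], model.radii[i] + rmax) if j != i]
        keep = np.ones(len(pts), dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - model.coords[j]) ** 2, axis=1)
            keep &= d2 > model.radii[j] ** 2
        pts_out.append(pts[keep])
    points = np.vstack(pts_out)
    potential = grid.interpolate(points)

    if axis is None:
        axis = np.array([0.0, 0.0, 1.0])
    if origin is None:
        origin = model.coords.mean(axis=0)
    from .pore import to_axis_frame

    local = to_axis_frame(points, axis, origin)
    rho = np.hypot(local[:, 0], local[:, 1])
    if pore_radius is None:
        # envelope from the innermost surface points near the axis
        pore_radius = float(np.percentile(rho, 10))
    in_pore = (rho <= pore_radius + 2.0) & (np.abs(local[:, 2]) <= half_length)
    in_gap = (~in_pore) & (np.abs(local[:, 2]) <= gap_half_width)
    region = np.where(in_pore, "pore_lining", np.where(in_gap, "gap", "exterior"))
    return SurfacePotential(points, potential, region)


def pore_positive_fraction(sp: SurfacePotential) -> dict:
    """Fraction of pore-lining surface with phi > 0, plus summary stats."""
    mask = sp.region == "pore_lining"
    if not mask.any():
        raise ValueError("surface has no pore-lining points")
    phi = sp.potential[mask]
    return {
        "fraction_positive": float(np.mean(phi > 0)),
        "mean": float(phi.mean()),
        "min": float(phi.min()),
        "max": float(phi.max()),
        "n_points": int(mask.sum()),
    }


def write_dx(grid: PotentialGrid, path) -> None:
    """Write the solved potential as an OpenDX scalar grid."""
    if grid.phi is None:
        raise RuntimeError("grid not solved")
    nx, ny, nz = grid.dims
    with open(path, "w") as fh:
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {grid.spacing:.6f} 0 0\n")
        fh.write(f"delta 0 {grid.spacing:.6f} 0\n")
        fh.write(f"delta 0 0 {grid.spacing:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {nx * ny * nz} data follows\n"
        )
        flat = grid.phi.ravel()
        for i in range(0, len(flat), 3):
            fh.write(" ".join(f"{v:.6e}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "potential (kT/e)" class field\n')
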
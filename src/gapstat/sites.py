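"""Metal-coordination sites, polar contacts and buried interface areas.

A metal site is detected geometrically: every protein oxygen/nitrogen within
a cutoff of the metal is a candidate ligand.  The default discovery cutoff is
2.9 A — wide enough that a refined coordination sphere with a ~2.6 A mean
distance is captured in full; trajectory-based coordination analysis (in
:mod:`gapstat.ionstats`) uses the stricter 2.6 A criterion instead.

Coordination geometry is classified by exhaustive assignment of the observed
metal->ligand unit vectors to the vertices of ideal polyhedra (tetrahedron,
trigonal bipyramid, square pyramid, octahedron), minimising the RMS angular
deviation over all vertex permutations and rigid rotations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .params import ACIDIC_OXYGENS, golden_spiral_points, residue_group_charge, vdw_radius
from .structure import Atom, Structure

__all__ = [
    "MetalSite",
    "Contact",
    "find_metal_sites",
    "site_formal_charge",
    "classify_site_geometry",
    "detect_bidentate",
    "find_polar_contacts",
    "interface_area",
    "shrake_rupley_sasa",
]

GEOMETRY_CLASSES = (
    "tetrahedral",
    "square_pyramidal",
    "trigonal_bipyramidal",
    "octahedral",
    "irregular",
)

#: angular-RMSD threshold (degrees) beyond which a site is "irregular"
IRREGULAR_THRESHOLD_DEG = 20.0


@dataclass
class MetalSite:
    """A bound metal with its coordinating protein atoms."""

    metal: Atom
    ligand_atoms: list[Atom]
    distances: list[float]
    cn: int = 0
    formal_charge: int = 0
    geometry_class: str = "irregular"
    geometry_rmsd_deg: float = float("nan")
    subunits_involved: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if len(self.ligand_atoms) != len(self.distances):
            raise ValueError("ligand_atoms and distances must be parallel")
        self.cn = len(self.ligand_atoms)
        self.subunits_involved = frozenset(a.chain_id for a in self.ligand_atoms)

    @property
    def mean_distance(self) -> float:
        return float(np.mean(self.distances)) if self.distances else float("nan")


@dataclass(frozen=True)
class Contact:
    atom_a: Atom
    atom_b: Atom
    distance: float
    kind: str  # salt_bridge | hydrogen_bond | vdw
    scope: str  # intrasubunit | intersubunit | interhemichannel


def find_metal_sites(
    s: Structure,
    metal_elements: set[str] | frozenset[str] = frozenset({"CA"}),
    cutoff: float = 2.9,
    include_water: bool = False,
) -> list[MetalSite]:
    """One :class:`MetalSite` per metal atom with >= 1 ligand within ``cutoff``.

    Ligands are protein O/N atoms (plus water oxygens when requested), sorted
    by distance.  Metals with no ligand in range are dropped, not an error.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    metals = [a for a in s.atoms if a.element.upper() in {m.upper() for m in metal_elements}]
    water = {"HOH", "WAT", "H2O"}
    candidates = []
    for a in s.atoms:
        if a in metals:
            continue
        if a.residue_name.upper() in water:
            if include_water and a.element.upper() == "O":
                candidates.append(a)
            continue
        if not a.is_hetero and a.element.upper() in ("O", "N"):
            candidates.append(a)
    if not candidates:
        return []
    tree = cKDTree(np.stack([a.position for a in candidates]))
    sites = []
    for metal in metals:
        idx = tree.query_ball_point(metal.position, cutoff)
        if not idx:
            continue
        ligs = [candidates[i] for i in idx]
        dists = [float(np.linalg.norm(l.position - metal.position)) for l in ligs]
        order = np.argsort(dists)
        ligs = [ligs[i] for i in order]
        dists = [dists[i] for i in order]
        site = MetalSite(metal=metal, ligand_atoms=ligs, distances=dists)
        site.formal_charge = site_formal_charge(site)
        if site.cn in (4, 5, 6):
            site.geometry_class, site.geometry_rmsd_deg = classify_site_geometry(site)
        sites.append(site)
    return sites


def site_formal_charge(site: MetalSite) -> int:
    """Sum of formal group charges of the coordinating moieties.

    A carboxylate counts once per residue even when both oxygens coordinate
    (bidentate); backbone carbonyls, amide groups and waters are neutral.
    The metal's own charge is not included.
    """
    total = 0.0
    counted: set[tuple[str, int]] = set()
    for a in site.ligand_atoms:
        res = a.residue_name.upper()
        key = (a.chain_id, a.residue_number)
        if res in ACIDIC_OXYGENS:
            # only the side-chain oxygens carry the group charge; a backbone
            # O of Glu/Asp coordinating alone contributes nothing
            if a.name.upper() in ACIDIC_OXYGENS[res]:
                if key not in counted:
                    total += -1.0
                    counted.add(key)
        elif res in ("LYS", "ARG", "HIS"):
            if a.name.upper() in ("NZ", "NH1", "NH2", "NE", "ND1", "NE2"):
                if key not in counted:
                    total += 1.0
                    counted.add(key)
        else:
            total += residue_group_charge(res) if key not in counted else 0.0
            counted.add(key)
    return int(round(total))


def _ideal_templates(cn: int) -> dict[str, np.ndarray]:
    s3 = math.sqrt(3.0)
    if cn == 4:
        return {
            "tetrahedral": np.array(
                [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
            )
            / s3
        }
    if cn == 5:
        eq = [[1, 0, 0], [0, 1, 0], [-1, 0, 0], [0, -1, 0]]
        tbp_eq = [
            [1, 0, 0],
            [-0.5, s3 / 2, 0],
            [-0.5, -s3 / 2, 0],
        ]
        return {
            "square_pyramidal": np.array([[0, 0, 1]] + eq, dtype=float),
            "trigonal_bipyramidal": np.array(
                [[0, 0, 1], [0, 0, -1]] + tbp_eq, dtype=float
            ),
        }
    if cn == 6:
        return {
            "octahedral": np.array(
                [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
                dtype=float,
            )
        }
    raise ValueError(f"geometry classification supports CN in 4..6, got {cn}")


def _kabsch_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising ||b - a @ R.T|| (rows are vectors)."""
    h = a.T @ b
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _angular_rmsd(template: np.ndarray, observed: np.ndarray) -> float:
    """Min-over-permutations RMS angle (deg) between matched unit vectors."""
    n = len(template)
    best = math.inf
    for perm in itertools.permutations(range(n)):
        t = template[list(perm)]
        rot = _kabsch_rotation(t, observed)
        aligned = t @ rot.T
        cosang = np.clip(np.sum(aligned * observed, axis=1), -1.0, 1.0)
        ang = np.degrees(np.arccos(cosang))
        rms = math.sqrt(float(np.mean(ang**2)))
        if rms < best:
            best = rms
    return best


def classify_site_geometry(site: MetalSite) -> tuple[str, float]:
    """Best-matching ideal polyhedron and its angular RMSD in degrees."""
    vecs = np.stack([a.position - site.metal.position for a in site.ligand_atoms])
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("ligand coincides with metal position")
    unit = vecs / norms[:, None]
    best_class, best_rmsd = "irregular", math.inf
    for name, template in _ideal_templates(site.cn).items():
        rmsd = _angular_rmsd(template, unit)
        if rmsd < best_rmsd:
            best_class, best_rmsd = name, rmsd
    if best_rmsd > IRREGULAR_THRESHOLD_DEG:
        return "irregular", best_rmsd
    return best_class, best_rmsd


def detect_bidentate(site: MetalSite) -> list[dict]:
    """Residues whose carboxylate donates both oxygens to the metal.

    Each entry reports the residue identity, the two metal-oxygen distances
    and their absolute difference.
    """
    by_res: dict[tuple[str, int, str], dict[str, float]] = {}
    for a, d in zip(site.ligand_atoms, site.distances):
        res = a.residue_name.upper()
        if res in ACIDIC_OXYGENS and a.name.upper() in ACIDIC_OXYGENS[res]:
            by_res.setdefault((a.chain_id, a.residue_number, res), {})[a.name.upper()] = d
    out = []
    for (chain, num, res), dd in sorted(by_res.items()):
        if len(dd) == 2:
            d1, d2 = sorted(dd.values())
            out.append(
                {
                    "chain_id": chain,
                    "residue_number": num,
                    "residue_name": res,
                    "distances": (d1, d2),
                    "difference": d2 - d1,
                }
            )
    return out


# charged-group heavy atoms for salt-bridge detection
_NEGATIVE = {("GLU", "OE1"), ("GLU", "OE2"), ("ASP", "OD1"), ("ASP", "OD2")}
_POSITIVE = {("LYS", "NZ"), ("ARG", "NH1"), ("ARG", "NH2"), ("ARG", "NE"),
             ("HIS", "ND1"), ("HIS", "NE2")}


def find_polar_contacts(
    s: Structure,
    salt_bridge_cutoff: float = 4.0,
    hbond_cutoff: float = 3.5,
    chain_groups: dict[str, int] | None = None,
) -> list[Contact]:
    """Salt bridges and hydrogen bonds between polar heavy atoms.

    No hydrogen positions are assumed (crystal structures at this resolution
    carry none), so hydrogen bonds are distance-only N/O pairs.  ``chain_groups``
    optionally maps chain ids to hemichannel indices so contacts can be
    labelled ``interhemichannel``; without it, any cross-chain contact is
    ``intersubunit``.
    """
    if salt_bridge_cutoff <= 0 or hbond_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    polar = [a for a in s.atoms if not a.is_hetero and a.element.upper() in ("O", "N")]
    if not polar:
        return []
    coords = np.stack([a.position for a in polar])
    tree = cKDTree(coords)
    maxcut = max(salt_bridge_cutoff, hbond_cutoff)
    pairs = tree.query_pairs(maxcut)
    contacts = []
    for i, j in sorted(pairs):
        a, b = polar[i], polar[j]
        if a.chain_id == b.chain_id and a.residue_number == b.residue_number:
            continue
        # exclude trivially bonded neighbours along the backbone
        if (
            a.chain_id == b.chain_id
            and abs(a.residue_number - b.residue_number) == 1
            and {a.name, b.name} <= {"N", "O", "C"}
        ):
            continue
        d = float(np.linalg.norm(a.position - b.position))
        key_a = (a.residue_name.upper(), a.name.upper())
        key_b = (b.residue_name.upper(), b.name.upper())
        charged_pair = (key_a in _NEGATIVE and key_b in _POSITIVE) or (
            key_a in _POSITIVE and key_b in _NEGATIVE
        )
        if charged_pair and d <= salt_bridge_cutoff:
            kind = "salt_bridge"
        elif d <= hbond_cutoff:
            kind = "hydrogen_bond"
        else:
            continue
        if a.chain_id == b.chain_id:
            scope = "intrasubunit"
        elif chain_groups and chain_groups.get(a.chain_id) != chain_groups.get(b.chain_id):
            scope = "interhemichannel"
        else:
            scope = "intersubunit"
        contacts.append(Contact(a, b, d, kind, scope))
    return contacts


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), rolling-probe sampling.

    Each atom's accessible sphere (radius ``r_i + probe``) is sampled with
    ``n_points`` golden-spiral points; a point is accessible when it lies
    outside every neighbour's accessible sphere.
    """
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe
    n = len(coords)
    if n == 0:
        return np.zeros(0)
    sphere = golden_spiral_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(n)
    rmax = radii.max()
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        nbrs = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbrs:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > radii[j] ** 2
        areas[i] = 4.0 * math.pi * radii[i] ** 2 * accessible.mean()
    return areas


def _selection_radii(atoms: list[Atom]) -> np.ndarray:
    return np.array([vdw_radius(a.element, a.name, a.residue_name) for a in atoms])


def interface_area(
    s: Structure,
    group_a: list[Atom],
    group_b: list[Atom],
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Buried interface area (SASA(A) + SASA(B) - SASA(A u B)) / 2 in A^2."""
    if not group_a or not group_b:
        raise ValueError("both selections must be non-empty")
    ids_a = {id(a) for a in group_a}
    if any(id(b) in ids_a for b in group_b):
        raise ValueError("selections must be disjoint")
    ca, cb = np.stack([a.position for a in group_a]), np.stack([a.position for a in group_b])
    ra, rb = _selection_radii(group_a), _selection_radii(group_b)
    sasa_a = shrake_rupley_sasa(ca, ra, probe, n_points).sum()
    sasa_b = shrake_rupley_sasa(cb, rb, probe, n_points).sum()
    both = shrake_rupley_sasa(
        np.vstack([ca, cb]), np.concatenate([ra, rb]), probe, n_points
    ).sum()
    return max(0.0, 0.5 * (sasa_a + sasa_b - both))
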
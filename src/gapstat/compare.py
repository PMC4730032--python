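"""Superposition of paired structures and conformational-change metrics.

Atoms are paired by identity — same (chain, residue number, atom name) in
both structures — restricted to whatever is modelled in both, and the rigid
transform is the least-squares (Kabsch) optimum.  Global RMSD is the root
mean square over all matched atoms; per-chain values can be derived from the
per-residue table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pore import to_axis_frame
from .structure import Atom, Structure

__all__ = [
    "Superposition",
    "superpose",
    "per_residue_deviation",
    "sidechain_displacement",
    "radial_backbone_shift",
]


@dataclass
class Superposition:
    """Optimal rigid map ``x -> R x + t`` of mobile onto reference."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int
    pairing: list[tuple[Atom, Atom]]  # (mobile, reference)

    def __post_init__(self) -> None:
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise ValueError("rotation must be proper (det = +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def _match_atoms(
    mobile: Structure, reference: Structure, atom_names: set[str] | None
) -> list[tuple[Atom, Atom]]:
    ref_index = {
        (a.chain_id, a.residue_number, a.name): a
        for a in reference.atoms
        if not a.is_hetero
    }
    pairs = []
    for a in mobile.atoms:
        if a.is_hetero:
            continue
        if atom_names is not None and a.name not in atom_names:
            continue
        b = ref_index.get((a.chain_id, a.residue_number, a.name))
        if b is not None:
            pairs.append((a, b))
    return pairs


def superpose(
    mobile: Structure,
    reference: Structure,
    selection: str | set[str] | None = "CA",
) -> Superposition:
    """Least-squares rigid superposition of matched atoms (Kabsch).

    ``selection`` names the atom(s) used for the fit (default CA; ``None``
    uses every matched atom).  Pairing is the intersection of atoms sharing
    (chain, residue number, atom name).
    """
    if isinstance(selection, str):
        names: set[str] | None = {selection}
    else:
        names = set(selection) if selection is not None else None
    pairs = _match_atoms(mobile, reference, names)
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} matched atoms; need >= 3")
    x = np.stack([a.position for a, _ in pairs])
    y = np.stack([b.position for _, b in pairs])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    x0, y0 = x - xc, y - yc
    # collinearity check: rank of the centred mobile set
    if np.linalg.matrix_rank(x0, tol=1e-8) < 2:
        raise ValueError("matched atoms are collinear; superposition degenerate")
    h = x0.T @ y0
    u, sv, vt = np.linalg.svd(h)
    d = math.copysign(1.0, np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = yc - rot @ xc
    delta = x @ rot.T + trans - y
    rmsd = float(np.sqrt(np.mean(np.sum(delta**2, axis=1))))
    return Superposition(rot, trans, rmsd, len(pairs), pairs)


def per_residue_deviation(sup: Superposition) -> pd.DataFrame:
    """Post-superposition distance per matched atom, one row per residue/atom."""
    rows = []
    for a, b in sup.pairing:
        moved = sup.rotation @ a.position + sup.translation
        rows.append(
            {
                "chain_id": a.chain_id,
                "residue_number": a.residue_number,
                "residue_name": a.residue_name,
                "atom_name": a.name,
                "deviation": float(np.linalg.norm(moved - b.position)),
            }
        )
    return pd.DataFrame(rows)


def sidechain_displacement(
    sup: Superposition,
    mobile: Structure,
    reference: Structure,
    chain_id: str,
    residue_number: int,
    atom_name: str,
    pivot_atom: str = "CB",
) -> tuple[float, float]:
    """Displacement (A) and swing angle (deg) of one atom between states.

    Displacement is the post-superposition distance between the atom's two
    positions; the angle is between the pivot->atom vectors of the two states
    (pivot defaults to CB, falling back to CA for glycine-like residues).
    """
    try:
        a_mob = mobile.find_atom(chain_id, residue_number, atom_name)
        a_ref = reference.find_atom(chain_id, residue_number, atom_name)
    except KeyError as exc:
        raise ValueError(f"atom missing in one structure: {exc}") from exc
    moved = sup.rotation @ a_mob.position + sup.translation
    displacement = float(np.linalg.norm(moved - a_ref.position))

    def pivot(st: Structure) -> np.ndarray:
        for name in (pivot_atom, "CA"):
            try:
                return st.find_atom(chain_id, residue_number, name).position
            except KeyError:
                continue
        raise ValueError(f"no pivot atom for {chain_id}/{residue_number}")

    v_mob = sup.rotation @ (a_mob.position - pivot(mobile))
    v_ref = a_ref.position - pivot(reference)
    na, nb = np.linalg.norm(v_mob), np.linalg.norm(v_ref)
    if na == 0 or nb == 0:
        return displacement, 0.0
    cosang = float(np.clip(v_mob @ v_ref / (na * nb), -1.0, 1.0))
    return displacement, math.degrees(math.acos(cosang))


def radial_backbone_shift(
    sup: Superposition,
    mobile: Structure,
    reference: Structure,
    axis: np.ndarray,
    origin: np.ndarray,
    residue_range: tuple[int, int],
    chain_ids: list[str] | None = None,
) -> float:
    """Mean signed radial shift (mobile minus reference) of backbone atoms.

    Positive values mean the mobile state sits farther from the pore axis
    after applying the superposition.  Backbone atoms N, CA, C, O of residues
    in ``residue_range`` (inclusive) are averaged over all matched chains;
    the axis/origin refer to the reference frame.
    """
    lo, hi = residue_range
    backbone = {"N", "CA", "C", "O"}
    pairs = _match_atoms(mobile, reference, backbone)
    shifts = []
    for a, b in pairs:
        if not (lo <= a.residue_number <= hi):
            continue
        if chain_ids is not None and a.chain_id not in chain_ids:
            continue
        moved = sup.rotation @ a.position + sup.translation
        loc_m = to_axis_frame(moved[None, :], axis, origin)[0]
        loc_r = to_axis_frame(b.position[None, :], axis, origin)[0]
        shifts.append(math.hypot(loc_m[0], loc_m[1]) - math.hypot(loc_r[0], loc_r[1]))
    if not shifts:
        raise ValueError("no matched backbone atoms in the requested range")
    return float(np.mean(shifts))
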
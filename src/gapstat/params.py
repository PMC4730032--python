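"""Atomic parameter tables: van der Waals radii and formal group charges.

The radius table follows the class-based convention used in boundary-element
electrostatics codes: carbon 1.700 A; nitrogen 1.447 A (1.763 A in nitro
groups); carbonyl oxygen 1.542 A; hydroxyl oxygen 1.500 A; disulfide sulfur
1.491 A; thiol sulfur 1.812 A; calcium ion 1.650 A.  Atoms outside the listed
classes fall back to the class default for their element (oxygen -> carbonyl,
nitrogen -> plain nitrogen, sulfur -> thiol).

Charges are *formal* ionizable-group charges, not force-field partials:
Glu/Asp carboxylates carry -1 split over the two oxygens, Lys +1 on NZ,
Arg +1 split over NH1/NH2, Ca2+ ions +2.  Everything else is neutral.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "vdw_radius",
    "formal_charge_of_atom",
    "ACIDIC_OXYGENS",
    "BASIC_NITROGENS",
    "ParameterWarning",
]


class ParameterWarning(UserWarning):
    """Emitted when an atom falls outside the parameter tables."""


#: element fallback radii, Angstrom
ELEMENT_RADII = {
    "C": 1.700,
    "N": 1.447,
    "O": 1.542,
    "S": 1.812,
    "CA": 1.650,  # calcium ion
    "H": 1.000,
    "P": 1.800,
    "K": 1.760,
    "NA": 1.360,
    "CL": 1.810,
    "MG": 1.450,
    "ZN": 1.390,
    "SE": 1.900,
    "F": 1.470,
}

#: hydroxyl-class oxygen atom names (Ser OG, Thr OG1, Tyr OH, water O)
_HYDROXYL_O = {"OG", "OG1", "OH", "OW"}

#: carboxylate oxygen atom names per residue (bear the formal negative charge)
ACIDIC_OXYGENS = {
    "GLU": ("OE1", "OE2"),
    "ASP": ("OD1", "OD2"),
}

#: positively charged nitrogens per residue with their per-atom charge
BASIC_NITROGENS = {
    "LYS": {"NZ": 1.0},
    "ARG": {"NH1": 0.5, "NH2": 0.5},
}

_WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

_STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


def vdw_radius(element: str, atom_name: str = "", residue_name: str = "",
               disulfide: bool = False) -> float:
    """Class-aware van der Waals radius in Angstrom.

    Raises ``KeyError`` for elements absent from the table (the caller decides
    whether that is fatal; the electrostatics builder treats it as an error).
    """
    el = element.upper()
    if el == "O":
        if atom_name in _HYDROXYL_O or residue_name in _WATER_NAMES:
            return 1.500
        return 1.542
    if el == "S":
        return 1.491 if disulfide else 1.812
    if el == "N":
        # proteins contain no nitro groups; the 1.763 A class is kept for
        # completeness but never triggered by standard residues
        return 1.447
    if el in ELEMENT_RADII:
        return ELEMENT_RADII[el]
    raise KeyError(f"no van der Waals radius for element {element!r}")


def formal_charge_of_atom(atom, include_metal_charges: bool = True) -> float:
    """Formal charge (e) carried by one atom under the group-charge scheme."""
    if atom.formal_charge is not None:
        if atom.is_hetero and not include_metal_charges:
            return 0.0
        return float(atom.formal_charge)
    res = atom.residue_name.upper()
    name = atom.name.upper()
    if res in ACIDIC_OXYGENS and name in ACIDIC_OXYGENS[res]:
        return -0.5
    if res in BASIC_NITROGENS and name in BASIC_NITROGENS[res]:
        return BASIC_NITROGENS[res][name]
    if atom.element.upper() == "CA" and res in {"CA", "CA2", "ION"}:
        return 2.0 if include_metal_charges else 0.0
    return 0.0


def residue_group_charge(residue_name: str) -> float:
    """Formal side-chain group charge of a residue type (0 if unknown).

    Unknown residue types trigger a :class:`ParameterWarning` and count as
    neutral, mirroring how metal-site formal charges are accumulated.
    """
    res = residue_name.upper()
    if res in ("GLU", "ASP"):
        return -1.0
    if res in ("LYS", "ARG"):
        return 1.0
    if res in _STANDARD_RESIDUES or res in _WATER_NAMES or res == "DUM":
        return 0.0
    warnings.warn(
        f"residue {residue_name!r} has no group-charge parameters; counted as 0",
        ParameterWarning,
        stacklevel=2,
    )
    return 0.0


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` nearly uniform unit vectors on the sphere (golden-spiral layout)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
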
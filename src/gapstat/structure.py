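"""Macromolecular structure model and crystallographic utilities.

A deliberately small, array-friendly atom model sits at the centre of the
package: parsing of PDB/mmCIF is delegated to :mod:`gemmi`, after which the
structure is held as a flat, ordered list of :class:`Atom` records plus
optional crystal metadata.  Coordinates are kept in the deposited orthogonal
Angstrom frame; nothing is re-originated on read (pore-axis alignment is an
explicit step in :mod:`gapstat.pore`).

Alternate locations are resolved at parse time: the highest-occupancy
conformer wins, ties broken by altloc letter order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "CrystalCell",
    "Structure",
    "read_structure",
    "write_pdb",
    "expand_assembly",
    "assembly_ops",
    "matthews_solvent",
]

#: Partial-specific-volume convention for protein, Angstrom^3 per Dalton.
PROTEIN_VOLUME_PER_DALTON = 1.230

# chain-label pool used when symmetry expansion needs fresh identifiers
_CHAIN_POOL = "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"


@dataclass
class Atom:
    """One atom record, author numbering, coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False
    #: explicit formal charge (e); None = derive from residue/atom tables
    formal_charge: float | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.element = self.element.strip().upper()
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")
        if not self.element:
            raise ValueError(f"atom {self.name}: empty element symbol")

    def copy(self) -> "Atom":
        return replace(self, position=self.position.copy())


@dataclass(frozen=True)
class CrystalCell:
    """Unit-cell dimensions (Angstrom / degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not (0.0 < ang < 180.0):
                raise ValueError("cell angles must lie in (0, 180) degrees")

    @property
    def volume(self) -> float:
        """Triclinic cell volume in Angstrom^3."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        return (
            self.a
            * self.b
            * self.c
            * math.sqrt(max(0.0, 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg))
        )


class Structure:
    """Ordered atom collection with optional crystallographic metadata.

    Parameters
    ----------
    atoms:
        Atom records in file order.
    cell, space_group:
        Crystal metadata, if known.
    symmetry_ops:
        Optional list of ``(R, t)`` pairs (3x3 rotation, 3-vector translation)
        taken from the file's biological-assembly records.
    """

    def __init__(
        self,
        atoms: Iterable[Atom],
        cell: CrystalCell | None = None,
        space_group: str | None = None,
        symmetry_ops: list[tuple[np.ndarray, np.ndarray]] | None = None,
        id: str = "",
    ) -> None:
        self.atoms: list[Atom] = list(atoms)
        self.cell = cell
        self.space_group = space_group
        self.symmetry_ops = symmetry_ops
        self.id = id

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(N, 3) coordinate array, a fresh copy in file order."""
        if not self.atoms:
            return np.empty((0, 3))
        return np.stack([a.position for a in self.atoms])

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for atom, row in zip(self.atoms, xyz):
            atom.position = row.copy()

    @property
    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def select(
        self,
        chain_id: str | Sequence[str] | None = None,
        residue_number: int | Sequence[int] | None = None,
        residue_name: str | Sequence[str] | None = None,
        atom_name: str | Sequence[str] | None = None,
        element: str | Sequence[str] | None = None,
        hetero: bool | None = None,
    ) -> list[Atom]:
        """Return atoms matching every given criterion (None = wildcard)."""

        def as_set(x):
            if x is None:
                return None
            if isinstance(x, (str, int)):
                return {x}
            return set(x)

        chains, resnums = as_set(chain_id), as_set(residue_number)
        resnames, names, elems = as_set(residue_name), as_set(atom_name), as_set(element)
        out = []
        for a in self.atoms:
            if chains is not None and a.chain_id not in chains:
                continue
            if resnums is not None and a.residue_number not in resnums:
                continue
            if resnames is not None and a.residue_name not in resnames:
                continue
            if names is not None and a.name not in names:
                continue
            if elems is not None and a.element.upper() not in {str(e).upper() for e in elems}:
                continue
            if hetero is not None and a.is_hetero != hetero:
                continue
            out.append(a)
        return out

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if (
                a.chain_id == chain_id
                and a.residue_number == residue_number
                and a.name == atom_name
            ):
                return a
        raise KeyError(f"atom {chain_id}/{residue_number}/{atom_name} not found")

    def copy(self) -> "Structure":
        return Structure(
            [a.copy() for a in self.atoms],
            cell=self.cell,
            space_group=self.space_group,
            symmetry_ops=None if self.symmetry_ops is None else list(self.symmetry_ops),
            id=self.id,
        )


class ParseError(RuntimeError):
    """Raised when a structure file cannot be read."""


def _from_gemmi(st: gemmi.Structure) -> Structure:
    st.setup_entities()
    # altloc resolution: highest occupancy wins, ties by altloc letter
    atoms: list[Atom] = []
    model = st[0]
    serial = 0
    for chain in model:
        for res in chain:
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                prev = best.get(at.name)
                if prev is None:
                    best[at.name] = at
                elif at.occ > prev.occ or (at.occ == prev.occ and at.altloc < prev.altloc):
                    best[at.name] = at
            is_het = res.het_flag == "H"
            for at in best.values():
                serial += 1
                atoms.append(
                    Atom(
                        serial=serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(1.0, max(0.0, at.occ)),
                        b_factor=at.b_iso,
                        is_hetero=is_het,
                    )
                )
    cell = None
    if st.cell and st.cell.a > 0:
        cell = CrystalCell(
            st.cell.a, st.cell.b, st.cell.c, st.cell.alpha, st.cell.beta, st.cell.gamma
        )
    ops = assembly_ops(st)
    return Structure(
        atoms,
        cell=cell,
        space_group=st.spacegroup_hm or None,
        symmetry_ops=ops or None,
        id=st.name,
    )


def assembly_ops(st: gemmi.Structure) -> list[tuple[np.ndarray, np.ndarray]]:
    """Rotation/translation pairs of the file's first biological assembly."""
    ops: list[tuple[np.ndarray, np.ndarray]] = []
    if len(st.assemblies) == 0:
        return ops
    for gen in st.assemblies[0].generators:
        for oper in gen.operators:
            tr = oper.transform
            rot = np.array(tr.mat.tolist(), dtype=float)
            vec = np.array(tr.vec.tolist(), dtype=float)
            ops.append((rot, vec))
    return ops


def read_structure(path: str | Path, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``format`` may be ``"pdb"``, ``"mmcif"`` or ``"auto"`` (by extension).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif format == "auto":
            st = gemmi.read_structure(str(path))
        else:
            raise ValueError(f"unknown format {format!r}; expected pdb/mmcif/auto")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown format" in str(exc):
            raise
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    out = _from_gemmi(st)
    if not out.id:
        out.id = path.stem
    return out


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.id or "model"
    if s.cell is not None:
        st.cell = gemmi.UnitCell(
            s.cell.a, s.cell.b, s.cell.c, s.cell.alpha, s.cell.beta, s.cell.gamma
        )
    if s.space_group:
        st.spacegroup_hm = s.space_group
    # gemmi's add_chain/add_residue copy their argument and can invalidate
    # previously held references, so each container is built completely
    # before being inserted into its parent
    by_chain: dict[str, list[Atom]] = {}
    for a in s.atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    model = gemmi.Model("1")
    for chain_id, atoms in by_chain.items():
        chain = gemmi.Chain(chain_id)
        by_res: dict[tuple[int, str], list[Atom]] = {}
        for a in atoms:
            by_res.setdefault((a.residue_number, a.residue_name), []).append(a)
        for (resnum, resname), res_atoms in by_res.items():
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(resnum, " ")
            res.het_flag = "H" if res_atoms[0].is_hetero else "A"
            for a in res_atoms:
                at = gemmi.Atom()
                at.name = a.name
                at.element = gemmi.Element(a.element)
                at.pos = gemmi.Position(*a.position)
                at.occ = a.occupancy
                at.b_iso = a.b_factor
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_pdb(s: Structure, path: str | Path) -> None:
    """Write the structure as a fixed-column PDB file (gemmi backend)."""
    _to_gemmi(s).write_pdb(str(path))


def _validate_rotation(rot: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    rot = np.asarray(rot, dtype=float)
    if rot.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if abs(np.linalg.det(rot) - 1.0) > tol:
        raise ValueError(f"matrix is not a proper rotation (det={np.linalg.det(rot):.6f})")
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-5):
        raise ValueError("matrix is not orthogonal")
    return rot


def expand_assembly(
    s: Structure, ops: Sequence[tuple[np.ndarray, np.ndarray]]
) -> Structure:
    """Apply each (rotation, translation) op to a copy of ``s``.

    The first copy keeps the original chain identifiers; subsequent copies are
    relabelled with fresh identifiers so that every chain in the output is
    unique.  Six crystallographic ops applied to the asymmetric-unit dimer of
    a gap junction crystal yield the biological dodecamer.
    """
    if len(ops) == 0:
        raise ValueError("ops must be non-empty")
    if len(s) == 0:
        raise ValueError("structure has no coordinates")
    validated = [(_validate_rotation(r), np.asarray(t, dtype=float).reshape(3)) for r, t in ops]

    used = set(s.chain_ids)
    pool = iter(c for c in _CHAIN_POOL if c not in used)
    out_atoms: list[Atom] = []
    serial = 0
    for k, (rot, trans) in enumerate(validated):
        relabel: dict[str, str] = {}
        identity = k == 0
        for a in s.atoms:
            if identity:
                new_chain = a.chain_id
            else:
                if a.chain_id not in relabel:
                    try:
                        relabel[a.chain_id] = next(pool)
                    except StopIteration as exc:
                        raise ValueError("chain-label pool exhausted") from exc
                new_chain = relabel[a.chain_id]
            serial += 1
            new = a.copy()
            new.serial = serial
            new.chain_id = new_chain
            if not (identity and np.array_equal(rot, np.eye(3)) and not trans.any()):
                new.position = rot @ a.position + trans
            out_atoms.append(new)
    return Structure(
        out_atoms,
        cell=s.cell,
        space_group=s.space_group,
        id=f"{s.id}_assembly" if s.id else "assembly",
    )


def matthews_solvent(
    cell: CrystalCell, z_asu: int, n_per_asu: int, mw_da: float
) -> tuple[float, float]:
    """Matthews coefficient (A^3/Da) and solvent fraction of a crystal.

    ``z_asu`` is the number of asymmetric units in the cell (e.g. 18 for H32),
    ``n_per_asu`` the number of protein molecules per AU, ``mw_da`` the
    molecular weight of one molecule in Daltons.  The solvent fraction uses
    the conventional protein partial specific volume of 1.230 A^3/Da.
    """
    if z_asu <= 0 or n_per_asu <= 0 or mw_da <= 0:
        raise ValueError("z_asu, n_per_asu and mw_da must be positive")
    v_m = cell.volume / (z_asu * n_per_asu * mw_da)
    solvent = min(1.0, max(0.0, 1.0 - PROTEIN_VOLUME_PER_DALTON / v_m))
    return v_m, solvent
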
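"""Ion-trajectory statistics: axial densities, Boltzmann-inversion PMFs,
pore occupancy and metal-coordination time series.

The PMF is the standard Boltzmann inversion of an equilibrium axial density,

    PMF(Z) = -kT ln( <rho(Z)> / rho_bulk ),

with the bulk density averaged over designated bulk bins so that the PMF is
zero in bulk solvent.  Ions are counted inside a fixed-radius cylinder (the
default 7 A matches a channel's minimum pore radius) in non-overlapping bins
of width dZ = 5 A.  Bins with zero counts get a censored lower bound from a
half-count pseudo-count instead of an infinite PMF.

Trajectories are plain extended-XYZ text: a frame is an atom-count line, a
comment line ``t=<ns>``, then one ``<species> <x> <y> <z>`` line per ion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "IonTrajectory",
    "DensityProfile",
    "PMFProfile",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "axial_density",
    "pmf_from_density",
    "pore_occupancy",
    "coordination_timeseries",
]

DEFAULT_CYLINDER_RADIUS = 7.0  # A, minimum pore radius at the lysine ring
DEFAULT_DZ = 5.0  # A
BULK_HALF_LENGTH = 60.0  # |Z| beyond this is bulk solvent (120 A channel)


@dataclass
class IonTrajectory:
    """Per-frame ion coordinates by species, in the channel frame (axis = Z)."""

    frames: list[dict[str, np.ndarray]]
    frame_interval: float = 0.1  # ns
    box: tuple[float, float] | None = None  # optional (cyl radius, half length)

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("trajectory must contain at least one frame")
        for f in self.frames:
            for sp, xyz in f.items():
                xyz = np.asarray(xyz, dtype=float)
                if xyz.ndim != 2 or xyz.shape[1] != 3 or not np.all(np.isfinite(xyz)):
                    raise ValueError(f"bad coordinates for species {sp}")
                f[sp] = xyz

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.frames:
            for sp in f:
                seen.setdefault(sp, None)
        return list(seen)


def write_xyz_trajectory(traj: IonTrajectory, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, frame in enumerate(traj.frames):
            n = sum(len(v) for v in frame.values())
            fh.write(f"{n}\nt={i * traj.frame_interval:.4f}\n")
            for sp, xyz in frame.items():
                for x, y, z in xyz:
                    fh.write(f"{sp} {x:.4f} {y:.4f} {z:.4f}\n")


def read_xyz_trajectory(path: str | Path, frame_interval: float | None = None) -> IonTrajectory:
    frames: list[dict[str, np.ndarray]] = []
    times: list[float] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"bad frame header at line {i + 1}: {lines[i]!r}") from exc
        comment = lines[i + 1].strip()
        if comment.startswith("t="):
            times.append(float(comment[2:]))
        per_species: dict[str, list[list[float]]] = {}
        for k in range(n):
            parts = lines[i + 2 + k].split()
            per_species.setdefault(parts[0], []).append([float(v) for v in parts[1:4]])
        frames.append(
            {sp: np.array(rows, dtype=float).reshape(-1, 3) for sp, rows in per_species.items()}
        )
        i += 2 + n
    if frame_interval is None:
        frame_interval = times[1] - times[0] if len(times) > 1 else 0.1
    return IonTrajectory(frames, frame_interval=frame_interval)


@dataclass
class DensityProfile:
    z_bin_centers: np.ndarray
    counts: np.ndarray  # total ion-frame counts per bin
    density: np.ndarray  # ions / A^3, frame-averaged
    n_frames: int
    cylinder_radius: float
    dz: float


@dataclass
class PMFProfile:
    z_bin_centers: np.ndarray
    counts: np.ndarray
    density: np.ndarray
    pmf: np.ndarray  # kT, bulk-zeroed
    censored: np.ndarray  # bool, True where pmf is a lower bound
    bulk_density: float
    cylinder_radius: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": self.z_bin_centers,
                "count": self.counts,
                "density": self.density,
                "pmf": self.pmf,
                "censored": self.censored,
            }
        )


def axial_density(
    traj: IonTrajectory,
    species: str,
    radius: float = DEFAULT_CYLINDER_RADIUS,
    dz: float = DEFAULT_DZ,
    z_range: tuple[float, float] | None = None,
) -> DensityProfile:
    """Frame-averaged axial ion density inside a fixed-radius cylinder.

    An ion counts in bin k at a frame when its radial distance from the Z
    axis is <= ``radius`` and its z lies in the half-open bin [z_k, z_k+dz).
    Density is counts / (n_frames * pi r^2 dz).
    """
    if radius <= 0 or dz <= 0:
        raise ValueError("radius and dz must be positive")
    if z_range is None:
        zmax = 0.0
        for f in traj.frames:
            if species in f and len(f[species]):
                zmax = max(zmax, float(np.abs(f[species][:, 2]).max()))
        half = dz * math.ceil(max(zmax, dz) / dz)
        z_range = (-half, half)
    lo, hi = z_range
    n_bins = max(1, int(round((hi - lo) / dz)))
    edges = lo + dz * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for f in traj.frames:
        xyz = f.get(species)
        if xyz is None or len(xyz) == 0:
            continue
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        sel = xyz[r <= radius, 2]
        sel = sel[(sel >= lo) & (sel < edges[-1])]
        if len(sel):
            counts += np.histogram(sel, bins=edges)[0]
    volume = math.pi * radius**2 * dz
    density = counts / (traj.n_frames * volume)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(centers, counts, density, traj.n_frames, radius, dz)


def pmf_from_density(
    profile: DensityProfile,
    bulk_bins: np.ndarray | None = None,
    bulk_half_length: float = BULK_HALF_LENGTH,
) -> PMFProfile:
    """Boltzmann inversion ``PMF = -kT ln(rho/rho_bulk)``, bulk-zeroed.

    ``bulk_bins`` is a boolean mask over bins; by default bins with
    |z| > ``bulk_half_length`` are bulk.  Zero-count bins are reported as a
    censored lower bound using a half-count pseudo-count.
    """
    z = profile.z_bin_centers
    if bulk_bins is None:
        bulk_bins = np.abs(z) > bulk_half_length
    bulk_bins = np.asarray(bulk_bins, dtype=bool)
    if not bulk_bins.any():
        raise ValueError("no bulk bins designated")
    bulk_density = float(profile.density[bulk_bins].mean())
    if bulk_density <= 0:
        raise ValueError("bulk density is zero; PMF reference undefined")
    volume = math.pi * profile.cylinder_radius**2 * profile.dz
    floor_density = 0.5 / (profile.n_frames * volume)
    censored = profile.counts == 0
    dens = np.where(censored, floor_density, profile.density)
    pmf = -np.log(dens / bulk_density)
    # re-zero over bulk bins (exactly zero mean if densities are uniform there)
    pmf = pmf - pmf[bulk_bins & ~censored].mean() if (bulk_bins & ~censored).any() else pmf
    return PMFProfile(
        z, profile.counts, profile.density, pmf, censored, bulk_density,
        profile.cylinder_radius,
    )


def pore_occupancy(
    traj: IonTrajectory,
    species: str,
    radius: float = DEFAULT_CYLINDER_RADIUS,
    half_length: float = BULK_HALF_LENGTH,
    z_range: tuple[float, float] | None = None,
) -> tuple[float, np.ndarray]:
    """Mean and per-frame count of ions inside the pore envelope.

    The envelope is a cylinder of the given radius with |z| <= half_length
    (or an explicit ``z_range``).
    """
    lo, hi = (-half_length, half_length) if z_range is None else z_range
    series = np.zeros(traj.n_frames)
    for t, f in enumerate(traj.frames):
        xyz = f.get(species)
        if xyz is None or len(xyz) == 0:
            continue
        r = np.hypot(xyz[:, 0], xyz[:, 1])
        series[t] = int(np.sum((r <= radius) & (xyz[:, 2] >= lo) & (xyz[:, 2] <= hi)))
    return float(series.mean()), series


_WATER_PREFIXES = ("WAT", "HOH", "W:")


def coordination_timeseries(
    ion_frames: np.ndarray,
    ligand_frames: dict[str, np.ndarray],
    cutoff: float = 2.6,
    strict: bool = True,
) -> dict:
    """Per-frame coordination sets of one metal ion.

    ``ion_frames`` is (T, 3); each ligand entry is either (T, 3) or a static
    (3,) position.  A ligand coordinates at a frame when its distance to the
    ion is < ``cutoff`` (or <= with ``strict=False``).  Ligand labels starting
    with a water prefix (``WAT``/``HOH``/``W:``) are tallied separately for
    the water-count statistics.
    """
    ion = np.asarray(ion_frames, dtype=float).reshape(-1, 3)
    T = len(ion)
    per_frame: list[list[str]] = [[] for _ in range(T)]
    fractions: dict[str, float] = {}
    for label, pos in ligand_frames.items():
        pos = np.asarray(pos, dtype=float)
        if pos.ndim == 1:
            pos = np.broadcast_to(pos, (T, 3))
        d = np.linalg.norm(pos - ion, axis=1)
        coordinated = d < cutoff if strict else d <= cutoff
        fractions[label] = float(coordinated.mean())
        for t in np.nonzero(coordinated)[0]:
            per_frame[t].append(label)
    is_water = {lbl: lbl.upper().startswith(_WATER_PREFIXES) for lbl in ligand_frames}
    water_counts = np.array(
        [sum(1 for lbl in frame if is_water[lbl]) for frame in per_frame]
    )
    cn_series = np.array([len(frame) for frame in per_frame])
    return {
        "per_frame": per_frame,
        "fractions": fractions,
        "cn_mean": float(cn_series.mean()),
        "cn_series": cn_series,
        "water_mean": float(water_counts.mean()),
        "water_series": water_counts,
    }
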
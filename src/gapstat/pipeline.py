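"""End-to-end analysis pipeline with a consolidated, schema-checked report.

A single :class:`PipelineConfig` drives every stage: structure loading (or
synthetic generation), metal-site detection, pore profiling, paired-structure
comparison, Poisson electrostatics with and without the bound metal charges,
and an equilibrium ion simulation whose Boltzmann-inversion PMF closes the
loop from surface potential to permeation statistics.

Without input files the pipeline runs entirely on the synthetic toy channel:
a docked two-hemichannel assembly with six +2 sites per hemichannel ring at
|z| = 28 A, a lysine-like constriction ring, and a perturbed "free" partner
whose E47-like side chain is swung away from the coordinating pose.
"""

from __future__ import annotations

import json
import math
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    LangevinSpec,
    axial_density,
    barrier_from_grid,
    build_charge_radius_model,
    clearance_check,
    cross_pore_distance,
    detect_bidentate,
    determine_axis,
    find_metal_sites,
    find_polar_contacts,
    gaussian_barrier,
    interface_area,
    limiting_diameter,
    make_gjc_like_channel,
    matthews_solvent,
    per_residue_deviation,
    perturb_structure,
    pmf_from_density,
    pore_occupancy,
    pore_positive_fraction,
    radial_backbone_shift,
    radius_profile,
    read_structure,
    sidechain_displacement,
    simulate_ion_trajectory,
    site_ring_metrics,
    solve_poisson,
    superpose,
    surface_potential_map,
)
from .structure import CrystalCell

__all__ = ["PipelineConfig", "run_pipeline", "validate_report", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All knobs of one reproducible run; echoed into the report."""

    bound_structure: str | None = None  # path; None -> synthetic toy channel
    free_structure: str | None = None
    metal_element: str = "CA"
    metal_cutoff: float = 2.9
    salt_bridge_cutoff: float = 4.0
    hbond_cutoff: float = 3.5
    pore_dz: float = 1.0
    hydrated_ion_diameter: float = 6.6
    grid_spacing: float = 1.5
    grid_padding: float = 8.0
    eps_in: float = 4.0
    eps_out: float = 78.5
    electro_temperature: float = 298.15
    pmf_radius: float = 7.0
    pmf_dz: float = 5.0
    bulk_half_length: float = 60.0
    run_trajectory: bool = True
    traj_n_steps: int = 20000
    traj_record_interval: int = 50
    traj_n_ions: int = 60
    traj_half_length: float = 82.5
    sim_temperature: float = 310.0
    seed: int = 0
    output_dir: str = "gapstat_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return round(v, ndigits) if math.isfinite(v) else v
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return (and write) the consolidated report."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "stages": {}}
    t_start = time.time()

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as exc:  # propagate with stage name
                raise StageError(name, exc) from exc
            result["elapsed_s"] = round(time.time() - t0, 3)
            report["stages"][name] = _round_floats(result)

        return wrap

    synthetic = config.bound_structure is None
    sel = None if synthetic else "CA"

    # ---- structures -------------------------------------------------------
    if synthetic:
        bound = make_gjc_like_channel()
        free = perturb_structure(
            make_gjc_like_channel(include_metals=False),
            [
                (
                    {"chain_id": c, "residue_number": 47, "atom_name": ["CD", "OE1", "OE2"]},
                    {"rotate": {"about": (c, 47, "CB"), "axis": (0, 0, 1), "angle_deg": 100}},
                )
                for c in "ABCDEFGHIJKL"
            ]
            + [({"residue_number": [229, 230, 231]}, {"radial": 0.8})],
        )
    else:
        bound = read_structure(config.bound_structure)
        free = read_structure(config.free_structure) if config.free_structure else None

    @stage("structures")
    def _structures():
        return {
            "synthetic": synthetic,
            "bound_atoms": len(bound),
            "bound_chains": bound.chain_ids,
            "free_atoms": None if free is None else len(free),
        }

    axis, origin = determine_axis(bound)

    # ---- metal sites ------------------------------------------------------
    sites = find_metal_sites(bound, {config.metal_element}, config.metal_cutoff)

    @stage("metal_sites")
    def _sites():
        if not sites:
            return {"n_sites": 0}
        rings = site_ring_metrics(sites, axis, origin)
        return {
            "n_sites": len(sites),
            "mean_coordination_distance": float(
                np.mean([s.mean_distance for s in sites])
            ),
            "coordination_numbers": sorted({s.cn for s in sites}),
            "formal_charges": sorted({s.formal_charge for s in sites}),
            "geometry_classes": sorted({s.geometry_class for s in sites}),
            "bidentate_residues_per_site": float(
                np.mean([len(detect_bidentate(s)) for s in sites])
            ),
            "rings": [
                {
                    "axial_position": r["axial_position"],
                    "n_sites": r["n_sites"],
                    "mean_separation": r["mean_separation"],
                    "mean_rotation_deg": r["mean_rotation_deg"],
                }
                for r in rings
            ],
        }

    # ---- pore geometry ----------------------------------------------------
    profile = radius_profile(bound, axis, origin, dz=config.pore_dz)

    @stage("pore")
    def _pore():
        dmin, z_at = limiting_diameter(profile)
        ok, margin = clearance_check(profile, config.hydrated_ion_diameter)
        out = {
            "limiting_diameter": dmin,
            "z_at_minimum": z_at,
            "clearance_probe_diameter": config.hydrated_ion_diameter,
            "clearance_pass": bool(ok),
            "clearance_margin": margin,
            "axis": axis.tolist(),
        }
        try:
            nz = cross_pore_distance(
                bound, 41, "NZ", axis=axis, origin=origin, z_range=(10, 60)
            )
            out["nz_opposing_distance"] = nz.opposing
        except (ValueError, KeyError):
            pass
        try:
            ca = cross_pore_distance(
                bound, 0, "", element=config.metal_element, axis=axis, origin=origin,
                z_range=(10, 60),
            )
            out["site_cross_lumen_max"] = ca.max
        except (ValueError, KeyError):
            pass
        pd.DataFrame({"z": profile.z, "radius": profile.radius}).to_csv(
            outdir / "pore_profile.csv", index=False, float_format="%.4f"
        )
        return out

    # ---- polar contacts ---------------------------------------------------
    @stage("contacts")
    def _contacts():
        res = {}
        for label, st in (("bound", bound), ("free", free)):
            if st is None:
                continue
            contacts = find_polar_contacts(
                st, config.salt_bridge_cutoff, config.hbond_cutoff
            )
            res[label] = {
                "n_salt_bridges": sum(c.kind == "salt_bridge" for c in contacts),
                "n_hydrogen_bonds": sum(c.kind == "hydrogen_bond" for c in contacts),
                "n_intersubunit": sum(c.scope != "intrasubunit" for c in contacts),
            }
        return res

    # ---- interface area ---------------------------------------------------
    @stage("interface")
    def _interface():
        chains = [c for c in bound.chain_ids if c != "X"]
        ga = [a for a in bound.atoms if a.chain_id == chains[0] and not a.is_hetero]
        gb = [a for a in bound.atoms if a.chain_id == chains[1] and not a.is_hetero]
        return {
            "chains": chains[:2],
            "buried_area": interface_area(bound, ga, gb),
        }

    # ---- crystallographic utility (demonstration numbers) ----------------
    @stage("matthews")
    def _matthews():
        if bound.cell is not None:
            cell = bound.cell
            note = "from input structure cell"
        else:
            cell = CrystalCell(100.0, 100.0, 100.0)
            note = "synthetic cubic demonstration cell"
        v_m, solv = matthews_solvent(cell, 1, 1, 10000.0)
        return {
            "note": note + " (1 x 10 kDa molecule)",
            "v_m": v_m,
            "solvent_fraction": solv,
            "volume_constant": 1.230,
        }

    # ---- conformational comparison ---------------------------------------
    if free is not None:
        sup = superpose(free, bound, selection=sel)

        @stage("compare")
        def _compare():
            dev = per_residue_deviation(sup)
            dev.to_csv(outdir / "per_residue_deviation.csv", index=False,
                       float_format="%.4f")
            out = {
                "global_rmsd": sup.rmsd,
                "n_pairs": sup.n_pairs,
                "max_deviation": float(dev["deviation"].max()),
                "max_deviation_residue": int(
                    dev.loc[dev["deviation"].idxmax(), "residue_number"]
                ),
            }
            try:
                disp, ang = sidechain_displacement(sup, free, bound, "A", 47, "CD")
                out["e47_cd_displacement"] = disp
                out["e47_swing_deg"] = ang
            except (ValueError, KeyError):
                pass
            try:
                out["radial_backbone_shift"] = radial_backbone_shift(
                    sup, free, bound, axis, origin, (229, 231)
                )
            except ValueError:
                pass
            return out

    # ---- electrostatics ---------------------------------------------------
    model_with = build_charge_radius_model(bound, include_metal_charges=True)
    model_without = build_charge_radius_model(bound, include_metal_charges=False)
    grid_with = solve_poisson(
        model_with, config.grid_spacing, config.grid_padding,
        config.eps_in, config.eps_out, config.electro_temperature,
    )
    grid_without = solve_poisson(
        model_without, config.grid_spacing, config.grid_padding,
        config.eps_in, config.eps_out, config.electro_temperature,
    )

    @stage("electrostatics")
    def _electro():
        out = {"total_charge_with_metal": model_with.total_charge,
               "total_charge_without_metal": model_without.total_charge}
        for label, grid, model in (
            ("with_metal", grid_with, model_with),
            ("without_metal", grid_without, model_without),
        ):
            sp = surface_potential_map(
                grid, model, axis=axis, origin=origin,
                pore_radius=config.pmf_radius + 5.0,
            )
            out[label] = pore_positive_fraction(sp)
        return out

    # ---- ion trajectory + PMF --------------------------------------------
    if config.run_trajectory:

        @stage("trajectory_pmf")
        def _traj():
            zb, ub = barrier_from_grid(grid_with, +1.0, radius=config.pmf_radius)
            zf, uf = barrier_from_grid(grid_without, +1.0, radius=config.pmf_radius)
            out = {
                "barrier_peak_with_metal": float(np.max(ub)),
                "barrier_peak_without_metal": float(np.max(uf)),
            }
            # equilibrium simulation in a reference 3 kT Gaussian barrier
            u_true = gaussian_barrier(3.0)
            spec = LangevinSpec(
                potential=u_true,
                cylinder_radius=config.pmf_radius,
                half_length=config.traj_half_length,
                species={"K": (config.traj_n_ions, 1.0),
                         "CL": (config.traj_n_ions, -1.0)},
                n_steps=config.traj_n_steps,
                record_interval=config.traj_record_interval,
                seed=config.seed,
                temperature=config.sim_temperature,
            )
            traj = simulate_ion_trajectory(spec)
            L = config.traj_half_length
            dens = axial_density(traj, "K", config.pmf_radius, config.pmf_dz, (-L, L))
            pmf = pmf_from_density(dens, bulk_half_length=config.bulk_half_length)
            pmf.to_frame().to_csv(outdir / "pmf_k.csv", index=False,
                                  float_format="%.5f")
            dens_cl = axial_density(traj, "CL", config.pmf_radius, config.pmf_dz, (-L, L))
            pmf_cl = pmf_from_density(dens_cl, bulk_half_length=config.bulk_half_length)
            pmf_cl.to_frame().to_csv(outdir / "pmf_cl.csv", index=False,
                                     float_format="%.5f")
            occ_k, _ = pore_occupancy(traj, "K", config.pmf_radius, z_range=(-7.5, 7.5))
            occ_cl, _ = pore_occupancy(traj, "CL", config.pmf_radius, z_range=(-7.5, 7.5))
            out.update(
                {
                    "recovered_barrier_kT": float(np.nanmax(pmf.pmf)),
                    "true_barrier_kT": 3.0,
                    "k_occupancy_center": occ_k,
                    "cl_occupancy_center": occ_cl,
                    "n_frames": traj.n_frames,
                }
            )
            return out

    report["elapsed_s"] = round(time.time() - t_start, 3)
    validate_report(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


# ---------------------------------------------------------------------------
# report schema (shipped as JSON next to the package) and a small validator
# ---------------------------------------------------------------------------

_SCHEMA_PATH = Path(__file__).parent / "report_schema.json"


def validate_report(report: dict) -> None:
    """Check the report against the shipped schema (required keys + types)."""
    with open(_SCHEMA_PATH) as fh:
        schema = json.load(fh)
    _check(report, schema, "report")


_TYPES = {
    "object": dict,
    "number": (int, float),
    "integer": int,
    "string": str,
    "boolean": bool,
    "array": list,
    "null": type(None),
}


def _check(value, schema, path):
    typ = schema.get("type")
    if typ is not None:
        allowed = typ if isinstance(typ, list) else [typ]
        if not any(isinstance(value, _TYPES[t]) and not (
            t == "number" and isinstance(value, bool)
        ) for t in allowed):
            raise ValueError(f"{path}: expected {typ}, got {type(value).__name__}")
    for key, sub in schema.get("properties", {}).items():
        if key in value:
            _check(value[key], sub, f"{path}.{key}")
    for key in schema.get("required", []):
        if key not in value:
            raise ValueError(f"{path}: missing required key {key!r}")
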
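{
  "type": "object",
  "required": ["config", "stages"],
  "properties": {
    "config": {
      "type": "object",
      "required": ["seed", "metal_cutoff", "grid_spacing", "pmf_radius", "pmf_dz"],
      "properties": {
        "seed": {"type": "integer"},
        "metal_cutoff": {"type": "number"},
        "grid_spacing": {"type": "number"},
        "pmf_radius": {"type": "number"},
        "pmf_dz": {"type": "number"},
        "bound_structure": {"type": ["string", "null"]},
        "free_structure": {"type": ["string", "null"]}
      }
    },
    "stages": {
      "type": "object",
      "required": ["structures", "metal_sites", "pore", "electrostatics"],
      "properties": {
        "structures": {
          "type": "object",
          "required": ["bound_atoms"],
          "properties": {"bound_atoms": {"type": "integer"}}
        },
        "metal_sites": {
          "type": "object",
          "required": ["n_sites"],
          "properties": {
            "n_sites": {"type": "integer"},
            "mean_coordination_distance": {"type": "number"},
            "rings": {"type": "array"}
          }
        },
        "pore": {
          "type": "object",
          "required": ["limiting_diameter", "clearance_pass"],
          "properties": {
            "limiting_diameter": {"type": "number"},
            "clearance_pass": {"type": "boolean"},
            "clearance_margin": {"type": "number"}
          }
        },
        "compare": {
          "type": "object",
          "required": ["global_rmsd", "n_pairs"],
          "properties": {
            "global_rmsd": {"type": "number"},
            "n_pairs": {"type": "integer"}
          }
        },
        "electrostatics": {
          "type": "object",
          "required": ["total_charge_with_metal", "total_charge_without_metal"]
        },
        "trajectory_pmf": {
          "type": "object",
          "required": ["recovered_barrier_kT", "true_barrier_kT"]
        }
      }
    },
    "elapsed_s": {"type": "number"}
  }
}
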
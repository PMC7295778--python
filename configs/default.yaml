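# Reference protocol: umbrella sampling of a K+ ion over the collar barrier.
# All keys carry explicit unit suffixes; conversion to internal units
# (A, kJ/mol, ps) happens at parse time.
landscape:
  barrier_height_kJ_per_mol: 6.0
  barrier_center_z_A: 22.0
  barrier_width_A: 1.5
  n_bulk: 6.5
  n_collar: 3.0
  n_dip_width_A: 1.5
  coupling_kappa_kJ_per_mol: 5.0
  temperature_K: 303.15
  diffusion_z_A2_per_ps: 0.2
  diffusion_n_per_ps: 0.5
  field_strength_V_per_nm: 0.0
  ion_charge_e: 1.0
  box_length_z_A: 88.0
windows:
  center_min_A: 16.5
  center_max_A: 36.5
  spacing_A: 0.2
  force_constant_kJ_per_mol_nm2: 3000.0
  duration_ps: 2000.0
  sample_interval_ps: 1.0
wham:
  n_bins: 100
  tolerance: 1.0e-6
  bootstraps: 200
coordination:
  cutoff_A: 3.0
  snapshot_stride: 10
  n_hydroxyl_near_collar: 1
barrier:
  barrier_range_A: [19.0, 25.0]
  reference_range_A: [16.5, 18.5]
flux:
  rate_per_min: 0.12
  amplitude_pct: 100.0
  noise_sd_pct: 2.0
  n_replicates: 3
seed: 1
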
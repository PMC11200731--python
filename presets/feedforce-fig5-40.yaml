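drill:
  diameter_mm: 3.5
  point_angle_deg: 108.0
  helix_angle_deg: 23.0
  material:
    name: 316L stainless steel
    density_g_cm3: 7.99
    elastic_modulus_mpa: 193000.0
    poisson_ratio: 0.25
    yield_stress_mpa: 290.0
    ultimate_stress_mpa: 579.0
    ultimate_strain: 0.003
    specific_heat_j_kg_c: 500.0
    thermal_conductivity_w_m_k: 16.2
    damage_failure_strain: null
    damage_plastic_displacement_mm: null
bone:
  thickness_mm: 4.0
  outer_diameter_mm: 8.0
  material:
    name: cortical bone
    density_g_cm3: 1.64
    elastic_modulus_mpa: 16700.0
    poisson_ratio: 0.3
    yield_stress_mpa: 105.0
    ultimate_stress_mpa: 106.0
    ultimate_strain: 0.008
    specific_heat_j_kg_c: 1640.0
    thermal_conductivity_w_m_k: 0.452
    damage_failure_strain: 0.008
    damage_plastic_displacement_mm: 0.3
  initial_temperature_c: 22.0
rotational_speed_rpm: 800.0
feed_force_n: 40.0
friction_coefficient: 0.3
heat_partition_to_drill: 0.5
inelastic_heat_fraction: 0.9
target_depth_mm: null
predrill_diameter_mm: null
calibration: null
grid_spacing_mm: 0.05
time_step_safety: 0.4
post_drill_hold_s: 5.0
max_time_s: 120.0
name: feedforce-fig5-40
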
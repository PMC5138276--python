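# Human catalog (70 kg adult).
# Device power/efficiency/floor are the sheep device carried over; the
# element contact geometry is human-specific (both carotid and vertebral
# arteries are reachable in the human neck), so the element conductances
# are calibrated against the published human predictions (0.64/0.43 °C/h).
species: human
body_mass_kg: 70.0
environment_T_C: 24.0
metabolic_total_kcal_day: 1200.0
metabolic_shares:
  body: 0.78
  head: 0.20
  neck: 0.02
tissues:
  body: {mass_kg: 59.02439, specific_heat_J_kgC: 3500.0}
  head: {mass_kg: 4.5, specific_heat_J_kgC: 3500.0}
  neck: {mass_kg: 1.47561, specific_heat_J_kgC: 3500.0}
blood:
  density_kg_m3: 1050.0
  specific_heat_J_kgC: 3617.0
blood_nodes:
  blood_neck_in: {volume_m3: 3.0e-05, wall_conductance_W_C: 4.49053}
  blood_head: {volume_m3: 2.0e-04, wall_conductance_W_C: 11.1601}
  blood_neck_out: {volume_m3: 3.0e-05, wall_conductance_W_C: 39.9206}
  blood_body: {volume_m3: 4.5e-03, wall_conductance_W_C: 77.5159}
flow_m3_s: 1.99987e-05
conductances:
  g_be: 3.46278
  g_he: 0.889951
  g_bn: 0.5
  g_nh: 0.6
collar:
  source_power_W: 60.0
  efficiency: 0.6
  n_elements: 2
  skin_floor_C: 5.0
  guard_band_C: 1.0
  element_mode: quasi_steady
  element_heat_capacity_J_C: 400.0
  g_elem_neck_W_C: 4.59398
  g_elem_env_W_C: 0.0595403
  g_elem_elem_W_C: 0.5
provenance:
  body_mass_kg: literature-default
  environment_T_C: literature-default
  metabolic_total_kcal_day: literature-default
  metabolic_shares.body: literature-default
  metabolic_shares.head: literature-default
  metabolic_shares.neck: literature-default
  tissues.body.mass_kg: calibrated
  tissues.body.specific_heat_J_kgC: literature-default
  tissues.head.mass_kg: literature-default
  tissues.head.specific_heat_J_kgC: literature-default
  tissues.neck.mass_kg: calibrated
  tissues.neck.specific_heat_J_kgC: literature-default
  blood.density_kg_m3: literature-default
  blood.specific_heat_J_kgC: literature-default
  blood_nodes.blood_neck_in.volume_m3: literature-default
  blood_nodes.blood_neck_in.wall_conductance_W_C: calibrated
  blood_nodes.blood_head.volume_m3: literature-default
  blood_nodes.blood_head.wall_conductance_W_C: calibrated
  blood_nodes.blood_neck_out.volume_m3: literature-default
  blood_nodes.blood_neck_out.wall_conductance_W_C: calibrated
  blood_nodes.blood_body.volume_m3: literature-default
  blood_nodes.blood_body.wall_conductance_W_C: calibrated
  flow_m3_s: calibrated
  conductances.g_be: calibrated
  conductances.g_he: calibrated
  conductances.g_bn: literature-default
  conductances.g_nh: literature-default
  collar.source_power_W: literature-default
  collar.efficiency: literature-default
  collar.n_elements: literature-default
  collar.skin_floor_C: literature-default
  collar.guard_band_C: literature-default
  collar.element_mode: literature-default
  collar.element_heat_capacity_J_C: literature-default
  collar.g_elem_neck_W_C: calibrated
  collar.g_elem_env_W_C: calibrated
  collar.g_elem_elem_W_C: literature-default
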
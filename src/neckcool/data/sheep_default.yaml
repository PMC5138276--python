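# Sheep catalog (adult Bergamasca ewe, ~68 kg).
# Provenance: "literature-default" = standard physiological value;
# "calibrated" = fitted against the experimental Table-1 summaries
# (baselines 36.5/37.3 °C) and the model's published cooling rates
# (0.4/0.2 °C/h); the published supplement values were not available
# for transcription, so no entry is flagged "supplement".
species: sheep
body_mass_kg: 68.0
environment_T_C: 24.0
metabolic_total_kcal_day: 1200.0
metabolic_shares:
  body: 0.95
  head: 0.03
  neck: 0.02
tissues:
  body: {mass_kg: 59.93, specific_heat_J_kgC: 3500.0}
  head: {mass_kg: 2.5, specific_heat_J_kgC: 3500.0}
  neck: {mass_kg: 2.0, specific_heat_J_kgC: 3500.0}
blood:
  density_kg_m3: 1050.0
  specific_heat_J_kgC: 3617.0
blood_nodes:
  blood_neck_in: {volume_m3: 2.5e-05, wall_conductance_W_C: 5.65796}
  blood_head: {volume_m3: 1.5e-04, wall_conductance_W_C: 15.0}
  blood_neck_out: {volume_m3: 2.5e-05, wall_conductance_W_C: 29.1191}
  blood_body: {volume_m3: 3.2e-03, wall_conductance_W_C: 71.1532}
flow_m3_s: 1.67905e-05
conductances:
  g_be: 3.12506
  g_he: 0.715571
  g_bn: 0.5
  g_nh: 0.5
collar:
  source_power_W: 60.0
  efficiency: 0.6
  n_elements: 2
  skin_floor_C: 5.0
  guard_band_C: 1.0
  element_mode: quasi_steady
  element_heat_capacity_J_C: 400.0
  g_elem_neck_W_C: 0.566701
  g_elem_env_W_C: 0.62914
  g_elem_elem_W_C: 0.5
provenance:
  body_mass_kg: literature-default
  environment_T_C: literature-default
  metabolic_total_kcal_day: literature-default
  metabolic_shares.body: literature-default
  metabolic_shares.head: literature-default
  metabolic_shares.neck: literature-default
  tissues.body.mass_kg: literature-default
  tissues.body.specific_heat_J_kgC: literature-default
  tissues.head.mass_kg: literature-default
  tissues.head.specific_heat_J_kgC: literature-default
  tissues.neck.mass_kg: literature-default
  tissues.neck.specific_heat_J_kgC: literature-default
  blood.density_kg_m3: literature-default
  blood.specific_heat_J_kgC: literature-default
  blood_nodes.blood_neck_in.volume_m3: literature-default
  blood_nodes.blood_neck_in.wall_conductance_W_C: calibrated
  blood_nodes.blood_head.volume_m3: literature-default
  blood_nodes.blood_head.wall_conductance_W_C: literature-default
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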
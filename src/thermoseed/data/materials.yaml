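# Built-in material registry: literature thermophysical parameters of tissues
# and composite-seed components used by the planning scenarios.
# All values SI with temperatures in degrees Celsius.
version: "1.0"

materials:
  tumor:
    density_kg_m3: 1060
    heat_capacity_J_kgC: 3540
    conductivity_W_mC: 0.52
    perfusion_rate_1_s: 0.000833
    metabolic_q0_W_m3: 5790
  liver:
    density_kg_m3: 1079
    heat_capacity_J_kgC: 3540
    conductivity_W_mC: 0.52
    perfusion_rate_1_s: 0.0155
    metabolic_q0_W_m3: 10682
  muscle:
    density_kg_m3: 1090
    heat_capacity_J_kgC: 3421
    conductivity_W_mC: 0.49
    perfusion_rate_1_s: 0.000643
    metabolic_q0_W_m3: 988
  mnp:
    density_kg_m3: 5180
    heat_capacity_J_kgC: 670
    conductivity_W_mC: 40
  silver:
    density_kg_m3: 10490
    heat_capacity_J_kgC: 235
    conductivity_W_mC: 429
  titanium:
    density_kg_m3: 4500
    heat_capacity_J_kgC: 523
    conductivity_W_mC: 21.90
  air:
    density_kg_m3: 1.184
    heat_capacity_J_kgC: 1005
    conductivity_W_mC: 0.0262

blood:
  density_kg_m3: 1050
  heat_capacity_J_kgC: 3617
  arterial_temperature_C: 37

# Volume fractions of the composite-seed components (sum to 1).
seed_volume_fractions:
  mnp: 0.1656
  silver: 0.2888
  titanium: 0.4090
  air: 0.1366
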
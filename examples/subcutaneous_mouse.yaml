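# One seed in an ellipsoidal subcutaneous tumor (semi-axes 5 x 3.5 x 2 mm)
# embedded 1/5 of its minor axis in muscle; exposed surface cooled by air.
scenario: subcutaneous_mouse
resolution_m: 1.5e-4
convection:
  coefficient_W_m2C: 5.0
  ambient_C: 25.0
output_dir: runs/subcutaneous_mouse
rng_seed: 0
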
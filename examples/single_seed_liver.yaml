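# One composite seed centered in the deep-seated liver phantom
# (15 mm tumor sphere inside 25 mm liver, outer surface at 37 C).
scenario: single_seed_liver
resolution_m: 5.0e-5
solver:
  tol: 1.0e-4
  damping: 0.7
output_dir: runs/single_seed_liver
rng_seed: 0
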
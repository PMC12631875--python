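# Four parallel composite seeds (one opposite pair in each central plane),
# spacing d_mm between the two seeds of each pair.
scenario: four_seed_liver
d_mm: 5.85
resolution_m: 1.25e-4
output_dir: runs/four_seed_liver
rng_seed: 0
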
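# Two parallel composite seeds at transverse spacing d_mm in the liver phantom.
scenario: two_seed_liver
d_mm: 3.0
resolution_m: 1.25e-4
output_dir: runs/two_seed_liver
rng_seed: 0
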
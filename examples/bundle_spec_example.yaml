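# BundleSpec fields for `memqa simulate bundle --spec ...`
n_helices: 4
helix_length: 24
target_thickness: 30.0
tilt_deg: 10.0
loop_length: 4
radius: 8.0
noise_sigma: 0.3
seed: 0
plddt_tm: 90.0
plddt_loop: 60.0
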
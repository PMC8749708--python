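# Full imaging-depth sweep at default noise.
depths_mm: [4, 7, 10, 13, 16, 19, 22, 25]
pO2_levels: [0.0, 150.0]
replicates: 7
n_photons: 100000
seed: 1
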
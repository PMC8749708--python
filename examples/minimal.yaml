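# One PALI acquisition: node at 4 mm, oxygenated solution.
depth_mm: 4.0
node_radius_mm: 3.0
voxel_mm: 0.4
n_photons: 100000
n_averages: 100
pO2_mmhg: 150.0
seed: 1
fit_model: auto
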
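# Default methylene-blue photophysics (literature-typical values).
# Any field may be overridden; units as in palisim.photophysics.
eta: 0.52                   # triplet quantum yield
sigma_g: 2.791e-16          # ground-state cross-section at 660 nm, cm^2
eps_triplet: 1.4e4          # triplet extinction at 830 nm, 1/(M cm)
pump_pulse_duration: 5.0e-9 # s
k_dim: 2.5e3                # dimerization constant, 1/M
total_conc: 4.0e-4          # M
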
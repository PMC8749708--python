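# Methods

`palisim` is a forward simulator and analysis toolkit for photoacoustic
lifetime imaging (PALI) of tissue oxygen. This note records the models it
implements, the parameters that matter, the numerical choices, and what
the simulations do and do not capture.

## Physical model

### Triplet photophysics and Stern-Volmer oximetry

Methylene blue (MB) monomers pumped at 660 nm cross into a long-lived
triplet state whose decay rate is set by collisional oxygen quenching:

    kt = kQ * pO2 + k0

Pumping during a pulse of duration `t` follows the two-state kinetics

    nt = beta * n / (alpha + beta) * (1 - exp(-(alpha + beta) t)),
    beta = eta * sigma_g * phi / (h * nu),

with `n` the photoactive monomer concentration, `alpha = kt` the triplet
decay rate, and `phi` the local fluence rate (W/cm^2). The monomer
concentration comes from the dimerization equilibrium `K = [D]/[M]^2`,
solved in the cancellation-free form `m = 2 T / (1 + sqrt(1 + 8 K T))`;
with the default `K = 2500 1/M` a 400 uM solution is 50% monomeric.
Dimers only sequester dye; they are not modeled as photoactive.

The default rate constants `k0 = 1.84e4 1/s` and
`kQ = (6.05e5 - 1.84e4)/150 1/(s mm Hg)` correspond to flash-photolysis
rates of deoxygenated (0 mm Hg) and air-saturated (150 mm Hg) MB
solutions. Quantum yield (0.52), ground-state extinction at 660 nm
(7.3e4 1/(M cm)) and triplet extinction at 830 nm (1.4e4 1/(M cm)) are
literature-typical values for MB and are configurable; the package's
results depend on them only through overall signal scale, never through
the recovered decay rates.

Molar extinction coefficients are decadic by spectroscopic convention;
absorption coefficients used in transport and pressure generation are
natural, so every conversion carries an explicit ln(10).

### Light transport

Photon-packet Monte Carlo on a voxel grid (default 40 x 40 x 35 mm at
0.4 mm voxels, which resolves the 3 mm node radius with ~7 voxels;
0.2 mm is configurable when finer sampling of the node boundary is
wanted). Neck-tissue optics: mu_a = 0.22 / 0.235 1/cm and
mu_s' = 9.1 / 7.3 1/cm at 660 / 830 nm, Henyey-Greenstein anisotropy
g = 0.9 with mu_s = mu_s'/(1 - g). Boundaries are refractive-index
matched (packets escape on exit); there is no Fresnel reflection,
polarization, fluorescence, or time-resolved transport.

Scattering lengths are sampled from the local mu_s by consuming a sampled
optical depth across voxel boundaries; absorption attenuates the packet
weight continuously along each sub-step, and fluence is scored with a
track-length estimator (sum of `w * ds` per voxel, analytically
integrated against the absorption decay). The track-length estimator
remains exact in non-absorbing voxels and reproduces the incident fluence
in the vacuum limit, which a per-collision `w * mu_a/mu_t` deposit cannot
score. Russian roulette triggers below weight 1e-4 with survival
probability 0.1; the roulette ledger is reported so that
`launched = absorbed + escaped + roulette_net` holds to float precision
in every run. Fluence maps are normalized so the launched energy equals
beam pulse fluence times beam area, giving J/cm^2 per pulse, and are
bit-reproducible for a fixed seed.

The deep-fluence validation compares the on-axis log-slope in a
homogeneous slab against diffusion theory's
`mu_eff = sqrt(3 mu_a (mu_a + mu_s'))` (2.48 1/cm at the 660 nm tissue
values); a broad beam (>= 20 mm radius on a >= 60 mm wide grid) is
needed so the 5-15 mm depth range is quasi-planar.

### Acoustic detection

Initial pressure follows `P = Gamma * mu_a * phi` with the dimensionless
Grueneisen parameter (default 0.2); with mu_a in 1/cm and phi in J/cm^2,
P is numerically in MPa. Only the triplet-state absorption generates the
delay-dependent probe signal; the pump's own photoacoustic transient
(ground-state dye plus tissue absorption at 660 nm) is simulated as the
pump artifact.

A full-wave acoustic solver is deliberately not used. Decay-rate
recovery depends on relative amplitudes across pump-probe delays, not on
waveform fidelity, and tissue acoustic attenuation is neglected
throughout. Detection is therefore a far-field time-of-flight
projection: each voxel contributes `p * V / (4 pi r)` at delay `r / c`
(c = 1540 m/s), weighted by a cosine directivity inside the aperture
half-angle `atan((D/2)/F)` of the focused element (default 12.7 mm
diameter, 25 mm focal length, focus placed on the node center), sampled
at 40 MS/s with linear interpolation, and band-limited by a zero-phase
Gaussian response around 5 MHz with 0.6 fractional bandwidth. The
zero-phase response preserves arrival times exactly; absolute received
units are uncalibrated (MPa mm^2), which is irrelevant because every
analysis step is scale-invariant.

Receiver noise is additive white Gaussian with per-sample standard
deviation equal to the noise-equivalent pressure (NEP). The NEP of a
real receiver is estimated from a paired transducer/hydrophone
measurement as `NEP = Unoise * Hsig / Usig` (pre-arrival RMS times the
hydrophone-to-transducer peak-to-peak ratio). The simulation default
(2.41e-6 MPa per frame) is calibrated once so that the reference
acquisition — node at the shallowest 4 mm sweep depth, 100-frame
averaging — yields SNR ~100 on the averaged corrected trace.

SNR is defined as peak-to-peak signal amplitude divided by twice the RMS
of a pre-arrival noise window. This is one of several conventions; it is
pinned because depth-limit statements quoted in SNR units depend on it.

## Acquisition protocol and rate recovery

Twelve pump-probe delays log-spaced from 0.5 to 1000 us sample the decay
evenly on the time scales of both oxygenated (~1.7 us) and deoxygenated
(~54 us) lifetimes. At each delay, 100 pump-probe and 100 pump-only
frames are averaged; the averaged frame is generated directly with noise
std reduced by sqrt(100), which is exact for Gaussian noise and 100x
cheaper than per-frame simulation. The pump-only frame, rescaled by the
pump-energy ratio, is subtracted to remove the pump artifact, and the
result is normalized by probe pulse energy (per-frame energy jitter is
supported and cancels exactly through this chain). The amplitude at the
longest delay — where the triplet state has fully decayed — is
subtracted from all delays as background, and that reference delay is
excluded from fitting. The residual bias of this step is
`exp(-kt * tau_max)` (~1e-8 for the deoxygenated rate, 0 to double
precision for the oxygenated rate).

### Amplitude estimator

Two estimators are provided. `extract_amplitude` is the raw peak-to-peak
within a gate of +-3 us around the focal arrival time (wide enough to
cover the 6 mm node). Peak-to-peak, however, is a biased statistic: the
expected peak-to-peak of pure noise over an m-sample gate is ~5.6 sigma
for m = 240, so weak delays ride on a noise floor and — because the
background reference is itself at that floor — strong delays acquire a
constant negative offset after background subtraction. Measured on the
simulator this biases recovered rates by ~7% at SNR 100 and ~15% at
SNR 50, regardless of averaging.

The default estimator is therefore a gated linear projection of the
corrected trace onto the known transient shape (a matched filter, scaled
to peak-to-peak units). It is linear in the data, hence unbiased under
additive Gaussian noise, and it leaves the noiseless pipeline exactly
proportional to `exp(-kt tau)`. In simulation the template is the known
clean signal; on real data the highest-SNR (shortest-delay) corrected
frame would serve. Peak-to-peak remains available via
`amplitude_method="ptp"` and is always used for the SNR metric.

### Decay fitting

Amplitudes are normalized to the earliest delay and time is shifted to
start there, which makes fits invariant to uniform rescaling and keeps
the double model's unit-sum constraint representable (a two-exponential
mixture re-expressed from a shifted origin is again a unit-sum mixture
with the same rates). Models:

- single: `A exp(-b s)`;
- double: `a exp(-b s) + (1-a) exp(-c s)`, `a in [0, 1]`; the *slower*
  of (b, c) is recorded, since that is the monomer triplet rate that
  tracks oxygen;
- auto: both are fitted and an F-test on the residual sum of squares
  (2 extra parameters, alpha = 0.05) decides.

Fits use damped least squares (trust-region reflective; the bounds
`a in [0,1]`, rates in [1e2, 1e8] 1/s make the unbounded
Levenberg-Marquardt variant inapplicable) with analytic Jacobians and
log-linear initialization from the early/late thirds of the schedule.
Bound-limited or non-converged fits are returned flagged, never raised;
constant amplitude vectors short-circuit to a flagged degenerate result.

## Depth-sweep evaluation

Node depths 4-25 mm in 3 mm steps (1-16 mm for the benchtop-phantom
emulation mode), oxygenations {0, 150} mm Hg, 7 replicates. Per depth one
pump Monte Carlo is run (pump transport does not depend on the decay
rate); per oxygenation the triplet map and probe Monte Carlo are
recomputed; replicates share the clean traces and differ in their noise
stream, mirroring repeated acquisitions on one physical setup. Per-delay
amplitudes scale as `exp(-kt tau)` from the zero-delay probe run — the
probe-absorption nonlinearity (less triplet self-shielding at long
delays) is intentionally not re-simulated per delay.

Two depth criteria are scanned shallow to deep, reporting the first
exceedance, its bracketing interval, and `inf` when the swept range is
never exceeded:

- clinical imaging depth: mean recovered rate deviates from truth by
  more than 10 mm Hg through the truth calibration
  (`|mean - truth| / kQ > 10`);
- measurement depth limit: `|mean percent error| - 2 SD > 0` across
  replicates (zero error outside the two-sigma band).

Because the 10 mm Hg threshold is an *absolute* rate error
(`10 kQ ~ 3.9e4 1/s`) while the log-spaced schedule makes the rate
uncertainty approximately *proportional* to the rate itself, the
oxygenated condition (kt = 6.05e5 1/s) reaches the threshold at ~6.5%
relative error whereas the deoxygenated condition (kt = 1.84e4 1/s)
must err by ~210%. The clinical depth for the oxygenated level is
therefore intrinsically shallower than for the deoxygenated level in
this simulator — the same ordering the benchtop phantom experiment
shows (10 mm Hg exceeded at 16 mm for oxygenated, beyond 16 mm for
deoxygenated) — and the absolute depth values depend on the NEP
calibration, so only orderings and trends are meaningful, not the
absolute millimetre figures.

Default problem sizes (1e5 photons per transport run, 0.4 mm voxels,
7 replicates, 5 seed sets for sweep statistics, 1e6 photons for the
diffusion-slope validation) were chosen once as the package's standard
desk-scale configuration.

## Phantom design

Intralipid/India-ink mixtures are designed by measuring each stock's
per-fraction attenuation from a transmission-dilution series fitted to
the effective single exponential `T = exp(-mu_eff d f)` — ordinary least
squares on `-ln T` against `d f`, through the origin since `T(0) = 1` by
construction. This is an effective-attenuation approximation, not
diffusion-theory transmittance with boundary terms; it is exactly the
model the dilution measurement realizes. Scatterer absorption and
absorber scattering are assumed negligible, so the two target fractions
decouple linearly; a required fraction above 1 raises an infeasibility
error.

## What the synthetic data does not capture

- Generated decays are exactly single-exponential; the double-exponential
  behaviour of real deoxygenated MB solutions (attributed to additional
  triplet reactions) exists here only as a fitting model, so passing
  tests validate the fitting path, not the chemistry.
- No acoustic attenuation, speckle, reverberation, or beamforming; the
  time-of-flight projection preserves relative amplitudes but not
  absolute waveforms, so absolute depth limits are not transferable to
  hardware.
- Uniform dye loading in a perfectly spherical node; no photobleaching or
  singlet-oxygen chemistry; laser energy jitter defaults to zero.
- Replicate scatter comes from receiver noise only; real replicates add
  alignment, flow, and oxygenation drift, so simulated reliability
  depths are optimistic.
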
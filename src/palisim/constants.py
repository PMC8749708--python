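"""Physical constants and documented default parameter values.

All defaults are overridable through the YAML configuration layer
(:mod:`palisim.config`); nothing in the simulation kernels reads this
module directly except through explicitly passed parameters.

Unit conventions used throughout the package
--------------------------------------------
lengths        mm for geometry, cm for optical coefficients (1/cm)
fluence        J/cm^2 per pulse; fluence rate W/cm^2
concentration  mol/L (M)
rates          1/s
pressure       MPa  (1 J/cm^3 of absorbed energy density converts to
               1 MPa of initial pressure before the Grueneisen factor)
"""

# ---------------------------------------------------------------------------
# Universal constants
# ---------------------------------------------------------------------------
PLANCK_J_S = 6.62607015e-34
"""Planck constant h (J s)."""

SPEED_OF_LIGHT_M_S = 2.99792458e8
"""Speed of light in vacuum (m/s)."""

AVOGADRO = 6.02214076e23
"""Avogadro constant (1/mol)."""

LN10 = 2.302585092994046
"""Decadic-to-natural logarithm conversion for molar extinction coefficients."""

# ---------------------------------------------------------------------------
# Methylene-blue photophysics (literature-typical values; configurable)
# ---------------------------------------------------------------------------
MB_TRIPLET_QUANTUM_YIELD = 0.52
"""Triplet quantum yield of monomeric methylene blue in aqueous solution."""

MB_EXTINCTION_GROUND_660 = 7.3e4
"""Decadic molar extinction coefficient of ground-state MB monomer at the
660 nm pump wavelength, 1/(M cm)."""

MB_GROUND_CROSS_SECTION_CM2 = LN10 * MB_EXTINCTION_GROUND_660 * 1e3 / AVOGADRO
"""Ground-state absorption cross-section sigma_g at 660 nm (cm^2/molecule),
derived from the decadic extinction coefficient."""

MB_EXTINCTION_TRIPLET_830 = 1.4e4
"""Decadic molar extinction coefficient of triplet-state MB at the 830 nm
probe wavelength, 1/(M cm)."""

MB_DIMERIZATION_K = 2.5e3
"""Monomer-dimer equilibrium constant K = [D]/[M]^2 (1/M).  At 400 uM total
dye this value puts ~50% of the dye in the photoactive monomer form."""

MB_TOTAL_CONC_M = 4.0e-4
"""Default total methylene-blue concentration loaded into the node (M)."""

PUMP_PULSE_DURATION_S = 5e-9
"""Q-switched OPO pump pulse duration (s)."""

# ---------------------------------------------------------------------------
# Stern-Volmer truth calibration derived from flash-photolysis rates
# ---------------------------------------------------------------------------
RATE_OXYGENATED_1_S = 6.05e5
"""Triplet decay rate of an air-saturated (~150 mm Hg) MB solution, 1/s."""

RATE_DEOXYGENATED_1_S = 1.84e4
"""Triplet decay rate of an argon-purged (~0 mm Hg) MB solution, 1/s."""

PO2_OXYGENATED_MMHG = 150.0
PO2_DEOXYGENATED_MMHG = 0.0

SV_K0_1_S = RATE_DEOXYGENATED_1_S
"""Oxygen-independent triplet decay rate k0 (1/s)."""

SV_KQ_1_S_MMHG = (RATE_OXYGENATED_1_S - RATE_DEOXYGENATED_1_S) / PO2_OXYGENATED_MMHG
"""Stern-Volmer quenching constant kQ (1/(s mm Hg)) implied by the two
flash-photolysis rates at 150 and 0 mm Hg."""

# ---------------------------------------------------------------------------
# Neck-tissue optical properties
# ---------------------------------------------------------------------------
TISSUE_MUA_660 = 0.22        # 1/cm
TISSUE_MUSP_660 = 9.1        # 1/cm
TISSUE_MUA_830 = 0.235       # 1/cm
TISSUE_MUSP_830 = 7.3        # 1/cm
ANISOTROPY_G = 0.9
"""Henyey-Greenstein anisotropy factor; mu_s = mu_s' / (1 - g)."""

PUMP_WAVELENGTH_NM = 660.0
PROBE_WAVELENGTH_NM = 830.0
PUMP_FLUENCE_MJ_CM2 = 10.0
PROBE_FLUENCE_MJ_CM2 = 15.0

# ---------------------------------------------------------------------------
# Geometry defaults
# ---------------------------------------------------------------------------
GRID_SIZE_MM = (40.0, 40.0, 35.0)
VOXEL_SIZE_MM = 0.4
NODE_RADIUS_MM = 3.0
BEAM_RADIUS_MM = 10.0

# ---------------------------------------------------------------------------
# Acoustics
# ---------------------------------------------------------------------------
SPEED_OF_SOUND_M_S = 1540.0
GRUENEISEN = 0.2
XDCR_CENTER_FREQ_MHZ = 5.0
XDCR_FRACTIONAL_BW = 0.6
XDCR_ELEMENT_DIAMETER_MM = 12.7
XDCR_FOCAL_LENGTH_MM = 25.0
SAMPLING_RATE_MHZ = 40.0

NEP_MPA = 2.41e-6
"""Default per-frame noise-equivalent pressure (MPa, std of the zero-mean
Gaussian sample noise).  Calibrated once so that the reference acquisition
(node at the shallowest 4 mm sweep depth, 100-frame averaging) yields an
SNR of ~100 on the averaged, artifact-corrected trace."""

# ---------------------------------------------------------------------------
# Acquisition protocol
# ---------------------------------------------------------------------------
N_DELAYS = 12
DELAY_MIN_US = 0.5
DELAY_MAX_US = 1000.0
N_AVERAGES = 100
N_REPLICATES = 7

# ---------------------------------------------------------------------------
# Depth-sweep protocol
# ---------------------------------------------------------------------------
SWEEP_DEPTHS_MM = tuple(range(4, 26, 3))          # 4 .. 25 mm, step 3
PHANTOM_SWEEP_DEPTHS_MM = tuple(range(1, 17, 3))  # 1 .. 16 mm, step 3
SWEEP_PO2_MMHG = (0.0, 150.0)
CLINICAL_ERROR_THRESHOLD_MMHG = 10.0
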
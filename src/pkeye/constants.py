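"""Physical constants, unit conversions and shipped default parameters.

All internal hydraulic computation is done in SI (Pa, m, m³/s); every user
interface speaks the bench units of the platform (mmHg, µL/min, °C). The
defaults collected here are calibration seeds: the platform publications
report relative orderings and operating points, not microstructural
constants, so pore radii / porosity / compartment transfer coefficients are
package choices that can be overridden in any config.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Unit conversions (exact contract values)
# ---------------------------------------------------------------------------
MMHG_TO_PA: float = 133.322          # 1 mmHg in Pa
PA_TO_MMHG: float = 1.0 / MMHG_TO_PA
ULMIN_TO_M3S: float = 1.0 / 6.0e10   # 1 µL/min = 1e-9 m³ / 60 s
M3S_TO_ULMIN: float = 6.0e10
SECONDS_PER_DAY: float = 86400.0
SECONDS_PER_MINUTE: float = 60.0

# ---------------------------------------------------------------------------
# Membrane defaults (calibration seeds; only relative MWCO ordering is
# experimentally constrained, so absolute values are overridable choices)
# ---------------------------------------------------------------------------
DEFAULT_MEMBRANE_THICKNESS_M: float = 30e-6     # regenerated cellulose film
DEFAULT_PORE_DENSITY_PER_M2: float = 1e12

#: MWCO (kDa) -> seed single-pore radius (m). Dialysis-membrane pore radii
#: scale sub-linearly with cut-off; these seeds preserve the measured
#: ordering (higher MWCO -> more permeable) and sit in the nanometre range
#: typical of regenerated cellulose.
DEFAULT_PORE_RADIUS_BY_MWCO_M: dict[str, float] = {
    "12-14": 2e-9,
    "50": 4e-9,
    "300": 12e-9,
}

#: Exposed clamp diameters of the pursing rigs, m.
PURSING_EXPOSED_DIAMETERS_M: tuple[float, ...] = (5.0e-3, 15.0e-3, 20.0e-3)

# ---------------------------------------------------------------------------
# Physiology / platform operating envelope
# ---------------------------------------------------------------------------
AQUEOUS_FLOW_RANGE_ULMIN: tuple[float, float] = (1.5, 3.0)
PHYSIOLOGICAL_IOP_MMHG: tuple[float, float] = (10.0, 20.0)
DEFAULT_AQUEOUS_FLOW_ULMIN: float = 2.0
SVF_VISCOSITY_RANGE_PAS: tuple[float, float] = (0.6, 0.8)
PBS_VISCOSITY_PAS: float = 1.0e-3

# Telemetry throughput caps of the acquisition chain
MAX_RECORDING_HZ: float = 50.0
MAX_CONTROLLERS: int = 6
MAX_SENSORS_PER_CONTROLLER: int = 6
DEFAULT_RECORDING_HZ: float = 1.0

# ---------------------------------------------------------------------------
# Compartment-model defaults (see docs/methods.md for the rationale; the
# published in vitro protein half-lives at 2.0 µL/min span roughly 5-15 days
# and these transfer coefficients place every membrane-bearing prototype in
# that band)
# ---------------------------------------------------------------------------
DEFAULT_POSTERIOR_VOLUME_ML: float = 4.0
DEFAULT_ANTERIOR_VOLUME_ML: float = 0.3
DEFAULT_HYALOID_TRANSFER_ULMIN: float = 0.20    # permeability-area product
DEFAULT_HYALOID_SIEVING: float = 0.05           # protein mostly rejected
DEFAULT_RCS_TRANSFER_ULMIN: float = 0.05        # tighter back membrane
DEFAULT_BACK_FLOW_ULMIN: float = 2.0

# ---------------------------------------------------------------------------
# Probe defaults
# ---------------------------------------------------------------------------
PROBE_EXCITATION_NM: float = 470.0
PROBE_INTEGRATION_WINDOW_MS: float = 250.0
DEFAULT_PROBE_READ_INTERVAL_S: float = 60.0
DEFAULT_PROBE_NOISE_SIGMA_UGML: float = 0.05
DEFAULT_PROBE_RESPONSE_FACTOR: float = 1000.0   # AUC units per (µg/mL)

#: Two-fold serial dilution of the 250 µg/mL stock used as default
#: calibration standards, µg/mL.
DEFAULT_CALIBRATION_STANDARDS_UGML: tuple[float, ...] = (
    62.5, 31.25, 15.625, 7.8125, 3.90625,
)

# ---------------------------------------------------------------------------
# Eye-movement platform defaults
# ---------------------------------------------------------------------------
ACCELEROMETER_RATE_HZ: float = 6400.0
TEMPERATURE_RATE_HZ: float = 1.0
DEFAULT_MOUNT_RADIUS_M: float = 0.10
DEFAULT_TEMPERATURE_PROBES: tuple[tuple[float, float], ...] = (
    (35.3, 0.6),   # probe 1: (setpoint °C, sigma °C)
    (34.0, 0.3),   # probe 2
)

# ---------------------------------------------------------------------------
# Flow-network defaults
# ---------------------------------------------------------------------------
DEFAULT_CONTROLLER_TIME_CONSTANT_S: float = 60.0
DEFAULT_LEAK_PRESSURE_THRESHOLD_MMHG: float = 2.0
DEFAULT_SPIKE_FACTOR: float = 2.0
DEFAULT_QC_WINDOW_S: float = 300.0
CIRCADIAN_DEFAULT_PEAK_HOUR: float = 8.0        # clock hour of maximum flow
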
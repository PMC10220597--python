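# Methods

This note documents the models behind `pkeye`, the defaults they ship
with, what the synthetic telemetry does and does not emulate, and the
numerical choices that matter.

## Membrane hydraulics

A dialysis membrane clamped over a circular area is modelled as N
identical cylindrical pores in parallel. The per-pore pressure drop is the
Poiseuille channel term plus the Sampson orifice term,
Δp = 8µTQ/(πR⁴) + 3µQ/R³, valid for low-Reynolds flow through a short
pore. The model is linear in flow, so inversion is exact, and it carries
three assumptions worth stating:

* **Uniform pores.** Real regenerated-cellulose membranes have a pore-size
  distribution; the twin's single effective radius reproduces any one
  operating point exactly but not the curvature of a full sweep.
* **Rigid membrane.** The bench observes membranes pursing (deforming)
  under pressure and breaking beyond a membrane-specific ceiling.
  Deformation is not modelled; rupture is available as an optional hard
  pressure ceiling (`burst_pressure`, default off) that raises an event.
* **Naive area scaling.** Flow scales with pore count, i.e. with the
  clamped area. The bench's own measurements scale sub-linearly (0.66 vs
  0.54 µL/min for 20 vs 15 mm diameter at 150 mmHg, where an area model
  predicts a 1.78× ratio); the discrepancy is real (edge effects,
  non-uniform pursing) and deliberately not absorbed into the model.

Membrane microstructure (thickness, porosity, pore radius) is not
published for these membranes, so absolute flow prediction from first
principles is not meaningful. The shipped values — thickness 30 µm, pore
density 10¹²/m², seed radii 2/4/12 nm for the 12–14/50/300 kDa cut-offs —
are calibration seeds chosen once to be physically plausible for
regenerated cellulose. Only *relative* statements are testable, and the
tests assert exactly those: fitted effective radii on the printed
operating points order strictly with MWCO at any common assumed
thickness/porosity.

The effective-radius fit minimises squared relative flow error. Because
model flow is Δp·N/k(R) with k(R) strictly monotone, the optimum
conductance has a closed form and the radius is recovered by bracketed
Brent root finding — no iterative least squares, no initial guess.

Units: all internal computation is SI (Pa, m³/s); interfaces use bench
units with the exact conversions 1 mmHg = 133.322 Pa and
1 µL/min = 1/6×10¹⁰ m³/s.

The stepped pressure sweep has no hysteresis by construction (the
ascending and descending branches share one model); the bench protocol was
likewise designed to minimise hysteresis, so staircase symmetry is a
stated model property, not a finding.

## Flow networks

Branches are lumped hydraulic resistances (model + tubing), mmHg per
µL/min; a parallel network under one pressure source solves as Q_i = P/R_i
with exact flow conservation. The bench's printed 1:6 spread of branch
flows (1.5–2.7 µL/min at one pressure) reflects unstated hardware
variation, so branch resistance variance is a free simulation parameter,
not a derived constant.

Flow-rate control is modelled as first-order pressure settling with a
60 s time constant (configurable); the bench only documents that pressure
is adjusted automatically, so any smooth settling law is defensible and
first-order is the simplest. Flow control is restricted to a single branch,
mirroring the physical constraint.

The circadian program is a sinusoid between configurable bounds (defaults
1.5–3.0 µL/min, 24 h period). The clock anchor of the maximum is not
documented beyond "morning"; the default places the peak at 08:00 and is
configurable.

QC detection uses robust statistics: centred rolling medians (default
300 s window) compared against expanding medians lagged by one window, so
an emerging fault cannot contaminate its own baseline. Defaults — leak
threshold 2 mmHg, spike factor 2.0 — formalise qualitative bench criteria
("pressure close to zero while flow unaltered"; "a spike in pressure").
The flow-unaltered condition is ±20% of the running flow baseline.
Contiguous flagged samples collapse to one event stamped at onset; events
cannot be flagged before one full window of baseline exists.

Telemetry obeys the acquisition chain's caps (50 Hz per channel, 6
controllers × 6 sensors, 1800 points/s aggregate), enforced by the config
validator.

## Compartmental clearance

The bench publications describe prototype geometry and flows but give no
governing equations; the two/three-compartment linear ODE here is this
package's formalisation. Masses in the posterior (V_p) and anterior (V_a)
cavities evolve by

    dM_p/dt = −(s·Q_p + PA_h)·C_p + PA_h·C_a − PA_rcs·C_p
    dM_a/dt = +(s·Q_p + PA_h)·C_p − PA_h·C_a − Q_out·C_a

with C = M/V, s the membrane sieving coefficient (fraction of convective
flux that carries drug), PA_h the hyaloid permeability–area product
(µL/min, so it adds directly to clearance terms), Q_p the posterior-routed
inflow (zero for anterior/ciliary-inflow prototypes) and PA_rcs the back
membrane of the RCS prototype, whose permeate is swept to a reservoir.
Both convective and diffusive pathways are parameterised because the bench
does not quantify which dominates. Injection is an instantaneous
well-mixed bolus displacing an equal buffer volume.

Defaults: V_p = 4.0 mL, V_a = 0.3 mL (human-scale; the physical
prototypes' cavity volumes are not published), PA_h = 0.20 µL/min,
s = 0.05, PA_rcs = 0.05 µL/min, back flow 2.0 µL/min. These were chosen
once so that every membrane-bearing prototype lands inside the published
5–15 day in vitro protein half-life band at 2.0 µL/min (first-generation
≈ 7.1 d, ciliary ≈ 10.6 d, RCS ≈ 8.3 d). The published half-lives are a
plausibility band only — fitting them would be circular, and the tests
never compare against them as point targets. Absolute half-life
prediction for a specific membrane/drug remains a calibration exercise.

Numerics: LSODA (stiff-capable, adaptive) with rtol 10⁻⁹ and atol 10⁻⁹ of
the dose, on a fixed output grid; a validator rejects output steps larger
than one tenth of the fastest compartment time constant. Mass balance
(compartments + cumulative outlets = dose) holds to ~10⁻¹⁵ relative and is
asserted to 0.1%. The test oracle is an independent fixed-step RK4
integrator at 100 substeps per output interval. Half-life estimation is
ordinary least squares on ln C vs t; the fit window must hold at least
five strictly positive samples, and non-decaying traces raise rather than
return a sign-flipped value. Because the outlet concentration rises while
the anterior cavity fills (for roughly the first day at default
parameters), terminal fits should start after the peak; `simulate_clearance`
fits the trailing half of the horizon by default.

## Eye motion

Programs transcribe the platform's published movement tables verbatim,
including their quirks: the smooth-pursuit table nets +40° (its last leg
is printed unsigned and is transcribed as positive), and the micro-saccade
table nets −1.1°. The originally commanded programs (20° in 1.8 s pursuit,
0.4° micro-saccades) differ slightly from the executed/measured ones
(20°/1.5 s, 0.55°); both ship as separate `*_programmed` presets, neither
"corrected".

The stage's internal velocity profile is not published. Profiles are
therefore configurable, defaulting to triangular — whose peak/mean ratio
of 2 reproduces the programmed pursuit maximum (22.2 vs 22°/s) — with
minimum-jerk (ratio 1.875) matching the measured pursuit peak (25.0 vs
25.18°/s). The measured micro-saccade peak/mean ratio (~1.34) matches no
standard profile and no profile is claimed to reproduce it. All profiles
integrate exactly to the programmed displacement, so net travel is
profile-independent.

The accelerometer model is a single-axis tangential sensor: a = r·α with
r the mount radius (default 0.10 m, not published, configurable),
resampled to the acquisition rate (6.4 kHz) with seeded Gaussian noise;
centripetal acceleration r·ω² is available behind a flag. Temperature
probes are Gaussian about their setpoints (defaults 35.3 ± 0.6 °C and
34.0 ± 0.3 °C at 1 Hz, the two platform probes).

## Concentration probe and valve multiplexer

The probe emits an AUC scalar linear in concentration; spectral shape,
photobleaching and inner-filter effects are not modelled, and the 470 nm
excitation / 250 ms integration window are carried as metadata and
validator constraints. The absolute extinction coefficient of the labelled
protein is not published, so the response factor is an arbitrary
configurable gain (1000 AUC per µg/mL) and only round-trip and linearity
properties are asserted, never absolute AUC values.

The probe reading noise of the physical instrument is likewise not
published. The default σ = 0.05 µg/mL is a calibration choice made once to
satisfy the two printed behaviours simultaneously: consecutive
once-per-minute readings during the decaying phase of a clearance differ
by less than 0.3 µg/mL, and the five-standard calibration line fits with
R² inside [0.99, 1.0). A larger σ (~1 µg/mL) would centre R² on the
printed 0.9942 but violate the 0.3 µg/mL bound; the shipped value keeps
both, at the cost of an R² much closer to 1 than the bench's.

Valve schedules tile the horizon exactly (no gaps, no overlaps):
round-robin (n inlets × dwell, e.g. three models every 10 min for 1 h),
alternating (model/reference, e.g. every 2 h), and duty-cycle
(on/off, e.g. 20 min through the probe every 4 h 40 min — interpreted as
a 300 min cycle because the gaps between sample runs are stated as
280 min). During waste windows the detector line is idle: no probe
samples are taken and no outflow rows are emitted, so the
outflow-equals-one-inlet invariant is asserted over routed windows.
Out-of-range readings are modelled only as zero-clipping of noisy blanks
(flagged); a configurable outlier process is deliberately out of scope.

Gapped traces are reconstructed by time-adjacency: a spacing over twice
the read interval starts a new window; each window reports its mean,
centre time, sample count and maximum successive difference.

## What the synthetic data does and does not show

The generators emulate the *recorded statistics* of the bench — Gaussian
sensor noise at documented rates, first-order controller settling, exact
valve timing — not its physics: no membrane fouling or deformation, no
tubing compliance, no evaporation, no protein aggregation or adsorption,
no motion–clearance coupling, no spectrometer optics. Passing tests
therefore demonstrate that the analysis chain (fitting, QC detection,
reconstruction) is correct under the platform's nominal noise model, not
that the underlying hardware behaves ideally.

All stochastic operations take an explicit seed; module streams are
derived from (seed, stable label) so adding a consumer never perturbs
another's draws, and identical seeds are bit-identical across runs.

## Problem sizes

Default test and script runs use 3–10 day clearance horizons at 60–600 s
output steps, 5-day telemetry at 1 Hz for QC scans, and 1000-draw
parameter sweeps for the hydraulic property checks — sizes chosen so the
full suite exercises every pathway at realistic durations while running
in seconds on a laptop.
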
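# pkeye

A desk-scale digital twin of a real-time monitoring platform for in vitro
ocular drug-delivery testing (the PK-Eye™ family of two-compartment eye
models driven by pressure-controlled microfluidics). The package simulates
every instrumented subsystem of the bench — membrane hydraulics, parallel
flow networks, compartmental drug clearance, the eye-movement stage and a
valve-multiplexed fluorescence concentration probe — and synthesises the
telemetry those instruments record, so analysis pipelines and QC logic can
be developed and tested without hardware.

It is written for pharmaceutical scientists and engineers who work with
in vitro ocular models: it answers questions like *what flow does a 300 kDa
dialysis membrane pass at 7 mmHg?*, *what does a 500 µg intravitreal bolus
look like at the outflow port over a week?*, and *will my leak detector
fire on five days of noisy pressure–flow telemetry?*

## Models at the core

**Membrane hydraulics.** The pressure drop across one pore of a thin
porous membrane is the sum of Poiseuille (channel) and Sampson (orifice)
terms,

    Δp = 8µTQ/(πR⁴) + 3µQ/R³

with µ the fluid's shear viscosity, T the membrane thickness, R the pore
radius and Q the per-pore flow. The relation is linear in Q and inverts
analytically; total flow through a clamped circular area scales with the
pore count. An effective pore radius can be fitted to measured
pressure–flow pairs (the printed bench operating points ship as a fixture
table), and the bench's automated up/down pressure staircase is simulated
with seeded sensor noise.

**Flow networks.** One pressure source feeding up to six eye models in
parallel behaves Ohmically: Q_i = P/R_i per branch, pressure common to all.
Flow-rate control regulates exactly one branch (as on the bench). A
circadian program varies inflow sinusoidally between the nocturnal
(1.5 µL/min) and morning (3.0 µL/min) aqueous secretion rates over 24 h,
and a QC scanner flags leaks (pressure collapses toward zero while flow is
unchanged) and blockages (pressure spikes above its running baseline).

**Compartmental clearance.** Each prototype is a pair of well-mixed
compartments (posterior ≈ 4 mL, anterior ≈ 0.3 mL) separated by a
dialysis membrane crossed by convective (sieving × posterior flow) and
diffusive (PA product) fluxes, with anterior washout at the aqueous flow
rate; the RCS prototype adds a posterior elimination route through a
second membrane. Terminal half-life is estimated from any concentration
trace by log-linear regression (t½ = ln 2/|slope|), and the shipped
defaults put all membrane prototypes in the 5–15 day band reported for
proteins at 2.0 µL/min.

**Eye motion and probe.** Movement programs (smooth pursuit, scene
saccades, micro-saccades) are segment lists executed under a configurable
velocity profile (rectangular / triangular / minimum-jerk, peak-to-mean
ratios 1 / 2 / 1.875); accelerometer (6.4 kHz) and temperature (1 Hz)
telemetry are synthesised from the trajectory. The virtual concentration
probe converts signal AUC to µg/mL through a fitted linear calibration and
is time-shared between flow lines by round-robin, alternating or
duty-cycle valve schedules; gapped traces are reconstructed window by
window.

## Worked example

Simulate a 500 µg intravitreal bolus clearing through the
first-generation prototype at 2.0 µL/min, then read the outlet with the
probe:

```python
import pkeye
from pkeye import compartment_pk as pk, probe as pr

model = pk.EyeModelConfig(prototype="first_generation", aqueous_inflow=2.0)
drug = pk.DrugSpec.from_concentration("labelled-albumin", 5.0, 100.0)  # 500 µg
result = pk.simulate_clearance(model, drug, duration=3 * 86400, step=60.0)
print(f"terminal half-life: {result.half_life:.2f} days "
      f"(R² {result.fit_r2:.4f})")
print(f"mass balance error: {result.mass_balance_error():.2e}")
```

prints

```
terminal half-life: 7.07 days (R² 1.0000)
mass balance error: 6.82e-16
```

— the bolus leaves the posterior cavity with a ~7-day terminal half-life
(within the published in vitro protein range) and the integrator conserves
the dose to machine precision. The same model through the command line:

```bash
pkeye simulate-clearance --prototype first_generation \
    --out-csv traces.csv --out-json report.json
pkeye circadian --out circadian.csv
pkeye motion --preset smooth_pursuit --out-csv traj.csv --out-json kin.json
```

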
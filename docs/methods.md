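# Methods

## Model

Both piezoresistors on the chip follow empirical quadratic
resistance–temperature laws over the calibrated band:

    R_OC(T)  = c2·T² + c1·T + c0          (on-chip fixed resistor, TCR only)
    R_MCL(T) = c2'·T² + c1'·T + c0'       (suspended resistor, TCR + bimorph)

The built-in reference laws are

    R_OC(T)  = 1.422×10⁻³ T² + 8.428×10⁻² T + 2719      [Ω, T in °C]
    R_MCL(T) = 1.085×10⁻³ T² + 9.861×10⁻¹ T + 2667      [Ω, T in °C]

calibrated on 20–70 °C. Both are strictly increasing there; the constructor
rejects any curve whose derivative changes sign on its declared band, which is
what makes the closed-form inversion single-valued.

Compensation is a per-sample, stateless transform (the only state is the
optional filter), so it runs on-line:

    T_sys   = R_OC⁻¹(r_oc[i])
    V_Com   = −V·(R_MCL(T_sys) − R_bal)/(4·R_bal)·g
    V_Out   = V_MCL − V_Com                (optionally low-pass filtered)

Exact cancellation of the thermal path and exact transparency to any additive
binding signal are algebraic identities of this flow; both are asserted as
tests at 1 nV / float precision.

## Assumptions

- The two resistors see the same temperature (on the real chip they are
  ~100 µm apart; a liquid-phase gradient between them is a residual error the
  method cannot remove).
- The calibration laws are stable between calibration and measurement
  (hysteresis is characterized, not corrected).
- The bridge operates in its linear small-signal regime, ΔR/R = −4ΔV/V.
- Binding enters as an additive resistance change k_sigma·σ(t) on the
  cantilever arm only.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| bridge supply V | V | 0.3 | reference instrument's operating point |
| amplifier gain g | — | 1000 | reference preamplifier |
| quarter factor | — | 4 | quarter-bridge small-signal relation |
| balance R_bal | Ω | first-sample R_MCL(T_sys) | gives V_Com and V_MCL a common zero; the subtraction is then meaningful without knowing the instrument's trim |
| low-pass cutoff | Hz | 0.1 | reference readout chain; order-1 exact-pole (impulse-invariant) discretization, DC gain exactly 1, initialized at the first sample |
| sample interval | s | 1 | acquisition rate is not otherwise pinned down; 1 Hz resolves the 0.1 Hz filter comfortably |
| meter quantization | Ω | 0.1 | digital multimeter accuracy |
| invert margin | °C | 5 | tolerated extrapolation beyond the calibration band for direct `invert` calls (warn inside, error outside) |
| k_sigma | Ω/(N/m) | 0.5 | **placeholder**: the true stress-to-resistance constant of the five-layer stack is a device property not derivable here; 0.5 makes a −3.1 N/m event ≈ 1.55 Ω ≈ 43 µV pre-amplifier, the observed order of magnitude. It must be the same constant on the simulation and analysis sides; round-trip identities then hold for any value |

Thermal sensitivities are always quoted **pre-amplifier** (slope divided by
g): the conventional figures for a 0.3 V bridge (tens of µV/°C uncompensated,
sub-µV/°C compensated) are only consistent at that level.

## Inversion and out-of-band samples

`invert` uses the cancellation-free (q-method) quadratic formula and selects
the root on the same side of the parabola vertex as the calibration band —
exactly one root can be admissible for a monotonic curve. Direct calls enforce
the ±5 °C margin; two roots inside the admissible band (only possible if the
monotonicity invariant is bypassed) raise an ambiguity error rather than a
silent choice.

The streaming path deliberately does **not** enforce the margin. The on-chip
thermometer is shallow (dR_OC/dT ≈ 0.12–0.2 Ω/°C), so with realistic meter
noise a single sample can imply a temperature tens of °C outside the band; a
streaming compensator must flag such samples (they are counted and logged) and
keep running, not abort a detection run. Only a resistance with no real
preimage (beyond the parabola extremum) raises, with the sample index.

## The simulator

`sensor_sim` generates what the instrument records: the two calibration laws
evaluated along a prescribed temperature path, plus k_sigma-scaled binding
stress on the cantilever arm, plus white Gaussian resistance noise, quantized
to the meter step (nearest multiple, half-up), then the amplified bridge
conversion. Traces are bit-reproducible from the scenario seed; the on-chip
noise vector is drawn before the cantilever noise vector from a single
`default_rng(seed)`.

Three bundled scenarios mirror the reference experiments in shape:

- `fig7_ramp` (seed 7): 1800 s at 1 Hz, linear 13.6 → 40.7 °C, noise 0.5 Ω —
  the thermal-sensitivity benchmark;
- `fig8_liquid` (seed 8): 25 200 s, sinusoidal ±0.9 °C ambient swing
  (1.8 °C change over ~3 h), no binding, noise 0.05 Ω;
- `fig9_crp` (seed 9): 3600 s, one −3.1 N/m compressive event (first-order
  kinetics, τ = 400 s, onset 600 s) under a −2 °C linear drift, noise 0.05 Ω.

Noise levels: 0.5 Ω for the ramp benchmark is the documented stress-test
condition for that experiment; elsewhere the default is 0.05 Ω — half the
meter's least significant digit, the standard dither level at which the
quantization staircase averages out of slow drifts (at much smaller noise the
staircase would bias window means; at 0.5 Ω the thermometer becomes the
dominant noise source).

What the simulator does **not** emulate: physical multimorph bending (the
printed empirical laws *are* the ground truth — no layer-mechanics model is
fitted; the layer stack is metadata used only for geometry checks), bubble and
flow-field artifacts beyond white noise, thermal gradients between the two
resistors, calibration drift/hysteresis, and 1/f electronics noise. Passing
tests therefore demonstrate the correctness and self-consistency of the
signal-processing chain, not the behaviour of real hardware; hardware-bound
statistics (thermometer agreement, hysteresis band, sweep CV) are implemented
as operations over supplied data, with simulated inputs in the tests.

## Statistical behaviour of the noisy protocols

Two of the recomputed quantities are estimates from prescribed noisy
protocols, and their seed-to-seed spread follows from OLS algebra (the test
suite computes the standard errors from the design matrix rather than
hard-coding them):

- Quadratic refit on 101 points (σ = 1 Ω, 20–70 °C): SE(c0) ≈ 1.0 Ω and
  SE(c1) ≈ 0.048 Ω/°C — the constant term is an extrapolation to 0 °C from a
  20–70 °C design, which is why its SE is as large as the noise itself.
  Recovery is asserted within 3 SE (and verified to hold in ≥ 95 % of 200
  seeded replicates).
- Ramp residual sensitivity: with σ = 0.5 Ω on a ~0.16 Ω/°C thermometer the
  inferred temperature carries ~3 °C of white noise, which propagates to the
  predicted cantilever resistance and puts the OLS slope's standard error
  near 0.29 µV/°C over a 27 °C ramp. The slope estimate is therefore a
  half-normal draw at roughly that scale: typically ~0.2 µV/°C, i.e. a
  ~100-fold reduction from the ≈29 µV/°C uncompensated drift, but individual
  seeds can land several-fold higher. A DC-gain-1 low-pass does not reduce
  this spread (slope estimation senses the noise spectrum at DC). The
  residual slope should be regressed against an independent temperature
  record where available; against the inferred T_sys it acquires an
  errors-in-variables bias of a few µV/°C under heavy thermometer noise.

## Numerical choices

- Fits are unweighted OLS on the Vandermonde system (homoscedastic meter
  noise); the fitted band is the data extent; rms residual is stored with the
  curve.
- Quadratic roots via the q-method (stable down to c2 → 0); c2 = 0 falls back
  to the linear solution.
- Quantization ties round half-up; step 0 disables quantization exactly.
- The low-pass uses a = 1 − exp(−dt/RC) per section so the discrete step
  response equals the continuous RC response at sample instants; DC gain is
  exactly 1 by construction.
- CSV round-trips are value-exact (`float_precision="round_trip"` on read,
  repr-based formatting on write); calibration JSON round-trips bit-exactly.
- Thermometer statistics match sweeps on a 0.1 °C grid (nearest cell); the CV
  pools per-sweep cell means and averages the per-cell CVs; the hysteresis
  band is the mean per-cell half-range, mapped to °C through the pooled
  fitted dR/dT.

## Detection summaries

A run's signal is read as (mean of the last window) − (mean of the first
window) of V_Out, default window 300 s, converted to stress. With the default
CRP-like scenario the first-order binding has saturated to < 0.2 % by the end
of the run, so the endpoint estimate is essentially unbiased; window-mean
noise contributes ~2 % at the default noise level.

## Problem sizes

Default runs are 1800–25 200 samples at 1 Hz; the full test suite plus the
acceptance recomputation completes in a few seconds on one core. These sizes
put the estimators comfortably into their asymptotic regime while keeping the
package trivially re-runnable.

## Known limitations

- The two printed laws are internally tense: the on-chip law's linear
  coefficient is ~10× smaller than the cantilever's, so the uncompensated
  drift implied by the laws (≈29 µV/°C over the ramp band) cannot be decomposed
  into the conventionally quoted TCR ≫ bimorph split. The package treats the
  laws as ground truth and does not attempt that decomposition.
- k_sigma is a placeholder (see above); absolute stress values from real
  hardware require an independently determined constant.
- The shallow on-chip thermometer is the accuracy bottleneck: 0.1 Ω of meter
  resolution is already ±0.5–0.8 °C of temperature resolution on this device.
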
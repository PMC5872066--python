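# canticomp

Real-time thermal self-elimination for single free-standing piezoresistive
microcantilever (MCL) biosensors.

## The problem

Label-free MCL biosensors transduce molecular binding into surface stress: the
beam bends, an embedded piezoresistor strains, and a quarter Wheatstone bridge
turns the resistance change into a voltage. In a *single-beam* configuration
(no reference cantilever) the dominant confounder is temperature, through two
effects at once: the temperature coefficient of resistance (TCR) of the
piezoresistor, and thermal (bimorph) bending of the multilayer beam. Ambient
drifts of a couple of °C produce voltage excursions far larger than a typical
protein-binding signal, so without correction the biological signal is
unreadable unless the whole instrument sits in a thermostat.

`canticomp` implements the software side of a thermostat-free alternative: an
*on-chip fixed piezoresistor* — same material, not released, hence TCR-only —
serves as a thermometer, and two empirical calibration laws turn its reading
into a prediction of the thermally induced cantilever signal, which is
subtracted in real time.

## The method

Calibration (once, in a temperature-controlled sweep) yields two quadratics:

    R_OC(T)  = a T² + b T + c      (on-chip fixed resistor: TCR only)
    R_MCL(T) = d T² + e T + f      (suspended MCL resistor: TCR + bimorph)

At run time, each sample flows through

    R_OC  →(invert first law)→  T_sys  →(second law)→  R_MCL,predicted
          →(bridge: ΔR/R = −4ΔV/V)→  V_Com,     V_Out = V_MCL − V_Com

The compensated output `V_Out` carries only the binding signal, which converts
to a surface-stress change Δσ (N/m, negative = compressive) through the bridge
relation and a transduction constant `k_sigma` (Ω per N/m).

The package provides, as both a library and a `canticomp` CLI:

- `calibration` — quadratic fitting (OLS), evaluation, closed-form monotonic
  inversion, thermometer validation statistics (agreement, hysteresis band, CV);
- `compensation` — bridge conversion, causal low-pass, the streaming
  compensation flow, residual thermal sensitivity (µV/°C, pre-amplifier);
- `sensor_sim` — a seeded simulator producing raw traces (meter quantization
  0.1 Ω, Gaussian resistance noise, binding events with first-order kinetics)
  from the calibration laws of a reference device, plus its five-layer
  geometry (200 × 150 µm, 1.265 µm stack);
- `stress` — voltage → surface-stress conversion and detection summaries;
- `io` / `cli` — unit-suffixed CSV formats, calibration-law JSON, subcommands
  `simulate`, `calibrate`, `compensate`, `analyze`.

## Worked example

Simulate a 30-minute 13.6 → 40.7 °C thermal ramp (no binding), then compensate
it with the device's calibration laws:

```sh
$ canticomp simulate --scenario fig7_ramp --out ramp.csv
wrote 1800 samples to ramp.csv
$ canticomp compensate --run ramp.csv --oc-cal oc.json --mcl-cal mcl.json --out ramp_out.csv
compensated 1800 samples; residual thermal sensitivity 0.721 uV/degC (pre-amplifier) -> ramp_out.csv
```

The uncompensated trace drifts at ≈ −29 µV/°C (pre-amplifier, 0.3 V bridge);
after compensation the residual slope is well under 1 µV/°C — the thermal
signal is eliminated to the level of the meter noise. A CRP-like detection run
(−3.1 N/m compressive binding event under a −2 °C ambient drift) recovers the
injected stress:

```sh
$ canticomp simulate --scenario fig9_crp --out traces.csv
wrote 3600 samples to traces.csv
$ canticomp compensate --run traces.csv --oc-cal oc.json --mcl-cal mcl.json --out out.csv
$ canticomp analyze --run out.csv --summary out.summary.json --out summary.json
surface stress change -3.1 N/m (compressive) -> summary.json
$ cat summary.json
{
  "sigma_final_Npm": -3.0999128479872393,
  "sign_label": "compressive",
  "v_out_final_V": 0.04317653350693442,
  "baseline_window_s": 300.0
}
```

`sigma_final_Npm` is the endpoint-minus-baseline stress estimate: the −3.1 N/m
event is recovered to 0.03 % despite the concurrent thermal drift, whose naive
(uncompensated) estimate would be off by more than a factor of two. The
calibration JSON files here are the built-in laws
(`canticomp.default_onchip_curve()` / `default_mcl_curve()` written with
`canticomp.io.write_calibration`); fit your own from sweep CSVs with
`canticomp calibrate`.

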
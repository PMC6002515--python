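# intermit

Intermittent sensorimotor control as discrete decisions about prediction
errors: a simulation and analysis toolkit.

Sustained human control — tracking a cursor, keeping a car in its lane —
often looks continuous but is arguably built from discrete, ballistic
**motor primitives**: stereotyped stepwise control adjustments, scalable in
amplitude and superposed in time. `intermit` implements a task-general
computational model of this idea and the analysis methods needed to test
it against recorded 1-D control signals:

- **Simulation** of closed-loop intermittent control: a noisy evidence
  accumulator integrates the control-error *prediction error*
  ε(t) = P_r(t) − P_p(t); at threshold it resets and issues a bell-rate
  stepwise adjustment of amplitude g̃ᵢ = K′(1+mᵢ)ε(tᵢ), while a
  corollary-discharge-like *prediction primitive* H is superposed onto the
  internal prediction P_p. Perceptual laws: cursor tracking
  (P = −(C − C_T)) and the two-point driver steering law
  (P = k_nI·θ_n + k_nP·θ̇_n + k_f·θ̇_f), with a linear single-track
  ("bicycle") vehicle model and a band-limited yaw-rate road disturbance.
- **Reconstruction** of a recorded control signal as a sequence of
  stepwise adjustments: Gaussian smoothing, rate-peak onset detection
  (onsets dated T_peak = τ_m + ΔT/2 before each rate peak), and
  overdetermined least squares for the amplitudes, with over-fit
  diagnostics and summary metrics.
- **Model fitting**: grid-search of the two-point gains against adjustment
  amplitudes or control rates (continuous / intermittent / predictive
  variants, R² objective, paired bootstrap comparison), and timing-model
  fitting (evidence accumulation vs. noisy threshold with refractory
  period) by binned χ² = Σ (Oⱼ−Eⱼ)²/(Eⱼ+1) with grid search plus bounded
  local refinement.

The model's key behavioural signatures: intermittent control
"masquerades" as continuous control once averaged; the prediction
acknowledges the currently observed error at each adjustment onset;
inter-adjustment intervals are right-skewed (first-passage times); and
without accumulator/motor noise, amplitude falls with interval length
(integrating a small error for a long time equals integrating a large
error briefly).

## Worked example

```python
import numpy as np
from intermit import (ControllerSpec, SteeringTask, StraightRoad, TwoPointLaw,
                      BicycleSpec, DisturbanceSpec, simulate,
                      build_H_steering_from_spec, generate_fixture, reconstruct)
from intermit.core import AccumulatorSpec

# closed-loop lane keeping at the default parameter set
plant = BicycleSpec.lane_keeping()                 # 97 km/h single-track model
ctl = ControllerSpec(sigma_m=0.8,                  # motor noise s.d.
                     accumulator=AccumulatorSpec(k=200.0, sigma_a=0.8))
ctl.H = build_H_steering_from_spec(plant, ctl.shape, ctl.tau_p)
task = SteeringTask(StraightRoad(), TwoPointLaw(), plant,
                    DisturbanceSpec(sigma_R=0.02))
trace = simulate(ctl, task, 120.0, seed=1)
dts = np.diff([e.t for e in trace.events])
print(f"{len(trace.events)} adjustments in 120 s ({len(trace.events)/120:.2f} Hz)")
print(f"median inter-adjustment interval: {np.median(dts):.2f} s")

# reconstruct a known stepwise signal
fx = generate_fixture(n_events=50, seed=4)
res = reconstruct(fx.series)
print(f"fixture: {res.n} adjustments recovered, "
      f"err99 = {res.metrics['err99']:.2e} deg, "
      f"compression = {res.metrics['compression']:.3f}")
```

Output:

```
133 adjustments in 120 s (1.11 Hz)
median inter-adjustment interval: 0.73 s
fixture: 50 adjustments recovered, err99 = 2.53e-13 deg, compression = 0.982
```

The simulated adjustment rate (~1.1 Hz) sits where routine human lane
keeping does; the reconstruction recovers all fifty ground-truth
adjustments essentially exactly, storing the signal as ~1.8% of its
samples.

There is also a CLI (`intermit simulate|reconstruct|fit-amplitude|
fit-timing|make-fixture|sweep-sigma-i`); every run logs its configuration
hash, seed and package version for bit-identical reproduction.

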
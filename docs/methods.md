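# Methods

## Model

One-dimensional sustained control is modelled as a sequence of discrete
control adjustments. The controller perceives a scalar control error
P(t) — the needed control adjustment, in control units — through a
perceptual delay τ_p: P_r(t) = P(t − τ_p). An internal prediction P_p(t)
of this quantity is maintained, and the difference

    ε(t) = P_r(t) − P_p(t)

(the control-error *prediction error*) drives a two-sided evidence
accumulator

    dA/dt = γ[η(ε)] − λA + ν,   ν ~ N(0, σ_a²·Δt) per step,

with gating γ(x) = sgn(x)·max(0, |x| − η₀) and linear activation
η(ε) = k·ε by default. Thresholds sit at ±1 (arbitrary activation units).
On reaching a threshold the activation resets to exactly zero and an
adjustment is issued: a stepwise change of the control signal with unit
profile G(t) (zero until the motor delay τ_m, one after τ_m + ΔT) whose
rate dG/dt is a Gaussian bell truncated at ±2 SD of its envelope
(mean τ_m + ΔT/2, SD ΔT/4), renormalised to unit integral. The amplitude
is g̃ᵢ = K′·(1+mᵢ)·ε(tᵢ) with signal-dependent motor noise
mᵢ ~ N(0, σ_m²). Control is the linear superposition
C(t) = C₀ + Σ g̃ᵢ G(t − tᵢ).

Simultaneously a *prediction primitive* H — a template of how the
perceived error is expected to decay in response to one adjustment — is
superposed: P_p(t) = Σ ε̃ᵢ H(t − tᵢ), with ε̃ᵢ = (1+mᵢ)ε(tᵢ) the efference
copy of what was actually issued. H jumps to one just after the onset
(thereby "acknowledging" the currently observed error: in the noise-free
limit, P_p immediately after an onset equals P_r at the onset) and falls
back to zero by a horizon T_p. For the cursor plant, where the control
signal is itself the controlled quantity, H(t) = 1 − G(t − τ_p). For
steering, H(t) = 1 − ω_G(t − τ_p)/S(v_x), where ω_G is the vehicle's
yaw-rate response to a unit steering adjustment G and S(v_x) its
steady-state yaw-rate gain; this is exact for pure yaw-rate errors and an
approximation otherwise.

With K′ equal to the continuous-law gain times ΔT, the window-averaged
intermittent output closely approximates the continuous law — the model
"masquerades" as continuous control.

## Perceptual laws and units

Cursor tracking uses P = −(C − C_T). Steering uses the two-point law
P = k_nI·θ_n + k_nP·θ̇_n + k_f·θ̇_f, where θ_n, θ_f are signed bearings of
centreline preview points at arc distances v_x·T_n and v_x·T_f ahead of
the vehicle's centreline projection (T_n = 0.25 s, T_f = 2 s). Bearing
rates are central differences over a short virtual kinematic advance of
the vehicle (±half a sample, lateral velocity and yaw rate held), which
handles straight and circular roads uniformly; the residual error is
O(h²) and negligible against the gains.

**Units.** The steering signal is in steering-wheel degrees throughout,
and the visual angles entering the two-point law are expressed in degrees
(rates in deg/s), so the default gains k_nI = 0.02, k_nP = 0.2 s,
k_f = 1.6 s map degrees to degrees. This choice makes the three scales
mutually consistent: typical lane-keeping yaw rates (~0.5 deg/s) map to
adjustment amplitudes of a few tenths of a degree up to a few degrees,
the same scale as the amplitude-distribution bins (0–3°, 0.25° wide) and
the threshold-model parameters (ε₀ in tenths of degrees). A radian
convention would shrink all model amplitudes by ~57× and leave those
scales unreachable. A single sign convention applies everywhere: lateral
offset, heading, yaw rate, bearing angles and steering angle are positive
leftward.

## Plant and road disturbance

The vehicle is a linear single-track model over (v_y, ω) driven by the
steering-wheel angle, advanced by exact zero-order-hold discretisation;
global pose integrates by forward Euler from the updated states. Default
physical parameters (mass 1500 kg, yaw inertia 2500 kg·m²,
axle distances 1.4/1.4 m, cornering stiffnesses 100/100 kN/rad, steering
ratio 16:1; speeds 97 km/h lane keeping, 43 km/h circle) describe a
neutral-steering saloon chosen for two properties: the yaw dynamics are
overdamped (monotone yaw-rate response to a steering step), and the
default two-point gains are *attuned* to the vehicle — an adjustment of
the amplitude the law calls for cancels close to all (≈108%) of the error
it responds to, so corrections do not systematically spawn corrective
cascades. `fit_bicycle_matrices` supports data-driven matrices instead.

The road disturbance is Gaussian white noise low-passed by a third-order
Butterworth filter at 0.5 Hz and rescaled so the signal's sample s.d.
equals σ_R (default 0.02 rad/s). It enters the vehicle as a weak forcing
on the yaw-acceleration channel, ω̇ += c_R·d(t) with coupling
c_R = 0.01 s⁻¹, i.e. filtered and damped by the vehicle's own yaw
dynamics rather than written onto the yaw rate directly. The coupling was
calibrated once, as a property of the study conditions, so that the
noise-free closed loop operates in the regime the framework describes —
infrequent adjustments (~0.5 Hz) triggered by slow error accumulation,
rising to ~1.1 Hz (the rate observed in routine human lane keeping) at
the full default noise levels. Stronger couplings push the
prediction-error pathway into multi-hertz chatter in which the
accumulator and motor noise parameters no longer shape behaviour.

## Reconstruction method

A recorded signal C(j) is smoothed with a unit-mass Gaussian kernel
(s.d. σ_I; defaults 0.1 s for lane keeping, 0.06 s for the circle task;
reflective edges). Local extrema of the smoothed rate whose magnitude
exceeds a prominence threshold become adjustment rate peaks; onsets are
dated T_peak = τ_m + ΔT/2 earlier. The default prominence is adaptive:
twice a robust (MAD-based) estimate of the s.d. of the smoothed rate's
first difference, floored at 10⁻³ of the rate range so numerically flat
stretches cannot spawn spurious peaks — a plain standard deviation is
inflated by the adjustment peaks themselves and misses small genuine
adjustments. Amplitudes then solve the overdetermined system
C = G·g (all-ones column plus shifted unit primitives) by a stable
least-squares factorisation, not the explicit normal-equations inverse;
duplicate onsets are merged with a warning. An adjustment whose fitted
peak rate |g̃ᵢ|·max(dG/dt) exceeds 1.25× the observed rate at its peak
time is flagged as a possible over-fit. Metrics: 99th-percentile absolute
reconstruction error, adjustment frequency, compression 1 − (n+1)/N, and
the fraction of consecutive samples with zero change at the recording
resolution (|ΔC| below half the 0.1° quantisation step).

## Fitting procedures

**Amplitudes.** Gains are grid searched exhaustively (continuous grid
k_nI ∈ {0, 0.01, …, 0.20}, k_nP ∈ {0, 0.1, …, 2}, k_f ∈ {0, 0.4, …, 12};
intermittent grids are these scaled by ΔT = 0.4 s), minimising SSE
against either control rates (continuous model, predictors delayed by
τ_d = 0.2 s) or reconstructed amplitudes (intermittent model, predictors
at τ_p + τ_m + ΔT/2 = 0.2 s before the rate peak); the predictive variant
subtracts P_p(tᵢ), built from the reconstructed amplitudes with K′ = 1,
from the model's prediction. R² = 1 − SSE/SST; ties keep the
lexicographically first combination. Paired model comparison uses a
drivers-resampling bootstrap (default 10 000 resamples); the one-sided
p-value is the fraction of resampled mean R² differences ≤ 0, ties
counted in.

**Timing.** Candidate timing models — the accumulator, and a classical
alternative that triggers when the time since the previous adjustment
exceeds Δ_min and |ε + ν_t| ≥ ε₀ with fresh ν_t ~ N(0, σ_t²) each step
(two-sided in magnitude, since steering needs both directions; the
amplitude rule is unchanged) — are fitted by simulating duration-matched
closed-loop lane keeping per parameter combination, counting events in
fixed 2-D bins over (inter-adjustment interval, |amplitude|) with edges
{0, 0.2, …, 6, ∞} s × {0, 0.25, …, 3, ∞}°, and minimising
χ² = Σ (Oⱼ−Eⱼ)²/(Eⱼ+1); the +1 tolerates empty model bins. All grid
points are evaluated with a common seed derived from the master seed
(common random numbers: deterministic objective, no selection bias toward
lucky draws), optionally averaging several repetitions per point when the
matched duration is short. The grid optimum is refined by a bounded
Powell search (box constraints at the grid extents, all evaluations on
one common seed); the refined χ² is never worse than the grid optimum
re-evaluated on that seed.

## Numerical choices

- Simulation step Δt = 1/60 s by default (the recording rate); delays are
  rounded to the nearest whole sample.
- Accumulator: Euler update; noise added after the drift term; threshold
  tested after the full step, boundary-inclusive; crossings dated at the
  step's end (error ≤ Δt); reset to exactly zero, accumulation of new
  input resumes the next step; no residual carried over.
- Delay buffers are back-filled with the t = 0 value of the delayed
  signal, avoiding spurious start-up transients.
- The bell profile uses the analytic truncated-normal CDF/PDF (exact, no
  quadrature); G and dG/dt are exactly 0/1 outside their supports, so an
  event's final contribution to C is exactly its amplitude.
- Zero-amplitude events (mᵢ = −1) are retained: they reset the
  accumulator and contribute a zero prediction.
- Adjustments may overlap without bound (pure superposition).
- The steering H is clipped to zero beyond the first time it decays below
  10⁻³, which defines T_p; the tracking H has T_p = τ_p + τ_m + ΔT
  exactly.
- Rate-peak ties within one sample keep the earlier peak; grid-search
  ties keep the first (lexicographically smallest) combination.
- A master seed spawns independent streams for accumulator noise, motor
  noise and the road disturbance, so switching one source off does not
  perturb the others' draws; identical specification and seed give a
  bit-identical trace.
- Target step inputs place the pre-step value on the t = 0 sample
  (target = 0 for t ≤ 0), so the onset chain τ_p + 1/k + τ_m lands on the
  grid exactly.

## Synthetic data: what it does and does not emulate

The generators reproduce the statistical structure the analyses assume:
Gaussian accumulator noise, signal-dependent motor noise, the
band-limited yaw disturbance, 60 Hz sampling, optional 0.1° quantisation
and white measurement noise, step and non-harmonic sum-of-sines targets
(components below 0.5 Hz), a straight lane and a 50 m circular track.
They do not emulate: realistic magnitudes of lateral lane deviation
(with the weak disturbance coupling the simulated vehicle wanders
centimetres, not decimetres), driver-to-driver heterogeneity, drifting
parameters, non-Gaussian disturbance events (potholes, wind gusts), or
visual-system detail behind the two-point angles. Passing tests therefore
demonstrate internal consistency of the framework and correctness of the
algorithms — parameter recovery, model discrimination on model-generated
data, reconstruction fidelity — not that the model explains human data;
that requires recorded steering.

Test problem sizes are deliberately desk-scale: 5 simulated minutes and
reduced grids for timing-model recovery (with the grid spanning the noise
parameters, which dominate identifiability at that scale — the
accumulator gain k is barely identifiable from noise-dominated
triggering), 10 simulated minutes and five seeds for the distribution
signatures. The threshold-model grid used in those checks is placed on
the scale of the synthetic model's own prediction errors (σ_t, ε₀ of
hundredths of a degree) so the alternative competes at its best rather
than as a strawman.

## Known limitations

- The steering prediction primitive treats every error as a yaw-rate
  error; position and heading errors are corrected through sequences of
  adjustments rather than one-shot, as intended by the design, but this
  makes closed-loop behaviour sensitive to the attunement between the
  two-point gains and the vehicle.
- The circle task uses preview points on the centreline for both near and
  far points; a tangent-point far point is not implemented, so circle
  behaviour is qualitative.
- The activation function is linear in all shipped analyses; a saturating
  activation is pluggable but untested against data.
- Leakage (λ) and gating (η₀) are implemented and tested mechanically,
  but no shipped result depends on them.
- The linear vehicle model has no tyre saturation, so the near-limit
  circle task is outside its regime of quantitative validity.
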
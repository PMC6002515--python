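"""Task-general intermittent controller.

Sustained one-dimensional control is modelled as a sequence of discrete,
stereotyped control adjustments. A noisy evidence accumulator integrates the
control-error *prediction error* ``eps = P_r - P_p``, where ``P_r`` is the
perceptually delayed control error and ``P_p`` an internal prediction of it.
When the accumulator reaches a threshold it is reset and a new motor
primitive is issued: a stepwise change of the control signal with a
bell-shaped rate profile, with amplitude proportional to the triggering
prediction error (plus signal-dependent motor noise). Simultaneously a
*prediction primitive* -- a corollary-discharge-like template of how the
control error is expected to decay in response to the adjustment -- is
superposed onto the running prediction ``P_p``.

With the intermittent gain ``Kprime`` equal to the continuous-law gain times
the adjustment duration, the averaged output of this controller closely
"masquerades" as the continuous law it generalises.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
from scipy.special import ndtr

from .series import UniformSeries

__all__ = [
    "PrimitiveShape",
    "PredictionPrimitive",
    "AccumulatorSpec",
    "AdjustmentEvent",
    "ControllerSpec",
    "ControllerTrace",
    "AccumulatorTrigger",
    "SimulationDiverged",
    "accumulator_step",
    "check_trigger",
    "make_adjustment",
    "control_signal",
    "control_rate",
    "prediction_signal",
    "simulate",
    "simulate_continuous_tracking",
    "first_rate_departure",
]

#: Half-width of the bell rate profile, in standard deviations of the
#: underlying Gaussian: the rate spans +-2 SD of its Gaussian envelope.
_BELL_SD_SPAN = 2.0


@dataclass(frozen=True)
class PrimitiveShape:
    """Stereotyped stepwise motor primitive.

    The unit primitive ``G(t)`` is zero up to the motor delay ``tau_m``,
    rises to one over the adjustment duration ``duration``, and stays at one
    thereafter. Its rate ``dG/dt`` is a bell: the density of a Gaussian with
    mean ``tau_m + duration/2`` and standard deviation ``duration/4``,
    truncated to the open interval ``(tau_m, tau_m + duration)`` (i.e. +-2
    standard deviations) and renormalised to unit integral. ``G`` is the
    corresponding (analytic) truncated-Gaussian CDF.

    Scaled by an amplitude, the primitive produces a smooth step of the
    control signal resembling a minimum-jerk movement.
    """

    duration: float = 0.4
    tau_m: float = 0.1

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("primitive duration must be positive")
        if self.tau_m < 0:
            raise ValueError("motor delay must be nonnegative")

    @property
    def mu(self) -> float:
        """Centre of the bell (time of peak rate)."""
        return self.tau_m + self.duration / 2.0

    @property
    def sd(self) -> float:
        """Standard deviation of the Gaussian envelope of the rate."""
        return self.duration / (2.0 * _BELL_SD_SPAN)

    @property
    def t_end(self) -> float:
        """Time at which the primitive is complete, ``tau_m + duration``."""
        return self.tau_m + self.duration

    @property
    def t_peak(self) -> float:
        """Offset from onset to the rate peak, ``tau_m + duration/2``."""
        return self.mu

    @property
    def _mass(self) -> float:
        # probability mass of the Gaussian inside +-2 SD
        return 2.0 * ndtr(_BELL_SD_SPAN) - 1.0

    def step(self, t) -> np.ndarray | float:
        """Unit step profile ``G(t)``; 0 for ``t <= tau_m``, 1 beyond the end."""
        t = np.asarray(t, dtype=float)
        z = (t - self.mu) / self.sd
        g = (ndtr(z) - ndtr(-_BELL_SD_SPAN)) / self._mass
        g = np.where(t <= self.tau_m, 0.0, g)
        g = np.where(t >= self.t_end, 1.0, g)
        out = np.clip(g, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def rate(self, t) -> np.ndarray | float:
        """Unit rate profile ``dG/dt``; zero outside ``(tau_m, tau_m + duration)``."""
        t = np.asarray(t, dtype=float)
        z = (t - self.mu) / self.sd
        dens = np.exp(-0.5 * z * z) / (self.sd * math.sqrt(2.0 * math.pi) * self._mass)
        inside = (t > self.tau_m) & (t < self.t_end)
        out = np.where(inside, dens, 0.0)
        return float(out) if out.ndim == 0 else out

    @property
    def peak_rate(self) -> float:
        """Maximum of ``dG/dt`` (at the bell centre), in 1/s."""
        return float(self.rate(self.mu))


def primitive_step(t, shape: PrimitiveShape):
    """Evaluate the unit step profile ``G(t)`` of ``shape``."""
    return shape.step(t)


class PredictionPrimitive:
    """Prediction primitive ``H(t)``.

    Describes how, in the controller's experience, a unit of control error
    is corrected over time by one control adjustment: ``H`` is zero for
    ``t <= 0``, jumps to one just after zero (acknowledging the observed
    error), and falls back to zero by the prediction horizon ``T_p``.
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray], T_p: float):
        if T_p <= 0:
            raise ValueError("prediction horizon must be positive")
        self._fn = fn
        self.T_p = float(T_p)

    def __call__(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        inside = (t > 0.0) & (t < self.T_p)
        out = np.where(inside, self._fn(np.where(inside, t, self.T_p / 2.0)), 0.0)
        return float(out) if out.ndim == 0 else out


@dataclass
class AccumulatorSpec:
    """Two-sided noisy evidence accumulator.

    ``dA/dt = gamma[eta(eps)] - lam*A + nu`` with gating
    ``gamma(x) = sgn(x) * max(0, |x| - eta0)`` and Gaussian noise ``nu`` of
    variance ``sigma_a**2 * dt`` per simulation step. The default activation
    is linear, ``eta(eps) = k * eps``. Thresholds sit at ``A_plus`` and
    ``A_minus`` (arbitrary units; unity magnitude by convention).
    """

    k: float = 200.0
    lam: float = 0.0
    eta0: float = 0.0
    sigma_a: float = 0.8
    A_plus: float = 1.0
    A_minus: float = -1.0
    activation: Optional[Callable[[float], float]] = None

    def __post_init__(self) -> None:
        if not (self.A_plus > 0.0 > self.A_minus):
            raise ValueError("thresholds must satisfy A_plus > 0 > A_minus")
        if self.sigma_a < 0 or self.lam < 0 or self.eta0 < 0:
            raise ValueError("sigma_a, lam and eta0 must be nonnegative")

    def drive(self, eps: float) -> float:
        """Gated drift ``gamma[eta(eps)]`` for a given prediction error."""
        eta = self.activation(eps) if self.activation is not None else self.k * eps
        return math.copysign(max(0.0, abs(eta) - self.eta0), eta)


def accumulator_step(A: float, eps: float, dt: float, spec: AccumulatorSpec,
                     noise: float = 0.0) -> float:
    """One Euler step of the accumulator.

    ``noise`` is the realised increment for this step, drawn by the caller
    from ``N(0, sigma_a**2 * dt)`` (zero for noise-free integration).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    return A + (spec.drive(eps) - spec.lam * A) * dt + noise


def check_trigger(A: float, spec: AccumulatorSpec) -> int:
    """Threshold test: +1 if ``A >= A_plus``, -1 if ``A <= A_minus``, else 0.

    Both tests are boundary-inclusive. On a trigger the caller must reset
    the activation to exactly zero; no residual is carried over.
    """
    if A >= spec.A_plus:
        return 1
    if A <= spec.A_minus:
        return -1
    return 0


@dataclass
class AdjustmentEvent:
    """One triggered control adjustment.

    ``eps_tilde = (1 + m) * eps`` is the motor-noise-corrupted amplitude
    basis (the efference copy of what was actually issued), and
    ``amplitude = Kprime * eps_tilde`` the adjustment amplitude in control
    units.
    """

    t: float
    eps: float
    m: float
    eps_tilde: float
    amplitude: float
    direction: int = 0


def make_adjustment(eps_trig: float, Kprime: float, sigma_m: float,
                    rng: Optional[np.random.Generator] = None,
                    t: float = 0.0) -> AdjustmentEvent:
    """Draw motor noise and build the adjustment for a triggering error.

    ``m`` is drawn from ``N(0, sigma_m**2)``; the event is emitted even when
    the resulting amplitude is zero (it still resets the accumulator and
    contributes a zero prediction).
    """
    if sigma_m < 0:
        raise ValueError("sigma_m must be nonnegative")
    m = float(rng.normal(0.0, sigma_m)) if (sigma_m > 0 and rng is not None) else 0.0
    eps_tilde = (1.0 + m) * eps_trig
    amp = Kprime * eps_tilde
    return AdjustmentEvent(t=t, eps=eps_trig, m=m, eps_tilde=eps_tilde,
                           amplitude=amp, direction=int(np.sign(amp)))


def control_signal(events: Sequence[AdjustmentEvent], t, C0: float,
                   shape: PrimitiveShape):
    """Superposed control signal ``C(t) = C0 + sum_i g_i * G(t - t_i)``."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, float(C0))
    for ev in events:
        out = out + ev.amplitude * shape.step(t - ev.t)
    return float(out) if out.ndim == 0 else out


def control_rate(events: Sequence[AdjustmentEvent], t, shape: PrimitiveShape):
    """Superposed control rate ``dC/dt = sum_i g_i * dG/dt(t - t_i)``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    for ev in events:
        out = out + ev.amplitude * shape.rate(t - ev.t)
    return float(out) if out.ndim == 0 else out


def prediction_signal(events: Sequence[AdjustmentEvent], t,
                      H: Callable[[np.ndarray], np.ndarray]):
    """Superposed control-error prediction ``P_p(t) = sum_i eps~_i * H(t - t_i)``."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape)
    for ev in events:
        out = out + ev.eps_tilde * np.asarray(H(t - ev.t))
    return float(out) if out.ndim == 0 else out


@dataclass
class ControllerSpec:
    """All parameters of the intermittent controller.

    ``Kprime`` maps a unit of triggering prediction error to an adjustment
    amplitude in control units; with ``Kprime = 1`` the control-error
    quantity ``P`` is itself a quantification of needed adjustment
    amplitude. ``H`` is the prediction primitive for the task at hand (see
    :mod:`intermit.plants` for constructors); it may be left ``None`` only
    for open-loop uses that never evaluate predictions.
    """

    tau_p: float = 0.05
    Kprime: float = 1.0
    sigma_m: float = 0.8
    shape: PrimitiveShape = field(default_factory=PrimitiveShape)
    accumulator: AccumulatorSpec = field(default_factory=AccumulatorSpec)
    H: Optional[PredictionPrimitive] = None
    C0: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_p < 0:
            raise ValueError("perceptual delay must be nonnegative")

    # -- flat config serialisation -------------------------------------
    _KEYS = ("tau_p", "tau_m", "dT", "Kprime", "k", "lam", "eta0",
             "sigma_a", "sigma_m", "C0")

    def to_dict(self) -> dict:
        """Flat key-value form (the prediction primitive is task-bound and
        rebuilt from task configuration, not serialised)."""
        return {
            "tau_p": self.tau_p, "tau_m": self.shape.tau_m,
            "dT": self.shape.duration, "Kprime": self.Kprime,
            "k": self.accumulator.k, "lam": self.accumulator.lam,
            "eta0": self.accumulator.eta0, "sigma_a": self.accumulator.sigma_a,
            "sigma_m": self.sigma_m, "C0": self.C0,
        }

    @classmethod
    def from_dict(cls, d: dict, H: Optional[PredictionPrimitive] = None,
                  build_tracking_H: bool = False) -> "ControllerSpec":
        unknown = set(d) - set(cls._KEYS)
        if unknown:
            raise KeyError(f"unknown controller keys: {sorted(unknown)}")
        shape = PrimitiveShape(duration=float(d.get("dT", 0.4)),
                               tau_m=float(d.get("tau_m", 0.1)))
        acc = AccumulatorSpec(k=float(d.get("k", 200.0)),
                              lam=float(d.get("lam", 0.0)),
                              eta0=float(d.get("eta0", 0.0)),
                              sigma_a=float(d.get("sigma_a", 0.8)))
        spec = cls(tau_p=float(d.get("tau_p", 0.05)),
                   Kprime=float(d.get("Kprime", 1.0)),
                   sigma_m=float(d.get("sigma_m", 0.8)),
                   shape=shape, accumulator=acc, H=H,
                   C0=float(d.get("C0", 0.0)))
        if H is None and build_tracking_H:
            from .plants import build_H_tracking
            spec.H = build_H_tracking(shape, spec.tau_p)
        return spec


class Task(Protocol):
    """Closed-loop environment seen by :func:`simulate`.

    ``reset`` is called once before the loop; ``step(j, C_now, C_prev)``
    must advance the controlled system across one sample using the control
    value ``C_prev`` held over the step, and return the perceptual control
    error ``P`` at sample ``j`` given the current control ``C_now``.
    """

    def reset(self, dt: float, n: int, rng: np.random.Generator) -> None: ...

    def step(self, j: int, C_now: float, C_prev: float) -> float: ...


class Trigger(Protocol):
    """Adjustment-triggering policy (accumulator by default)."""

    trace: np.ndarray

    def reset(self, n: int, dt: float, rng: np.random.Generator) -> None: ...

    def step(self, j: int, eps: float) -> int: ...


class AccumulatorTrigger:
    """Default trigger: noisy evidence accumulation to a threshold.

    Noise is added after the drift term, the threshold is tested after the
    full step (crossings are dated at the step's end), and the activation
    is reset to exactly zero on a trigger.
    """

    def __init__(self, spec: AccumulatorSpec):
        self.spec = spec
        self.trace = np.zeros(0)
        self._A = 0.0
        self._dt = 0.0
        self._noise: np.ndarray = np.zeros(0)

    def reset(self, n: int, dt: float, rng: np.random.Generator) -> None:
        self._A = 0.0
        self._dt = dt
        self.trace = np.zeros(n)
        if self.spec.sigma_a > 0:
            self._noise = rng.normal(0.0, self.spec.sigma_a * math.sqrt(dt), n)
        else:
            self._noise = np.zeros(n)

    def step(self, j: int, eps: float) -> int:
        A = accumulator_step(self._A, eps, self._dt, self.spec, self._noise[j])
        d = check_trigger(A, self.spec)
        if d != 0:
            A = 0.0
        self._A = A
        self.trace[j] = A
        return d


class SimulationDiverged(RuntimeError):
    """Raised when the controlled system leaves a plausible envelope."""


@dataclass
class ControllerTrace:
    """Full record of one closed-loop simulation.

    All series share the grid ``t0 + j*dt``. ``C`` is reproducible from
    ``events`` by superposition of the primitive shape (and ``Cdot``,
    ``Pp`` likewise from the rate and prediction profiles).
    """

    t0: float
    dt: float
    A: np.ndarray
    P: np.ndarray
    Pr: np.ndarray
    Pp: np.ndarray
    eps: np.ndarray
    C: np.ndarray
    Cdot: np.ndarray
    events: list[AdjustmentEvent]
    task_records: Optional[object] = None  # e.g. a DataFrame of plant states
    seed: Optional[int] = None

    _SERIES = ("A", "P", "Pr", "Pp", "eps", "C", "Cdot")

    def series(self, name: str) -> UniformSeries:
        if name not in self._SERIES:
            raise KeyError(name)
        return UniformSeries(self.t0, self.dt, getattr(self, name))

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.C))

    @property
    def duration(self) -> float:
        return self.dt * (len(self.C) - 1)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.times, "A": self.A, "P": self.P, "Pr": self.Pr,
            "Pp": self.Pp, "eps": self.eps, "C": self.C, "Cdot": self.Cdot,
        })

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t_i": [ev.t for ev in self.events],
            "eps_i": [ev.eps for ev in self.events],
            "m_i": [ev.m for ev in self.events],
            "amp": [ev.amplitude for ev in self.events],
        })


def _delay_samples(tau: float, dt: float) -> int:
    """Delays are rounded to the nearest whole sample."""
    return int(round(tau / dt))


def simulate(controller: ControllerSpec, task: Task, duration: float,
             dt: float = 1.0 / 60.0, seed: Optional[int] = None,
             trigger: Optional[Trigger] = None) -> ControllerTrace:
    """Run the intermittent controller in closed loop.

    Per sample: the plant is advanced under the currently issued control,
    the perceptual control error ``P`` is computed, delayed by ``tau_p``
    (delay buffers are back-filled with the t = 0 value to avoid start-up
    transients), the prediction ``P_p`` is subtracted to give ``eps``, and
    the trigger is stepped. On a trigger the accumulator is reset, motor
    noise is drawn, and the new adjustment's motor and prediction
    primitives are superposed onto the future of ``C``, ``Cdot`` and
    ``P_p``. Identical spec and seed give a bit-identical trace.

    The master ``seed`` spawns independent streams for accumulator noise,
    motor noise and the task (road disturbance), so switching one noise
    source off does not perturb the others' draws.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    shape = controller.shape
    H = controller.H
    if H is None:
        raise ValueError("controller.H must be set for closed-loop simulation "
                         "(see intermit.plants.build_H_tracking / build_H_steering)")
    trig = trigger if trigger is not None else AccumulatorTrigger(controller.accumulator)

    n = int(round(duration / dt)) + 1
    dp = _delay_samples(controller.tau_p, dt)

    # primitive windows on the simulation grid (offset 0 is the onset sample
    # itself, where both G and H are still zero)
    Lg = int(math.ceil(shape.t_end / dt))
    k_off = np.arange(1, Lg + 1) * dt
    Gw = np.asarray(shape.step(k_off))
    Gdw = np.asarray(shape.rate(k_off))
    Lh = int(math.ceil(H.T_p / dt))
    Hw = np.asarray(H(np.arange(1, Lh + 1) * dt))

    pad = max(Lg, Lh) + 1
    C = np.full(n + pad, controller.C0)
    Cdot = np.zeros(n + pad)
    Pp = np.zeros(n + pad)
    P = np.zeros(n)
    Pr = np.zeros(n)
    eps = np.zeros(n)

    ss = np.random.SeedSequence(seed if seed is not None else 0)
    acc_rng, motor_rng, task_rng = [np.random.default_rng(s) for s in ss.spawn(3)]
    task.reset(dt, n, task_rng)
    trig.reset(n, dt, acc_rng)

    events: list[AdjustmentEvent] = []
    for j in range(n):
        C_prev = C[j - 1] if j > 0 else controller.C0
        P[j] = task.step(j, C[j], C_prev)
        Pr[j] = P[j - dp] if j >= dp else P[0]
        eps[j] = Pr[j] - Pp[j]
        if trig.step(j, eps[j]) != 0:
            ev = make_adjustment(eps[j], controller.Kprime, controller.sigma_m,
                                 motor_rng, t=j * dt)
            events.append(ev)
            C[j + 1:j + 1 + Lg] += ev.amplitude * Gw
            C[j + 1 + Lg:] += ev.amplitude
            Cdot[j + 1:j + 1 + Lg] += ev.amplitude * Gdw
            Pp[j + 1:j + 1 + Lh] += ev.eps_tilde * Hw

    records = task.records() if hasattr(task, "records") else None
    return ControllerTrace(t0=0.0, dt=dt, A=trig.trace[:n], P=P, Pr=Pr,
                           Pp=Pp[:n], eps=eps, C=C[:n], Cdot=Cdot[:n],
                           events=events, task_records=records, seed=seed)


@dataclass
class ContinuousTrace:
    """Output of the continuous reference controller."""

    t0: float
    dt: float
    P: np.ndarray
    C: np.ndarray
    Cdot: np.ndarray

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.C))


def simulate_continuous_tracking(target: UniformSeries, K: float = 2.5,
                                 tau_d: float = 0.2, C0: float = 0.0) -> ContinuousTrace:
    """Continuous cursor-tracking law ``Cdot(t) = K * P(t - tau_d)``.

    The classical linear baseline which the intermittent controller
    generalises; used for onset-equivalence and masquerading comparisons.
    ``P = -(C - C_T)``; Euler integration on the target's grid with the
    delay buffer back-filled with the t = 0 value.
    """
    dt = target.dt
    n = len(target)
    dlag = _delay_samples(tau_d, dt)
    C = np.empty(n)
    Cdot = np.zeros(n)
    P = np.zeros(n)
    C[0] = C0
    for j in range(n):
        P[j] = target.values[j] - C[j]
        Pd = P[j - dlag] if j >= dlag else P[0]
        Cdot[j] = K * Pd
        if j + 1 < n:
            C[j + 1] = C[j] + dt * Cdot[j]
    return ContinuousTrace(t0=target.t0, dt=dt, P=P, C=C, Cdot=Cdot)


def first_rate_departure(times: np.ndarray, rate: np.ndarray,
                         tol: float = 0.0) -> Optional[float]:
    """Time of the first sample at which ``|rate|`` exceeds ``tol``."""
    idx = np.flatnonzero(np.abs(np.asarray(rate)) > tol)
    return float(times[idx[0]]) if idx.size else None
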
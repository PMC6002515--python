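"""Controlled systems and task-specific prediction primitives.

The trivial cursor plant (the control signal is the controlled quantity)
and a linear single-track ("bicycle") model of lateral vehicle dynamics,

    [dv_y/dt; domega/dt] = A [v_y; omega] + b delta,

with ``delta`` the steering-wheel angle in degrees, plus global-pose
kinematics, a band-limited yaw-rate road disturbance, and constructors for
the prediction primitives H of the tracking and steering tasks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from scipy.linalg import expm

from .core import PredictionPrimitive, PrimitiveShape, SimulationDiverged
from .perception import TwoPointLaw, two_point_P, two_point_angles
from .series import UniformSeries

__all__ = [
    "BicycleSpec",
    "VehicleState",
    "DisturbanceSpec",
    "SteeringTask",
    "bicycle_step",
    "steady_state_yaw_gain",
    "yaw_response_to_G",
    "build_H_steering",
    "build_H_steering_from_spec",
    "build_H_tracking",
    "road_disturbance",
    "fit_bicycle_matrices",
    "initial_state_for",
]

_DEG2RAD = math.pi / 180.0

#: Coupling (1/s) from the road-disturbance signal (rad/s) onto the yaw
#: acceleration channel. The disturbance acts as a weak yaw-moment forcing
#: filtered by the vehicle's own yaw dynamics; this constant sets how
#: strongly a given sigma_R excites the vehicle, and is chosen so that the
#: noise-free closed-loop steering model operates in the intended regime of
#: infrequent adjustments (residual perceived-error fluctuations of a few
#: thousandths of a degree of steering between disturbance episodes).
YAW_DISTURBANCE_COUPLING = 0.01


@dataclass
class BicycleSpec:
    """Linear bicycle model: system matrix, input vector, travel speed.

    ``A`` is 2x2 over the states ``(v_y, omega)``; ``b`` maps the
    steering-wheel angle (degrees) into their rates. Default
    parameterisations are stable (both eigenvalues in the left half plane).
    """

    A: np.ndarray
    b: np.ndarray
    v_x: float
    _disc: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float).reshape(2, 2)
        self.b = np.asarray(self.b, dtype=float).reshape(2)

    @classmethod
    def from_physical(cls, v_x: float, mass: float = 1500.0, I_z: float = 2500.0,
                      l_f: float = 1.4, l_r: float = 1.4, C_f: float = 100e3,
                      C_r: float = 100e3, steering_ratio: float = 16.0
                      ) -> "BicycleSpec":
        """Standard linear single-track parameterisation of a passenger car.

        Cornering stiffnesses in N/rad; the steering ratio converts
        steering-wheel degrees to road-wheel radians. The defaults describe
        a neutral-steering saloon chosen so that (i) the yaw dynamics are
        overdamped (monotone yaw-rate response to a steering step) and
        (ii) the default two-point steering gains are well attuned to the
        vehicle: a steering adjustment of the amplitude the two-point law
        calls for cancels close to all of the control error it responds to.
        """
        if v_x <= 0:
            raise ValueError("v_x must be positive")
        A = np.array([
            [-(C_f + C_r) / (mass * v_x),
             (C_r * l_r - C_f * l_f) / (mass * v_x) - v_x],
            [(C_r * l_r - C_f * l_f) / (I_z * v_x),
             -(C_f * l_f ** 2 + C_r * l_r ** 2) / (I_z * v_x)],
        ])
        scale = _DEG2RAD / steering_ratio
        b = np.array([C_f / mass, C_f * l_f / I_z]) * scale
        return cls(A=A, b=b, v_x=v_x)

    @classmethod
    def lane_keeping(cls) -> "BicycleSpec":
        """Default spec at the lane-keeping speed, 97 km/h."""
        return cls.from_physical(97.0 / 3.6)

    @classmethod
    def circle_task(cls) -> "BicycleSpec":
        """Default spec at the circle-task speed, 43 km/h."""
        return cls.from_physical(43.0 / 3.6)

    def discretise(self, dt: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Zero-order-hold exact discretisation, cached per step size.

        Returns ``(Ad, bd, wd)`` where ``bd`` maps the held steering angle
        and ``wd`` maps a held yaw-rate disturbance input (entering on the
        yaw-acceleration channel) into the next state.
        """
        if dt not in self._disc:
            M = np.zeros((4, 4))
            M[:2, :2] = self.A
            M[:2, 2] = self.b
            M[:2, 3] = [0.0, 1.0]
            Md = expm(M * dt)
            if not np.all(np.isfinite(Md)):
                raise np.linalg.LinAlgError("singular/degenerate discretisation")
            self._disc[dt] = (Md[:2, :2].copy(), Md[:2, 2].copy(),
                              Md[:2, 3].copy())
        return self._disc[dt]


@dataclass
class VehicleState:
    """Bicycle-model states plus global pose (x, y in m, psi in rad)."""

    v_y: float = 0.0
    omega: float = 0.0
    x: float = 0.0
    y: float = 0.0
    psi: float = 0.0


def bicycle_step(state: VehicleState, delta_deg: float, disturbance_omega: float,
                 dt: float, spec: BicycleSpec,
                 disturbance_coupling: float = YAW_DISTURBANCE_COUPLING
                 ) -> VehicleState:
    """Advance the vehicle one step.

    ``(v_y, omega)`` advance by the exact zero-order-hold solution under
    the held steering angle and the held road disturbance, which enters as
    a weak forcing on the yaw-acceleration channel (i.e. it perturbs the
    yaw rate through, and damped by, the vehicle's own yaw dynamics); the
    global pose integrates by forward Euler using the updated states.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    Ad, bd, wd = spec.discretise(dt)
    d = disturbance_coupling * disturbance_omega
    v_y = (Ad[0, 0] * state.v_y + Ad[0, 1] * state.omega
           + bd[0] * delta_deg + wd[0] * d)
    omega = (Ad[1, 0] * state.v_y + Ad[1, 1] * state.omega
             + bd[1] * delta_deg + wd[1] * d)
    x = state.x + dt * (spec.v_x * math.cos(state.psi) - v_y * math.sin(state.psi))
    y = state.y + dt * (spec.v_x * math.sin(state.psi) + v_y * math.cos(state.psi))
    psi = state.psi + dt * omega
    return VehicleState(v_y=v_y, omega=omega, x=x, y=y, psi=psi)


def steady_state_yaw_gain(spec: BicycleSpec) -> float:
    """Steady-state yaw-rate response per degree of steering, ``S(v_x)``:
    the second component of ``-A^-1 b``."""
    return float((-np.linalg.solve(spec.A, spec.b))[1])


def yaw_response_to_G(spec: BicycleSpec, shape: PrimitiveShape, horizon: float,
                      dt: float = 1e-3) -> UniformSeries:
    """Yaw-rate response ``omega_G(t)`` to a unit steering adjustment G,
    from rest."""
    if horizon <= shape.t_end:
        raise ValueError("horizon must exceed the primitive's completion time")
    t = np.arange(0.0, horizon + dt / 2.0, dt)
    u = np.asarray(shape.step(t))
    sys = sps.StateSpace(spec.A, spec.b.reshape(2, 1),
                         np.array([[0.0, 1.0]]), np.zeros((1, 1)))
    _, yout, _ = sps.lsim(sys, u, t)
    return UniformSeries(0.0, dt, np.asarray(yout))


#: H is clipped to zero beyond the first time it decays below this level.
H_CLIP_LEVEL = 1e-3


def build_H_steering(omega_G: UniformSeries, S: float, tau_p: float
                     ) -> PredictionPrimitive:
    """Steering prediction primitive ``H(t) = 1 - omega_G(t - tau_p)/S``.

    After a steering adjustment the control error is predicted to decay
    with the profile of the vehicle's yaw-rate response, delayed by the
    perceptual delay. The horizon ``T_p`` is the first time H falls below
    ``H_CLIP_LEVEL``; beyond it H is exactly zero.
    """
    if S == 0:
        raise ValueError("steady-state yaw gain must be nonzero")
    tg = omega_G.times + tau_p
    hg = 1.0 - omega_G.values / S
    below = np.flatnonzero(np.abs(hg) < H_CLIP_LEVEL)
    if below.size == 0:
        raise ValueError("omega_G horizon too short: H never decays below "
                         f"{H_CLIP_LEVEL}; extend the response horizon")
    T_p = float(tg[below[0]])

    def fn(t):
        return 1.0 - np.interp(np.asarray(t) - tau_p, omega_G.times,
                               omega_G.values, left=0.0) / S

    return PredictionPrimitive(fn, T_p)


def build_H_steering_from_spec(spec: BicycleSpec, shape: PrimitiveShape,
                               tau_p: float, horizon: float = 6.0,
                               dt: float = 1e-3) -> PredictionPrimitive:
    """Convenience wrapper: simulate ``omega_G``, compute ``S``, build H."""
    omega_G = yaw_response_to_G(spec, shape, horizon, dt)
    return build_H_steering(omega_G, steady_state_yaw_gain(spec), tau_p)


def build_H_tracking(shape: PrimitiveShape, tau_p: float) -> PredictionPrimitive:
    """Tracking prediction primitive ``H(t) = 1 - G(t - tau_p)``.

    For the cursor plant the control signal is the controlled quantity, so
    the error decays exactly as the (perception-delayed) adjustment
    completes; ``T_p = tau_p + tau_m + duration``.
    """

    def fn(t):
        return 1.0 - np.asarray(shape.step(np.asarray(t) - tau_p))

    return PredictionPrimitive(fn, tau_p + shape.t_end)


@dataclass
class DisturbanceSpec:
    """Band-limited Gaussian yaw-rate disturbance (rad/s)."""

    sigma_R: float = 0.02
    cutoff_hz: float = 0.5
    order: int = 3

    def __post_init__(self) -> None:
        if self.sigma_R < 0:
            raise ValueError("sigma_R must be nonnegative")


def road_disturbance(spec: DisturbanceSpec, n: int, dt: float,
                     rng: Optional[np.random.Generator] = None,
                     seed: Optional[int] = None) -> UniformSeries:
    """Sample a yaw-rate disturbance sequence.

    White Gaussian noise low-pass filtered by a Butterworth filter of the
    given order and cutoff, then rescaled so the realised sample standard
    deviation equals ``sigma_R``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    nyquist = 0.5 / dt
    if spec.cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {spec.cutoff_hz} Hz >= Nyquist {nyquist} Hz")
    if spec.sigma_R == 0:
        return UniformSeries(0.0, dt, np.zeros(n))
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    ba = sps.butter(spec.order, spec.cutoff_hz / nyquist)
    y = sps.lfilter(*ba, white)
    sd = float(np.std(y))
    if sd > 0:
        y = y * (spec.sigma_R / sd)
    return UniformSeries(0.0, dt, y)


def fit_bicycle_matrices(delta: UniformSeries, v_y: UniformSeries,
                         omega: UniformSeries, v_x: float = float("nan")
                         ) -> BicycleSpec:
    """Least-squares fit of the bicycle A, b from recorded signals.

    State derivatives are finite differences (central in the interior);
    ``[dv_y/dt; domega/dt]`` is regressed on ``[v_y, omega, delta]``.
    """
    if not (delta.same_grid(v_y) and delta.same_grid(omega)):
        raise ValueError("series must share the same time grid")
    if len(delta) < 10:
        raise ValueError("need at least 10 samples")
    X = np.column_stack([v_y.values, omega.values, delta.values])
    Y = np.column_stack([np.gradient(v_y.values, delta.dt),
                         np.gradient(omega.values, delta.dt)])
    scale = np.linalg.norm(X, axis=0)
    dead = scale < 1e-12 * max(scale.max(), 1.0)
    theta, _res, rank, _sv = np.linalg.lstsq(X, Y, rcond=None)
    if rank < 3:
        if dead.any():
            # an identically zero regressor (e.g. no steering input during a
            # free decay) is benign: the minimum-norm solution zeroes its
            # coefficient
            import warnings

            warnings.warn("degenerate regressor(s) in bicycle fit; "
                          "coefficients set to zero")
        else:
            raise np.linalg.LinAlgError("rank-deficient regression: signals "
                                        "do not excite all states")
    A = theta[:2, :].T
    b = theta[2, :]
    return BicycleSpec(A=A, b=b, v_x=v_x)


def initial_state_for(geometry, spec: BicycleSpec) -> VehicleState:
    """Vehicle state on the centreline, heading along the road.

    On the circle the initial yaw rate matches steady circling at ``v_x``.
    """
    if geometry.kind == "straight":
        return VehicleState(x=geometry.origin[0], y=geometry.origin[1],
                            psi=geometry.heading)
    # circle: start at angle 0, travelling tangentially
    x = geometry.centre[0] + geometry.radius
    y = geometry.centre[1]
    psi = geometry.direction * math.pi / 2.0
    omega = geometry.direction * spec.v_x / geometry.radius
    return VehicleState(omega=omega, x=x, y=y, psi=psi)


class SteeringTask:
    """Closed-loop road tracking with the bicycle plant.

    Each step holds the previously issued steering-wheel angle over the
    sample, advances the vehicle (with the yaw-rate disturbance), and
    evaluates the two-point control error. Raises
    :class:`~intermit.core.SimulationDiverged` if the vehicle leaves a
    plausible envelope instead of silently clipping.
    """

    def __init__(self, geometry, law: TwoPointLaw, plant: BicycleSpec,
                 disturbance: Optional[DisturbanceSpec] = None,
                 initial_state: Optional[VehicleState] = None,
                 max_lateral_offset: float = 100.0,
                 disturbance_coupling: float = YAW_DISTURBANCE_COUPLING):
        self.geometry = geometry
        self.law = law
        self.plant = plant
        self.disturbance = disturbance or DisturbanceSpec(sigma_R=0.0)
        self._init_state = initial_state
        self.max_lateral_offset = max_lateral_offset
        self.disturbance_coupling = disturbance_coupling
        self._rec: Optional[dict] = None

    def reset(self, dt: float, n: int, rng: np.random.Generator) -> None:
        self._dt = dt
        self._Ad, self._bd, self._wd = self.plant.discretise(dt)
        self._dist = (self.disturbance_coupling
                      * road_disturbance(self.disturbance, n, dt, rng=rng).values)
        s = self._init_state or initial_state_for(self.geometry, self.plant)
        self.state = VehicleState(s.v_y, s.omega, s.x, s.y, s.psi)
        self._rec = {k: np.zeros(n) for k in
                     ("delta_deg", "vy", "omega", "x", "y", "psi")}

    def step(self, j: int, C_now: float, C_prev: float) -> float:
        st = self.state
        if j > 0:
            Ad, bd, wd = self._Ad, self._bd, self._wd
            d = self._dist[j]
            v_y = (Ad[0, 0] * st.v_y + Ad[0, 1] * st.omega
                   + bd[0] * C_prev + wd[0] * d)
            omega = (Ad[1, 0] * st.v_y + Ad[1, 1] * st.omega
                     + bd[1] * C_prev + wd[1] * d)
            st.x += self._dt * (self.plant.v_x * math.cos(st.psi)
                                - v_y * math.sin(st.psi))
            st.y += self._dt * (self.plant.v_x * math.sin(st.psi)
                                + v_y * math.cos(st.psi))
            st.psi += self._dt * omega
            st.v_y, st.omega = v_y, omega
        off = self.geometry.lateral_offset(st.x, st.y)
        if not (abs(off) < self.max_lateral_offset and abs(st.v_y) < 1e3):
            raise SimulationDiverged(
                f"vehicle diverged at t={j * self._dt:.2f} s "
                f"(lateral offset {off:.1f} m, v_y {st.v_y:.1f} m/s)")
        r = self._rec
        r["delta_deg"][j] = C_now
        r["vy"][j] = st.v_y
        r["omega"][j] = st.omega
        r["x"][j] = st.x
        r["y"][j] = st.y
        r["psi"][j] = st.psi
        angles = two_point_angles(st.x, st.y, st.psi, st.v_y, st.omega,
                                  self.plant.v_x, self.geometry,
                                  self.law.T_n, self.law.T_f, h=self._dt)
        return two_point_P(angles, self.law)

    def records(self):
        import pandas as pd

        if self._rec is None:
            return None
        n = len(self._rec["vy"])
        out = {"t": self._dt * np.arange(n)}
        out.update(self._rec)
        return pd.DataFrame(out)
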
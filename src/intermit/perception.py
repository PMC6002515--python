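"""Perceptual control-error laws and road geometry.

A control-error quantity ``P(t)`` quantifies the currently needed control
adjustment: the cursor-tracking law ``P = -(C - C_T)`` and the two-point
visual steering law ``P = k_nI*theta_n + k_nP*dtheta_n + k_f*dtheta_f``,
where ``theta_n`` and ``theta_f`` are the signed bearings of a near and a
far preview point on the lane centreline.

Sign conventions (used consistently across the package): the global frame
is x-forward/y-left with heading ``psi`` measured counter-clockwise;
lateral offset, heading, yaw rate, bearing angles and steering angle are
all positive leftward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .series import UniformSeries

__all__ = [
    "powers_P",
    "TrackingTask",
    "TwoPointLaw",
    "StraightRoad",
    "CircleTrack",
    "two_point_angles",
    "two_point_P",
    "delay",
    "geometry_from_config",
]


def powers_P(C, C_T):
    """Cursor-tracking control error ``P = -(C - C_T)``; zero on target."""
    return -(np.asarray(C, dtype=float) - np.asarray(C_T, dtype=float))


class TrackingTask:
    """Closed-loop cursor tracking: the control signal *is* the cursor.

    The plant is trivial (``Y*F = 1``): the controlled quantity equals the
    control signal, so the perceptual error at each sample is simply
    ``P = C_T - C``.
    """

    def __init__(self, target: UniformSeries):
        self.target = target

    def reset(self, dt: float, n: int, rng: np.random.Generator) -> None:
        if abs(self.target.dt - dt) > 1e-12:
            raise ValueError("target series grid does not match simulation dt")
        if len(self.target) < n:
            raise ValueError("target series shorter than the simulation")

    def step(self, j: int, C_now: float, C_prev: float) -> float:
        return float(self.target.values[j] - C_now)


@dataclass(frozen=True)
class TwoPointLaw:
    """Gains and preview times of the two-point steering law.

    With the intermittent gain fixed at one, the gains map bearing angles
    (degrees) and their rates (deg/s) to steering-wheel degrees; defaults
    are the values fitted to routine lane keeping.
    """

    k_nI: float = 0.02
    k_nP: float = 0.2
    k_f: float = 1.6
    T_n: float = 0.25
    T_f: float = 2.0

    def __post_init__(self) -> None:
        if min(self.k_nI, self.k_nP, self.k_f) < 0:
            raise ValueError("gains must be nonnegative")
        if self.T_n <= 0 or self.T_f <= 0:
            raise ValueError("preview times must be positive")


@dataclass(frozen=True)
class StraightRoad:
    """Straight lane centreline through ``origin`` along ``heading``."""

    origin: tuple[float, float] = (0.0, 0.0)
    heading: float = 0.0
    lane_width: float = 3.5

    kind = "straight"

    def preview_point(self, x: float, y: float, d: float) -> tuple[float, float]:
        """Centreline point an arc distance ``d`` ahead of the projection of
        ``(x, y)`` onto the centreline."""
        ux, uy = math.cos(self.heading), math.sin(self.heading)
        s = (x - self.origin[0]) * ux + (y - self.origin[1]) * uy
        return (self.origin[0] + (s + d) * ux, self.origin[1] + (s + d) * uy)

    def lateral_offset(self, x: float, y: float) -> float:
        """Signed offset from the centreline, positive leftward."""
        ux, uy = math.cos(self.heading), math.sin(self.heading)
        return -(x - self.origin[0]) * uy + (y - self.origin[1]) * ux


@dataclass(frozen=True)
class CircleTrack:
    """Circular centreline; ``direction`` +1 for counter-clockwise travel
    (leftward curve), -1 for clockwise."""

    radius: float = 50.0
    centre: tuple[float, float] = (0.0, 0.0)
    direction: int = 1
    lane_width: float = 3.5

    kind = "circle"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")

    def preview_point(self, x: float, y: float, d: float) -> tuple[float, float]:
        phi = math.atan2(y - self.centre[1], x - self.centre[0])
        phi2 = phi + self.direction * d / self.radius
        return (self.centre[0] + self.radius * math.cos(phi2),
                self.centre[1] + self.radius * math.sin(phi2))

    def lateral_offset(self, x: float, y: float) -> float:
        """Signed radial offset from the centreline, positive leftward
        relative to the direction of travel."""
        r = math.hypot(x - self.centre[0], y - self.centre[1])
        return -self.direction * (r - self.radius)


def _bearing(px: float, py: float, x: float, y: float, psi: float) -> float:
    """Signed bearing of a point in the vehicle frame, positive leftward."""
    dx, dy = px - x, py - y
    lon = dx * math.cos(psi) + dy * math.sin(psi)
    lat = -dx * math.sin(psi) + dy * math.cos(psi)
    return math.atan2(lat, lon)


def _angles_at(x, y, psi, geom, d_n, d_f):
    pn = geom.preview_point(x, y, d_n)
    pf = geom.preview_point(x, y, d_f)
    return _bearing(*pn, x, y, psi), _bearing(*pf, x, y, psi)


def two_point_angles(x: float, y: float, psi: float, v_y: float, omega: float,
                     v_x: float, geom, T_n: float = 0.25, T_f: float = 2.0,
                     h: float = 1.0 / 60.0):
    """Bearings and bearing rates of the near and far preview points.

    The near/far points lie on the lane centreline at arc distances
    ``v_x*T_n`` and ``v_x*T_f`` ahead of the vehicle's centreline
    projection. Rates are central differences over a short virtual
    kinematic advance of the vehicle (+-h/2 with the current lateral
    velocity and yaw rate held fixed).

    Returns ``(theta_n, dtheta_n, theta_f, dtheta_f)`` in degrees and
    deg/s: the two-point gains are fitted to degree-valued visual angles,
    matching the degree-valued steering-wheel signal (the fitted amplitude
    distributions and threshold parameters are on that scale).
    """
    if v_x <= 0:
        raise ValueError("longitudinal speed must be positive")
    d_n, d_f = v_x * T_n, v_x * T_f
    th_n, th_f = _angles_at(x, y, psi, geom, d_n, d_f)

    def _advanced(s: float):
        xn = x + s * (v_x * math.cos(psi) - v_y * math.sin(psi))
        yn = y + s * (v_x * math.sin(psi) + v_y * math.cos(psi))
        return _angles_at(xn, yn, psi + s * omega, geom, d_n, d_f)

    na, fa = _advanced(-h / 2.0)
    nb, fb = _advanced(h / 2.0)
    dth_n = _wrap(nb - na) / h
    dth_f = _wrap(fb - fa) / h
    r2d = 180.0 / math.pi
    return th_n * r2d, dth_n * r2d, th_f * r2d, dth_f * r2d


def _wrap(a: float) -> float:
    """Wrap an angle difference to (-pi, pi]."""
    return math.atan2(math.sin(a), math.cos(a))


def two_point_P(angles, law: TwoPointLaw) -> float:
    """Two-point control error from ``(theta_n, dtheta_n, theta_f, dtheta_f)``
    in degrees and deg/s; returns needed steering adjustment in degrees."""
    th_n, dth_n, _th_f, dth_f = angles
    return law.k_nI * th_n + law.k_nP * dth_n + law.k_f * dth_f


def delay(signal: UniformSeries, tau: float) -> UniformSeries:
    """Delay a series by ``tau`` (rounded to the nearest whole sample),
    back-filling the start with the t = 0 value."""
    if tau < 0:
        raise ValueError("delay must be nonnegative")
    d = int(round(tau / signal.dt))
    v = signal.values
    out = np.empty_like(v)
    out[:d] = v[0] if len(v) else 0.0
    out[d:] = v[: len(v) - d]
    return UniformSeries(signal.t0, signal.dt, out)


def geometry_from_config(cfg: dict):
    """Build a road geometry from a ``{kind, radius_m, lane_width_m}`` block."""
    kind = cfg.get("kind", "straight")
    width = float(cfg.get("lane_width_m", 3.5))
    if kind == "straight":
        return StraightRoad(lane_width=width)
    if kind == "circle":
        return CircleTrack(radius=float(cfg.get("radius_m", 50.0)), lane_width=width)
    raise ValueError(f"unknown road kind: {kind!r}")
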
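"""Scenario and fixture generation.

Deterministic construction of the study conditions: step and sum-of-sines
tracking targets, straight-road lane keeping and the 50 m circular track,
plus ground-truth fixtures (known adjustment sequences rendered into a
control signal, optionally with measurement noise and the 0.1 degree /
60 Hz recording characteristics) for exercising the reconstruction method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import AdjustmentEvent, PrimitiveShape, control_signal
from .perception import CircleTrack, StraightRoad
from .plants import DisturbanceSpec
from .series import UniformSeries

__all__ = [
    "Scenario",
    "Fixture",
    "step_target",
    "sum_of_sines_target",
    "generate_scenario",
    "generate_fixture",
]

#: Non-harmonic sum-of-sines components below the 0.5 Hz disturbance band:
#: (frequency Hz, amplitude) pairs, roughly 1/f amplitude weighting.
SUM_OF_SINES_COMPONENTS = (
    (0.065, 1.00),
    (0.106, 0.80),
    (0.164, 0.55),
    (0.253, 0.35),
    (0.391, 0.20),
)


@dataclass
class Scenario:
    """A named study condition with its parameters.

    ``kind`` is one of ``step_target``, ``sum_of_sines_target``,
    ``straight_lane``, ``circle_track``. Speeds default to the observed
    task averages (97 km/h lane keeping, 43 km/h circle).
    """

    kind: str
    duration: float = 30.0
    dt: float = 1.0 / 60.0
    seed: Optional[int] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")


def step_target(magnitude: float, duration: float,
                dt: float = 1.0 / 60.0) -> UniformSeries:
    """Step in target position: 0 for t <= 0, ``magnitude`` for t > 0."""
    n = int(round(duration / dt)) + 1
    v = np.full(n, float(magnitude))
    v[0] = 0.0
    return UniformSeries(0.0, dt, v)


def sum_of_sines_target(duration: float, dt: float = 1.0 / 60.0,
                        components=SUM_OF_SINES_COMPONENTS,
                        seed: Optional[int] = None) -> UniformSeries:
    """Sum-of-sines target: several non-harmonic components below 0.5 Hz.

    Phases are drawn uniformly from the seed (zero phases if no seed), so
    the same seed reproduces the same target exactly.
    """
    n = int(round(duration / dt)) + 1
    t = dt * np.arange(n)
    if seed is None:
        phases = np.zeros(len(components))
    else:
        phases = np.random.default_rng(seed).uniform(0, 2 * math.pi,
                                                     len(components))
    v = np.zeros(n)
    for (f, a), ph in zip(components, phases):
        v += a * np.sin(2 * math.pi * f * t + ph)
    return UniformSeries(0.0, dt, v)


def generate_scenario(spec: Scenario):
    """Materialise a scenario's simulation inputs.

    Tracking kinds return the target :class:`UniformSeries`; road kinds
    return ``(geometry, DisturbanceSpec, v_x)``. Deterministic given the
    scenario seed.
    """
    p = spec.params
    if spec.kind == "step_target":
        return step_target(p.get("magnitude", 1.0), spec.duration, spec.dt)
    if spec.kind == "sum_of_sines_target":
        return sum_of_sines_target(spec.duration, spec.dt,
                                   p.get("components", SUM_OF_SINES_COMPONENTS),
                                   seed=spec.seed)
    if spec.kind == "straight_lane":
        geom = StraightRoad(lane_width=p.get("lane_width_m", 3.5))
        dist = DisturbanceSpec(sigma_R=p.get("sigma_R", 0.02))
        return geom, dist, p.get("v_x", 97.0 / 3.6)
    if spec.kind == "circle_track":
        geom = CircleTrack(radius=p.get("radius_m", 50.0),
                           lane_width=p.get("lane_width_m", 3.5))
        dist = DisturbanceSpec(sigma_R=p.get("sigma_R", 0.02))
        return geom, dist, p.get("v_x", 43.0 / 3.6)
    raise ValueError(f"unknown scenario kind {spec.kind!r}")


@dataclass
class Fixture:
    """Ground-truth adjustment sequence and its rendered control signal."""

    events: list[AdjustmentEvent]
    series: UniformSeries
    clean: UniformSeries
    C0: float
    shape: PrimitiveShape


def generate_fixture(n_events: int = 50,
                     amplitude_range: tuple[float, float] = (0.3, 3.0),
                     min_spacing: float = 0.4,
                     spacing_jitter: float = 0.8,
                     noise_sd: float = 0.0,
                     quantise: Optional[float] = None,
                     seed: Optional[int] = None,
                     dt: float = 1.0 / 60.0,
                     shape: Optional[PrimitiveShape] = None,
                     C0: float = 0.0,
                     duration: Optional[float] = None) -> Fixture:
    """Synthesise a control signal from a known adjustment sequence.

    Onsets are grid-aligned with inter-onset gaps drawn uniformly from
    ``[min_spacing, min_spacing + spacing_jitter]``; amplitude magnitudes
    are uniform over ``amplitude_range`` with random sign. Optional white
    measurement noise (s.d. ``noise_sd``) and quantisation to multiples of
    ``quantise`` emulate recording characteristics (0.1 degree at 60 Hz).
    A margin is kept at both ends so smoothing edges cannot clip events.
    """
    if min_spacing < 0:
        raise ValueError("min_spacing must be nonnegative")
    lo, hi = amplitude_range
    if not 0 <= lo <= hi:
        raise ValueError("amplitude_range must be 0 <= lo <= hi")
    shape = shape or PrimitiveShape()
    rng = np.random.default_rng(seed)
    margin = 2.0
    gaps = rng.uniform(min_spacing, min_spacing + spacing_jitter,
                       size=max(n_events, 0))
    onsets = margin + np.cumsum(gaps) - gaps[0] if n_events else np.zeros(0)
    onsets = np.round(onsets / dt) * dt
    needed = (onsets[-1] if n_events else 0.0) + shape.t_end + margin
    total = duration if duration is not None else needed
    if total < needed:
        raise ValueError(f"duration {total} s too short for {n_events} events "
                         f"with the requested spacing (need {needed:.2f} s)")
    mags = rng.uniform(lo, hi, size=n_events)
    signs = rng.choice([-1.0, 1.0], size=n_events)
    events = [AdjustmentEvent(t=float(t), eps=float(m * s), m=0.0,
                              eps_tilde=float(m * s), amplitude=float(m * s),
                              direction=int(s))
              for t, m, s in zip(onsets, mags, signs)]
    n = int(round(total / dt)) + 1
    t = dt * np.arange(n)
    clean_v = np.asarray(control_signal(events, t, C0, shape))
    v = clean_v.copy()
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, n)
    if quantise:
        v = np.round(v / quantise) * quantise
    return Fixture(events=events, series=UniformSeries(0.0, dt, v),
                   clean=UniformSeries(0.0, dt, clean_v), C0=C0, shape=shape)
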
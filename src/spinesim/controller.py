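"""Hybrid equilibrium-point motor control and the flexion target scheduler.

Muscle stimulation combines a feed-forward open-loop co-contraction level
with a monosynaptic-reflex-like closed-loop term driving the fibre length
l_CE toward a desired length lambda (the equilibrium point):

    u = 1/2 (u_open + kappa (l_CE - lambda) / l_CE,opt),  clamped to [0, 1]

with gain kappa = 2.0 and equal mixing weights.  At a met target
(l_CE = lambda) the closed-loop term vanishes and the effective
stimulation is u_open / 2.

A forward flexion is discretised into target postures Lambda_k in 2-degree
increments of the lumbar angle change.  Descent advances to the next
target when |dphi_lum| >= a |Lambda_{m-1}| / 2, starting with a 6-degree
offset; the peak posture is held for 2 s; ascent decrements whenever
|dphi_lum| <= b |Lambda_{m-1}| / 2 + 0.1 (degrees), initiated with a
-6-degree offset, until the upright target is restored.  The printed
switching inequalities mix signs for negative flexion angles; the
magnitude reading implemented here is documented in the methods note.
Co-contraction variants are pure configuration (u_open pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List

import numpy as np

#: Co-contraction presets: (abdominal, back) open-loop stimulation levels.
COCONTRACTION_PRESETS: dict[str, tuple[float, float]] = {
    "lower": (0.01, 0.03),
    "original": (0.02, 0.04),
    "higher": (0.03, 0.05),
}


@dataclass
class ControllerConfig:
    """Gains, open-loop levels and switching constants of the controller."""

    u_open_abdominal: float = 0.02
    u_open_back: float = 0.04
    kappa: float = 2.0
    mix_weight: float = 0.5
    a: float = 1.68              # descent switching constant (generic model)
    b: float = 1.93              # ascent switching constant (generic model)
    increment_deg: float = 2.0
    start_offset_deg: float = 6.0
    hold_time: float = 2.0       # s at peak flexion
    peak_deg: float = -20.0      # desired peak change in lumbar angle
    thoracic_share: float = 0.5  # thoracic follow-through per unit lumbar angle
    #: droop compensation of the equilibrium-point targets during descent
    #: and hold: a purely proportional stimulation law settles short of the
    #: commanded posture, so the fibre-length excursions are scaled by this
    #: factor (a virtual trajectory slightly beyond the commanded angle);
    #: the ascent uses the uncompensated targets, whose droop already lies
    #: on the upright side
    target_gain: float = 1.3
    #: corresponding compensation during ascent: extensor targets are
    #: shortened toward upright so the stretch reflex lifts the trunk
    #: through each decrement threshold
    target_gain_ascent: float = 1.0

    def __post_init__(self) -> None:
        for u in (self.u_open_abdominal, self.u_open_back):
            if not 0.0 <= u <= 1.0:
                raise ValueError("u_open must lie in [0, 1]")
        if self.kappa <= 0 or self.increment_deg <= 0:
            raise ValueError("kappa and increment must be positive")

    def u_open(self, group: str) -> float:
        return self.u_open_abdominal if group == "abdominal" else self.u_open_back

    @classmethod
    def from_preset(cls, preset: str, **kwargs) -> "ControllerConfig":
        ua, ub = COCONTRACTION_PRESETS[preset]
        return cls(u_open_abdominal=ua, u_open_back=ub, **kwargs)

    def with_preset(self, preset: str) -> "ControllerConfig":
        ua, ub = COCONTRACTION_PRESETS[preset]
        return replace(self, u_open_abdominal=ua, u_open_back=ub)


def stimulation(u_open, kappa, l_CE, lam, l_CE_opt, mix_weight: float = 0.5):
    """Hybrid open/closed-loop stimulation, clamped to [0, 1]; array-friendly."""
    l_CE_opt = np.asarray(l_CE_opt, dtype=float)
    if np.any(l_CE_opt <= 0):
        raise ValueError("l_CE_opt must be positive")
    u = mix_weight * (
        np.asarray(u_open, dtype=float)
        + np.asarray(kappa, dtype=float)
        * (np.asarray(l_CE, dtype=float) - np.asarray(lam, dtype=float))
        / l_CE_opt
    )
    return np.clip(u, 0.0, 1.0)


@dataclass
class TargetSchedule:
    """Ordered target postures of a flexion-to-extension movement.

    ``angles_deg[k]`` is the commanded lumbar angle change of target k
    (0, -2, ..., peak); ``lambdas[k]`` maps every muscle to its desired
    fibre length at that posture.  ``index`` is the active target m.
    """

    angles_deg: List[float]
    lambdas: List[Dict[str, float]]
    index: int = 0
    phase: str = "descend"        # descend | hold | ascend | done
    hold_started: float | None = None
    events: List[tuple] = field(default_factory=list)
    lambdas_ascent: List[Dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if len(self.angles_deg) != len(self.lambdas):
            raise ValueError("one lambda map per target posture required")
        for lam in self.lambdas:
            if set(lam) != set(self.lambdas[0]):
                raise ValueError("lambda maps must cover the same muscles")

    @property
    def current_lambdas(self) -> Dict[str, float]:
        if self.phase in ("ascend", "done") and self.lambdas_ascent is not None:
            return self.lambdas_ascent[self.index]
        return self.lambdas[self.index]

    @property
    def current_angle_deg(self) -> float:
        return self.angles_deg[self.index]

    def copy(self) -> "TargetSchedule":
        return TargetSchedule(
            list(self.angles_deg),
            [dict(d) for d in self.lambdas],
            self.index,
            self.phase,
            self.hold_started,
            list(self.events),
        )


def make_target_schedule(
    angles_deg: List[float], lambdas: List[Dict[str, float]],
    lambdas_ascent: List[Dict[str, float]] | None = None,
) -> TargetSchedule:
    """Assemble a schedule from solved target postures (angle, lambda map)."""
    return TargetSchedule(
        angles_deg=list(angles_deg), lambdas=[dict(d) for d in lambdas],
        lambdas_ascent=[dict(d) for d in lambdas_ascent]
        if lambdas_ascent is not None else None)


def descent_angles(peak_deg: float, increment_deg: float) -> List[float]:
    """Commanded lumbar-angle targets, upright first: 0, -2, ... peak.

    The full ladder is kept in both directions; the 6-degree start offset
    of the protocol is realised by starting the schedule at the -6 entry
    (see :func:`start_index`), so the ascent can decrement through every
    2-degree step on the way back up.
    """
    n = int(round(abs(peak_deg) / increment_deg))
    angles = [-(k + 1) * increment_deg for k in range(n)]
    angles[-1] = -abs(peak_deg)
    return [0.0] + angles


def start_index(angles_deg: List[float], start_offset_deg: float) -> int:
    """Index of the first commanded target under the start offset."""
    for i, a in enumerate(angles_deg):
        if abs(a) >= start_offset_deg - 1e-9:
            return i
    return len(angles_deg) - 1


def update_phase(
    dphi_lum_deg: float,
    t: float,
    schedule: TargetSchedule,
    cfg: ControllerConfig,
) -> TargetSchedule:
    """Advance the event-based schedule given the current lumbar angle change.

    Operates on magnitudes (flexion angles are negative): descent advances
    when |dphi| >= a |Lambda_m| / 2 (inclusive), the peak is held for the
    configured time, ascent decrements when |dphi| <= b |Lambda_m| / 2 + 0.1
    with a start offset skipping back by 6 degrees, and the schedule is done
    once the upright target is active again.
    """
    s = schedule
    mag = abs(dphi_lum_deg)

    if s.phase == "descend":
        cur = abs(s.current_angle_deg)
        threshold = cfg.a * cur / 2.0
        if s.index + 1 < len(s.angles_deg) and mag >= threshold:
            s.index += 1
            s.events.append((t, "advance", s.current_angle_deg))
        if s.index == len(s.angles_deg) - 1 and mag >= abs(cfg.peak_deg):
            s.phase = "hold"
            s.hold_started = t
            s.events.append((t, "hold", s.current_angle_deg))
    elif s.phase == "hold":
        if (s.hold_started is not None
                and t - s.hold_started >= cfg.hold_time - 1e-6):
            s.phase = "ascend"
            # ascent initiated with the -6 degree offset: skip back
            target = abs(s.current_angle_deg) - cfg.start_offset_deg
            while s.index > 0 and abs(s.angles_deg[s.index]) > target + 1e-9:
                s.index -= 1
            s.events.append((t, "ascend", s.current_angle_deg))
    elif s.phase == "ascend":
        cur = abs(s.current_angle_deg)
        threshold = cfg.b * cur / 2.0 + 0.1
        if s.index > 0 and mag <= threshold:
            s.index -= 1
            s.events.append((t, "decrement", s.current_angle_deg))
        if s.index == 0 and mag <= cfg.b * cfg.increment_deg / 2.0 + 0.1:
            s.phase = "done"
            s.events.append((t, "done", 0.0))
    return s
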
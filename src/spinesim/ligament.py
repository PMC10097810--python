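"""Tension-only nonlinear ligament threads.

Each thread is a straight-line element whose static force-elongation curve
is fixed by two characteristic points: A at the transition from the
nonlinear toe to the linear region, and B just before failure.  The curve
contract implemented here:

* slack (zero force) at or below the rest length ``l0``;
* quadratic toe on [l0, lA] with F(l0) = 0, F(lA) = FA and the slope at A
  equal to the chord slope (FB - FA)/(lB - lA), i.e. C1 continuity into
* the linear region through A and B; beyond B the line extrapolates
  (no rupture model) and a warning is logged once per thread population;
* the force is clamped at >= 0, so if the characteristic data imply a
  negative initial lobe of the quadratic the thread simply engages
  slightly above l0 and the curve stays tension-only and non-decreasing.

Raw characteristic forces are divided by three (whole-structure data were
found too stiff otherwise) and by the number of parallel threads
representing the ligament at one level.  Damping is multiplicative on the
elastic force, F = F_el * (1 + d * dl/dt) floored at zero, matching the
s/m units of the ligament damping factor d = 3 s/m.

Prestrain: rest lengths are initialised from the build pose so that each
ligament carries its literature prestrain in the neutral position
(ALL 9%, PLL 13%, LF 11%, SSL 9%, CAP 5%, ITV none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Ligament prestrain in the neutral build pose (dimensionless strain).
PRESTRAIN: dict[str, float] = {
    "ALL": 0.09,
    "PLL": 0.13,
    "LF": 0.11,
    "SSL": 0.09,
    "CAP": 0.05,
    "ITV": 0.0,
}

#: Ligament damping factor (s/m), multiplicative on the elastic force.
DEFAULT_DAMPING = 3.0

#: Raw characteristic strain/force points before the /3 and /n_threads
#: scaling.  ALL/PLL/SSL/ITV magnitudes follow averaged thoracolumbar
#: tensile data of the Chazal type; the LF and CAP rows are assumed
#: regression-style values (the optimised points are not published) and are
#: meant to be overridden from the model file when better data exist.
RAW_CHARACTERISTIC_POINTS: dict[str, dict[str, float]] = {
    "ALL": {"eps_A": 0.12, "F_A": 135.0, "eps_B": 0.26, "F_B": 330.0},
    "PLL": {"eps_A": 0.14, "F_A": 72.0, "eps_B": 0.30, "F_B": 180.0},
    "LF": {"eps_A": 0.20, "F_A": 60.0, "eps_B": 0.45, "F_B": 160.0},  # assumed
    "SSL": {"eps_A": 0.25, "F_A": 60.0, "eps_B": 0.60, "F_B": 150.0},
    "ITV": {"eps_A": 0.12, "F_A": 50.0, "eps_B": 0.28, "F_B": 120.0},
    "CAP": {"eps_A": 0.15, "F_A": 70.0, "eps_B": 0.35, "F_B": 180.0},  # assumed
}

#: Division applied to whole-ligament forces before thread division.
FORCE_REDUCTION = 3.0


@dataclass
class LigamentParams:
    """Characteristic curve of one ligament thread (forces post-scaling)."""

    name: str
    eps_A: float
    F_A: float
    eps_B: float
    F_B: float
    l0: float
    eps_init: float = 0.0
    n_threads: int = 1
    d_damp: float = DEFAULT_DAMPING

    def __post_init__(self) -> None:
        if not (0.0 < self.eps_A < self.eps_B):
            raise ValueError("need 0 < eps_A < eps_B")
        if not (0.0 < self.F_A < self.F_B):
            raise ValueError("need 0 < F_A < F_B")
        if self.l0 <= 0.0:
            raise ValueError("rest length must be positive")
        if self.n_threads < 1:
            raise ValueError("thread count must be >= 1")

    @property
    def l_A(self) -> float:
        return self.l0 * (1.0 + self.eps_A)

    @property
    def l_B(self) -> float:
        return self.l0 * (1.0 + self.eps_B)

    @property
    def linear_slope(self) -> float:
        return (self.F_B - self.F_A) / (self.l_B - self.l_A)

    def toe_coefficients(self) -> tuple[float, float]:
        """(alpha, beta) of F = alpha*(l-l0) + beta*(l-l0)^2 on [l0, lA]."""
        d = self.l_A - self.l0
        k = self.linear_slope
        beta = (k * d - self.F_A) / d**2
        alpha = (2.0 * self.F_A - k * d) / d
        return alpha, beta


def scale_characteristic_points(
    raw: dict[str, float], l0: float, n_threads: int, *, name: str = "LIG",
    eps_init: float = 0.0, d_damp: float = DEFAULT_DAMPING,
) -> LigamentParams:
    """Scale raw strain/force points to one thread of rest length ``l0``.

    Characteristic forces are divided by ``FORCE_REDUCTION`` (= 3) and by
    the number of parallel threads; strains carry over unchanged so that
    l_A = l0 (1 + eps_A) and l_B = l0 (1 + eps_B).
    """
    if n_threads < 1:
        raise ValueError("thread count must be >= 1")
    if raw["F_A"] <= 0 or raw["F_B"] <= 0:
        raise ValueError("raw characteristic forces must be positive")
    div = FORCE_REDUCTION * n_threads
    return LigamentParams(
        name=name,
        eps_A=raw["eps_A"],
        F_A=raw["F_A"] / div,
        eps_B=raw["eps_B"],
        F_B=raw["F_B"] / div,
        l0=l0,
        eps_init=eps_init,
        n_threads=n_threads,
        d_damp=d_damp,
    )


def init_rest_length(attachment_distance_at_init: float, eps_init: float) -> float:
    """Rest length that realises ``eps_init`` at the build-pose distance."""
    if attachment_distance_at_init <= 0:
        raise ValueError("attachment distance must be positive")
    if eps_init <= -1.0:
        raise ValueError("prestrain must be > -1")
    return attachment_distance_at_init / (1.0 + eps_init)


def static_force(l, p: LigamentParams):
    """Static (undamped) tension at length ``l``; array-friendly."""
    l = np.asarray(l, dtype=float)
    alpha, beta = p.toe_coefficients()
    e = l - p.l0
    toe = alpha * e + beta * e * e
    lin = p.F_A + p.linear_slope * (l - p.l_A)
    F = np.where(l <= p.l0, 0.0, np.where(l <= p.l_A, toe, lin))
    return np.maximum(F, 0.0)


def ligament_force(l, dldt, p: LigamentParams):
    """Tension (N, >= 0) of one thread at length ``l`` and rate ``dl/dt``."""
    if not (np.all(np.isfinite(l)) and np.all(np.isfinite(dldt))):
        raise ValueError("non-finite ligament length or rate")
    if np.any(np.asarray(l) <= 0):
        raise ValueError("ligament length must be positive")
    F_el = static_force(l, p)
    return np.maximum(F_el * (1.0 + p.d_damp * np.asarray(dldt, dtype=float)), 0.0)


def ligament_potential(l, p: LigamentParams) -> float:
    """Elastic energy of one thread at length ``l`` (damping excluded)."""
    l = float(l)
    alpha, beta = p.toe_coefficients()

    def toe_int(x: float) -> float:
        # integral of the clamped toe from l0 to l0+x
        if alpha >= 0:
            return alpha * x**2 / 2.0 + beta * x**3 / 3.0
        # negative initial lobe is clamped to zero: integrate from the root
        x0 = -alpha / beta if beta > 0 else x
        if x <= x0:
            return 0.0
        f = lambda y: alpha * y**2 / 2.0 + beta * y**3 / 3.0
        return f(x) - f(x0)

    dA = p.l_A - p.l0
    if l <= p.l0:
        return 0.0
    if l <= p.l_A:
        return toe_int(l - p.l0)
    V_toe = toe_int(dA)
    e = l - p.l_A
    return V_toe + p.F_A * e + 0.5 * p.linear_slope * e**2


def build_cap_threads(
    facet_midpoints: dict[str, np.ndarray],
    facet_normals: dict[str, np.ndarray],
    length: float = 0.008,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Construct capsular-ligament attachment pairs from facet mid-points.

    For each side the inferior partner point is placed ``length`` (default
    8 mm, the anatomical facet dimension) along the facet normal from the
    superior facet mid-point; one thread per anatomical side.
    """
    pairs: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for side, mid in facet_midpoints.items():
        if side not in facet_normals:
            raise KeyError(f"missing facet normal for side {side!r}")
        n = np.asarray(facet_normals[side], dtype=float)
        n = n / np.linalg.norm(n)
        mid = np.asarray(mid, dtype=float)
        pairs[side] = (mid, mid + length * n)
    return pairs


_extrapolation_warned: set[str] = set()


def warn_beyond_B(name: str, l: float, p: LigamentParams) -> None:
    """Log once when a thread is stretched past point B (linear extrapolation)."""
    if l > p.l_B and name not in _extrapolation_warned:
        _extrapolation_warned.add(name)
        logger.warning(
            "ligament %s stretched beyond point B (l=%.4f m > l_B=%.4f m); "
            "force extrapolates linearly", name, l, p.l_B,
        )
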
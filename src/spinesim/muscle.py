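"""Four-element Hill-type muscle-tendon units (CE, PEE, SEE, SDE).

The muscle-tendon unit (MTU) combines a contractile element (CE) and a
parallel elastic element (PEE) for the fibre, in series with an elastic
tendon (SEE) and a serial damping element (SDE).  The cited formulation of
this model is not printed in the source material; the implementation here
is a standard four-element variant with one shared set of generic
constants (editable via :class:`MuscleConstants`) and three muscle-specific
parameters derived from anatomy:

    F_max    = sigma * PCSA            (sigma = 23 N/cm^2)
    l_CE,opt = m_ratio * l_MTU         (optimal posture at build)
    l_SEE,0  = l_MTU - l_CE,opt

Contraction dynamics: the fibre velocity follows from the force balance
CE + PEE = SEE + SDE, with a classic Hill hyperbola on the concentric
side, a continuous eccentric branch saturating at F_ecc * F_isom, and a
force-dependent serial damping coefficient.  The balance is quadratic in
the fibre velocity and solved in closed form per branch.

Activation dynamics: a first-order calcium-ion state driven by the neural
stimulation u, mapped through a sigmoid to activity (Hatze-style), with a
small basal activity floor to avoid degenerate dynamics.  For piecewise
constant u the calcium ODE integrates exactly, which ``activation_step``
exploits.

Muscle paths are piecewise straight lines between origin, up to two
deflection points and insertion; a deflection point may be constrained to
an elliptic area (via-ellipse), in which case it is placed at the
minimum-total-length position inside the area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

#: Specific maximum isometric stress (N/cm^2) shared by all trunk muscles.
SIGMA = 23.0


@dataclass
class MuscleConstants:
    """Generic activation/contraction constants shared by all MTUs.

    These mirror the role of a packaged "generic muscle parameters" table;
    all values are documented defaults (assumptions, not measurements).
    """

    A_rel: float = 0.25          # Hill constant (force-normalised)
    B_rel: float = 2.25          # Hill constant (1/s, velocity-normalised)
    F_ecc: float = 1.5           # eccentric force saturation / F_isom
    S_ecc: float = 2.0           # eccentric/concentric slope ratio at v=0
    fl_width: float = 0.45       # width of the bell-shaped force-length curve
    pee_slack_ratio: float = 1.0   # PEE engages at the optimal fibre length
    pee_ref_stretch: float = 1.8   # PEE reaches F_max at 1.8 l_CE,opt
    see_toe_strain: float = 0.02   # SEE toe/linear transition strain
    see_ref_strain: float = 0.04   # SEE strain at F_max
    D_SE: float = 0.3            # dimensionless SDE damping
    R_SE: float = 0.01           # minimum SDE damping fraction
    act_rate: float = 11.3       # calcium dynamics rate constant m (1/s)
    act_rho: float = 10.0        # sigmoid scaling of the activation map
    act_nu: float = 2.0          # sigmoid exponent
    basal_activity: float = 0.005  # stimulation-to-activity basal level


DEFAULT_CONSTANTS = MuscleConstants()


@dataclass
class Ellipse:
    """Elliptic deflection area bound to a body (local coordinates)."""

    centre: np.ndarray
    axis_u: np.ndarray   # in-plane unit direction of semi-axis a
    axis_v: np.ndarray   # in-plane unit direction of semi-axis b
    a: float
    b: float

    def __post_init__(self) -> None:
        self.centre = np.asarray(self.centre, dtype=float).reshape(3)
        self.axis_u = np.asarray(self.axis_u, dtype=float).reshape(3)
        self.axis_v = np.asarray(self.axis_v, dtype=float).reshape(3)
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


@dataclass
class MTUParams:
    """Muscle-specific parameters of one muscle-tendon unit."""

    name: str
    F_max: float
    l_CE_opt: float
    l_SEE_0: float
    m_ratio: float
    PCSA: float = 0.0           # cm^2
    sigma: float = SIGMA        # N/cm^2
    group: str = "back"         # "abdominal" | "back" (controller grouping)
    constants: MuscleConstants = field(default_factory=MuscleConstants)

    def __post_init__(self) -> None:
        if self.F_max <= 0 or self.l_CE_opt <= 0 or self.l_SEE_0 < 0:
            raise ValueError("muscle lengths/forces must be positive")


@dataclass
class MTUState:
    """Dynamic state of one MTU."""

    l_CE: float
    activity: float
    l_MTU: float = 0.0
    v_MTU: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.activity <= 1.0:
            raise ValueError("activity must lie in [0, 1]")
        if self.l_CE <= 0.0:
            raise ValueError("fibre length must be positive")


def derive_mtu_params(
    PCSA: float, m_ratio: float, l_MTU_at_build: float, *,
    name: str = "MTU", sigma: float = SIGMA, group: str = "back",
    constants: MuscleConstants | None = None,
) -> MTUParams:
    """Muscle-specific parameters from PCSA, fibre ratio and build length."""
    if PCSA <= 0 or l_MTU_at_build <= 0:
        raise ValueError("PCSA and build length must be positive")
    if not 0.0 < m_ratio <= 1.0:
        raise ValueError("m_ratio must lie in (0, 1]")
    l_ce_opt = m_ratio * l_MTU_at_build
    return MTUParams(
        name=name,
        F_max=sigma * PCSA,
        l_CE_opt=l_ce_opt,
        l_SEE_0=l_MTU_at_build - l_ce_opt,
        m_ratio=m_ratio,
        PCSA=PCSA,
        sigma=sigma,
        group=group,
        constants=constants or MuscleConstants(),
    )


# ---------------------------------------------------------------------------
# path routing


@dataclass
class RoutedPath:
    """Result of routing a muscle path through its deflection points."""

    l_MTU: float
    points: np.ndarray              # (n, 3) solved world points
    unit_vectors: np.ndarray        # (n-1, 3) segment directions
    ellipse_params: dict[int, float]  # warm-start angle per constrained index


def _plane_minimum(q1, q2, centre, normal):
    """Unconstrained minimiser of |p-q1|+|p-q2| over a plane."""
    d1 = float(np.dot(q1 - centre, normal))
    d2 = float(np.dot(q2 - centre, normal))
    if abs(d1) < 1e-14 and abs(d2) < 1e-14:
        return 0.5 * (q1 + q2)
    if d1 * d2 < 0:
        t = d1 / (d1 - d2)
        return q1 + t * (q2 - q1)
    # same side: reflect q2, straight line to the reflection crosses the plane
    q2r = q2 - 2.0 * d2 * normal
    d2r = float(np.dot(q2r - centre, normal))
    if abs(d1 - d2r) < 1e-14:
        return 0.5 * (q1 + q2) - d1 * normal
    t = d1 / (d1 - d2r)
    return q1 + t * (q2r - q1)


def solve_via_ellipse(
    q1: np.ndarray,
    q2: np.ndarray,
    centre: np.ndarray,
    axis_u: np.ndarray,
    axis_v: np.ndarray,
    a: float,
    b: float,
    warm_start: Optional[float] = None,
) -> tuple[np.ndarray, float]:
    """Minimum-total-length deflection point within an elliptic area.

    Returns the solved world point and the boundary angle used as warm
    start for the next call (nan when the interior solution is active).
    Interior solutions are allowed; the boundary is active only when the
    unconstrained shortest path leaves the area.
    """
    q1 = np.asarray(q1, float)
    q2 = np.asarray(q2, float)
    centre = np.asarray(centre, float)
    u = axis_u / np.linalg.norm(axis_u)
    v = axis_v / np.linalg.norm(axis_v)
    n = np.cross(u, v)
    n /= np.linalg.norm(n)

    p_free = _plane_minimum(q1, q2, centre, n)
    x = float(np.dot(p_free - centre, u))
    y = float(np.dot(p_free - centre, v))
    if (x / a) ** 2 + (y / b) ** 2 <= 1.0 + 1e-12:
        return centre + x * u + y * v, float("nan")

    def length(phi: float) -> float:
        p = centre + a * np.cos(phi) * u + b * np.sin(phi) * v
        return float(np.linalg.norm(p - q1) + np.linalg.norm(p - q2))

    if warm_start is not None and np.isfinite(warm_start):
        res = minimize_scalar(
            length, bounds=(warm_start - 0.8, warm_start + 0.8),
            method="bounded", options={"xatol": 1e-10},
        )
        phi_best = float(res.x)
    else:
        grid = np.linspace(0.0, 2.0 * np.pi, 64, endpoint=False)
        phi0 = grid[int(np.argmin([length(p) for p in grid]))]
        res = minimize_scalar(
            length, bounds=(phi0 - 0.2, phi0 + 0.2),
            method="bounded", options={"xatol": 1e-10},
        )
        phi_best = float(res.x)
    p = centre + a * np.cos(phi_best) * u + b * np.sin(phi_best) * v
    return p, phi_best


def route_path(
    points: Sequence[np.ndarray],
    ellipses: Optional[Sequence[Optional[tuple]]] = None,
    warm_start: Optional[dict[int, float]] = None,
) -> RoutedPath:
    """Route a piecewise straight muscle path through its world points.

    ``points`` are the world positions of origin, deflection point(s) and
    insertion.  ``ellipses`` optionally gives, per interior point, a tuple
    (centre, axis_u, axis_v, a, b) in world coordinates constraining that
    deflection point to an elliptic area; the point is then repositioned at
    the minimum-total-length location within the area (warm-started from
    the previous solution for temporal continuity).
    """
    pts = [np.asarray(p, dtype=float).reshape(3) for p in points]
    if len(pts) < 2:
        raise ValueError("a muscle path needs at least origin and insertion")
    if len(pts) > 4:
        raise ValueError("at most two deflection points are supported")
    warm = dict(warm_start or {})
    solved_angles: dict[int, float] = {}
    if ellipses is not None:
        for i, ell in enumerate(ellipses):
            idx = i + 1  # ellipses apply to interior points only
            if ell is None:
                continue
            centre, au, av, a, b = ell
            p, phi = solve_via_ellipse(
                pts[idx - 1], pts[idx + 1], centre, au, av, a, b,
                warm.get(idx),
            )
            pts[idx] = p
            solved_angles[idx] = phi
    arr = np.array(pts)
    seg = np.diff(arr, axis=0)
    lens = np.linalg.norm(seg, axis=1)
    if np.any(lens < 1e-12):
        raise ValueError("degenerate zero-length muscle path segment")
    return RoutedPath(
        l_MTU=float(lens.sum()),
        points=arr,
        unit_vectors=seg / lens[:, None],
        ellipse_params=solved_angles,
    )


# ---------------------------------------------------------------------------
# activation dynamics


def activity_from_gamma(gamma, c: MuscleConstants = DEFAULT_CONSTANTS):
    """Sigmoid map from the calcium state to activity in [basal, ~1)."""
    g = np.maximum(np.asarray(gamma, dtype=float), 0.0)
    s = (c.act_rho * g) ** c.act_nu
    return (c.basal_activity + s) / (1.0 + s)


def gamma_from_activity(activity, c: MuscleConstants = DEFAULT_CONSTANTS):
    a = np.clip(np.asarray(activity, dtype=float), c.basal_activity, 1.0 - 1e-12)
    s = (a - c.basal_activity) / (1.0 - a)
    return np.maximum(s, 0.0) ** (1.0 / c.act_nu) / c.act_rho


def activation_step(
    activity: float, u: float, dt: float,
    c: MuscleConstants = DEFAULT_CONSTANTS,
) -> float:
    """Advance activity under constant stimulation ``u`` for ``dt``.

    The calcium state relaxes exponentially toward u (exact solution of
    the linear ODE for piecewise-constant stimulation); the returned
    activity is the sigmoid of the advanced state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (0.0 <= u <= 1.0):
        raise ValueError("stimulation must lie in [0, 1]")
    gamma = gamma_from_activity(activity, c)
    gamma_new = u + (gamma - u) * np.exp(-c.act_rate * dt)
    return float(activity_from_gamma(gamma_new, c))


def activation_rate(gamma, u, c: MuscleConstants = DEFAULT_CONSTANTS):
    """d gamma / dt of the calcium state."""
    return c.act_rate * (np.asarray(u, dtype=float) - np.asarray(gamma, dtype=float))


# ---------------------------------------------------------------------------
# force elements


def force_length(l_CE, p: MTUParams):
    """Bell-shaped isometric force-length factor of the CE."""
    c = p.constants
    x = (np.asarray(l_CE, dtype=float) / p.l_CE_opt - 1.0) / c.fl_width
    return np.exp(-(x**2))


def force_pee(l_CE, p: MTUParams):
    """Parallel elastic force; quadratic above the PEE slack length."""
    c = p.constants
    l0 = c.pee_slack_ratio * p.l_CE_opt
    lref = c.pee_ref_stretch * p.l_CE_opt
    k = p.F_max / (lref - l0) ** 2
    e = np.maximum(np.asarray(l_CE, dtype=float) - l0, 0.0)
    return k * e * e


def force_see(l_SEE, p: MTUParams):
    """Serial elastic (tendon) force: quadratic toe, then linear.

    The toe ends at strain ``see_toe_strain`` carrying F_max/3, which makes
    the slope continuous into the linear region reaching F_max at
    ``see_ref_strain`` (with the default 0.02/0.04 strains).
    """
    c = p.constants
    if p.l_SEE_0 <= 0:
        # rigid tendon limit (m_ratio = 1)
        return np.where(np.asarray(l_SEE, dtype=float) > 0, np.inf, 0.0)
    eps = np.asarray(l_SEE, dtype=float) / p.l_SEE_0 - 1.0
    e1, e2 = c.see_toe_strain, c.see_ref_strain
    F1 = p.F_max * e1 / (2.0 * e2 - e1)   # slope-continuous toe terminus
    k_lin = 2.0 * F1 / e1                  # per unit strain
    toe = F1 * (np.maximum(eps, 0.0) / e1) ** 2
    lin = F1 + k_lin * (eps - e1)
    return np.where(eps <= 0.0, 0.0, np.where(eps <= e1, toe, lin))


def _d_se(F_im, F_pee, p: MTUParams) -> float:
    """Force-dependent serial damping coefficient (Ns/m)."""
    c = p.constants
    if p.l_SEE_0 <= 0:
        return 0.0
    d_max = c.D_SE * p.F_max * c.A_rel / (p.l_CE_opt * c.B_rel)
    return d_max * ((1.0 - c.R_SE) * (F_im + F_pee) / p.F_max + c.R_SE)


def mtu_force(
    l_MTU: float,
    v_MTU: float,
    l_CE: float,
    activity: float,
    p: MTUParams,
) -> tuple[float, float]:
    """Tension (N) and fibre velocity d l_CE/dt (m/s) of one MTU.

    Solves the CE+PEE vs SEE+SDE force balance for the fibre velocity in
    closed form (quadratic per Hill branch) and returns the tendon tension
    transmitted to the skeleton, clamped tension-only.
    """
    if not all(np.isfinite([l_MTU, v_MTU, l_CE, activity])):
        raise ValueError("non-finite MTU state")
    c = p.constants
    if p.l_SEE_0 <= 1e-12:
        # rigid tendon: fibre length is the MTU length
        F_im = activity * p.F_max * float(force_length(l_MTU, p))
        return max(F_im + float(force_pee(l_MTU, p)), 0.0), v_MTU

    F_im = activity * p.F_max * float(force_length(l_CE, p))
    F_pee = float(force_pee(l_CE, p))
    F_see = float(force_see(l_MTU - l_CE, p))
    d_se = _d_se(F_im, F_pee, p)
    a_p = c.A_rel * p.F_max
    b_p = c.B_rel * p.l_CE_opt

    G0 = F_im + F_pee - F_see - d_se * v_MTU
    if G0 > 0.0:
        # concentric branch: F_CE(v) = (F_im + a') b' / (b' - v) - a', v <= 0
        C0 = -a_p + F_pee - F_see - d_se * v_MTU
        A = d_se
        B = -(d_se * b_p - C0)
        Cq = -(F_im + a_p + C0) * b_p
        if A < 1e-14:
            v_ce = Cq / -B if abs(B) > 1e-14 else 0.0
        else:
            disc = max(B * B - 4.0 * A * Cq, 0.0)
            v_ce = (-B - np.sqrt(disc)) / (2.0 * A)
        v_ce = min(v_ce, 0.0)
        F_ce = (F_im + a_p) * b_p / (b_p - v_ce) - a_p
        if F_ce < 0.0:
            # required CE force negative: clamp at zero, balance the rest
            F_ce = 0.0
            if d_se > 1e-14:
                v_ce = v_MTU + (F_see - F_pee) / d_se
            v_ce = min(v_ce, 0.0)
    else:
        # eccentric branch: F_CE(v) = F_im (F_ecc - (F_ecc-1) b_e/(b_e+v))
        slope_con = (F_im + a_p) / b_p
        b_e = F_im * (c.F_ecc - 1.0) / (c.S_ecc * slope_con) if F_im > 1e-12 \
            else b_p * (c.F_ecc - 1.0) / c.S_ecc / c.A_rel
        C0 = F_pee - F_see - d_se * v_MTU
        A = d_se
        B = F_im * c.F_ecc + C0 + d_se * b_e
        Cq = (F_im + C0) * b_e
        if A < 1e-14:
            v_ce = -Cq / B if abs(B) > 1e-14 else 0.0
        else:
            disc = max(B * B - 4.0 * A * Cq, 0.0)
            v_ce = (-B + np.sqrt(disc)) / (2.0 * A)
        v_ce = max(v_ce, 0.0)

    tension = F_see + d_se * (v_MTU - v_ce)
    return max(tension, 0.0), float(v_ce)


def mtu_force_vec(
    l_MTU: np.ndarray,
    v_MTU: np.ndarray,
    l_CE: np.ndarray,
    activity: np.ndarray,
    F_max: np.ndarray,
    l_CE_opt: np.ndarray,
    l_SEE_0: np.ndarray,
    c: MuscleConstants = DEFAULT_CONSTANTS,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`mtu_force` for stacks of MTUs sharing constants.

    Elastic tendons only (l_SEE_0 > 0); cross-checked against the scalar
    solver in the test suite.
    """
    x = (l_CE / l_CE_opt - 1.0) / c.fl_width
    F_im = activity * F_max * np.exp(-(x**2))
    l0p = c.pee_slack_ratio * l_CE_opt
    k_pee = F_max / ((c.pee_ref_stretch - c.pee_slack_ratio) * l_CE_opt) ** 2
    e_pee = np.maximum(l_CE - l0p, 0.0)
    F_pee = k_pee * e_pee * e_pee
    eps = (l_MTU - l_CE) / l_SEE_0 - 1.0
    e1, e2 = c.see_toe_strain, c.see_ref_strain
    F1 = F_max * e1 / (2.0 * e2 - e1)
    k_lin = 2.0 * F1 / e1
    F_see = np.where(
        eps <= 0.0, 0.0,
        np.where(eps <= e1, F1 * (np.maximum(eps, 0.0) / e1) ** 2,
                 F1 + k_lin * (eps - e1)))
    d_max = c.D_SE * F_max * c.A_rel / (l_CE_opt * c.B_rel)
    d_se = d_max * ((1.0 - c.R_SE) * (F_im + F_pee) / F_max + c.R_SE)
    a_p = c.A_rel * F_max
    b_p = c.B_rel * l_CE_opt

    G0 = F_im + F_pee - F_see - d_se * v_MTU
    # concentric branch
    C0c = -a_p + F_pee - F_see - d_se * v_MTU
    Bc = -(d_se * b_p - C0c)
    Cc = -(F_im + a_p + C0c) * b_p
    disc_c = np.sqrt(np.maximum(Bc * Bc - 4.0 * d_se * Cc, 0.0))
    v_con = np.minimum((-Bc - disc_c) / (2.0 * d_se), 0.0)
    F_ce_con = (F_im + a_p) * b_p / (b_p - v_con) - a_p
    v_free = np.minimum(v_MTU + (F_see - F_pee) / d_se, 0.0)
    v_con = np.where(F_ce_con < 0.0, v_free, v_con)
    # eccentric branch
    slope_con = (F_im + a_p) / b_p
    b_e = np.where(
        F_im > 1e-12,
        F_im * (c.F_ecc - 1.0) / (c.S_ecc * slope_con),
        b_p * (c.F_ecc - 1.0) / (c.S_ecc * c.A_rel),
    )
    C0e = F_pee - F_see - d_se * v_MTU
    Be = F_im * c.F_ecc + C0e + d_se * b_e
    Ce = (F_im + C0e) * b_e
    disc_e = np.sqrt(np.maximum(Be * Be - 4.0 * d_se * Ce, 0.0))
    v_ecc = np.maximum((-Be + disc_e) / (2.0 * d_se), 0.0)

    v_ce = np.where(G0 > 0.0, v_con, v_ecc)
    tension = np.maximum(F_see + d_se * (v_MTU - v_ce), 0.0)
    return tension, v_ce
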
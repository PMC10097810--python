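"""Hill-type MTU: parameter derivation, routing, activation, contraction."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import minimize

import spinesim as ss
from spinesim.muscle import (
    DEFAULT_CONSTANTS,
    MuscleConstants,
    activation_rate,
    activation_step,
    activity_from_gamma,
    derive_mtu_params,
    force_pee,
    force_see,
    gamma_from_activity,
    mtu_force,
    mtu_force_vec,
    route_path,
    solve_via_ellipse,
)

RNG = np.random.default_rng(11)


class TestParamDerivation:
    def test_fmax_from_pcsa(self):
        p = derive_mtu_params(10.0, 0.5, 0.2)
        assert p.F_max == pytest.approx(230.0)

    def test_length_partition(self):
        p = derive_mtu_params(5.0, 0.5, 0.2)
        assert p.l_CE_opt == pytest.approx(0.1)
        assert p.l_SEE_0 == pytest.approx(0.1)

    def test_rigid_tendon_limit(self):
        p = derive_mtu_params(5.0, 1.0, 0.2)
        assert p.l_SEE_0 == 0.0

    def test_invalid_ratio(self):
        with pytest.raises(ValueError):
            derive_mtu_params(5.0, 1.5, 0.2)

    @pytest.mark.parametrize("which", ["generic", "individualised"])
    def test_partition_reproduced_after_geometry_scaling(self, generic_model, which):
        if which == "generic":
            model = generic_model
        else:
            lm = ss.export_landmarks(generic_model)
            model = ss.individualise(lm, generic_model, tilt_deg=0.0)
        for mus in model.muscles:
            pts = [model.body(pp.body).frame.transform_point(pp.point)
                   for pp in mus.path]
            l_mtu = sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:]))
            assert mus.params.l_CE_opt == pytest.approx(
                mus.params.m_ratio * l_mtu, rel=1e-9)
            assert mus.params.l_CE_opt + mus.params.l_SEE_0 == pytest.approx(
                l_mtu, rel=1e-9)
            assert mus.params.F_max == pytest.approx(23.0 * mus.params.PCSA)


class TestRouting:
    def test_straight_two_point_path(self):
        r = route_path([[0, 0, 0], [0.3, 0.4, 0.0]])
        assert r.l_MTU == pytest.approx(0.5)

    def test_collinear_deflection_point(self):
        r = route_path([[0, 0, 0], [0.15, 0.2, 0.0], [0.3, 0.4, 0.0]])
        assert r.l_MTU == pytest.approx(0.5, rel=1e-12)

    def test_degenerate_segment_rejected(self):
        with pytest.raises(ValueError):
            route_path([[0, 0, 0], [0, 0, 0], [1, 0, 0]])

    def test_ellipse_constraint_matches_brute_force(self):
        q1 = np.array([-0.3, 0.1, 0.25])
        q2 = np.array([0.35, -0.05, 0.3])
        centre = np.zeros(3)
        u = np.array([1.0, 0.0, 0.0])
        v = np.array([0.0, 1.0, 0.0])
        a, b = 0.05, 0.03
        p, phi = solve_via_ellipse(q1, q2, centre, u, v, a, b)

        def length(xy):
            pt = centre + xy[0] * u + xy[1] * v
            return np.linalg.norm(pt - q1) + np.linalg.norm(pt - q2)

        # brute-force oracle: dense interior grid plus very dense boundary
        best = np.inf
        for xx in np.linspace(-a, a, 200):
            for yy in np.linspace(-b, b, 150):
                if (xx / a) ** 2 + (yy / b) ** 2 <= 1.0:
                    best = min(best, length([xx, yy]))
        phis = np.linspace(0.0, 2.0 * np.pi, 400001)
        bl = np.linalg.norm(
            (centre + a * np.cos(phis)[:, None] * u + b * np.sin(phis)[:, None] * v)
            - q1, axis=1
        ) + np.linalg.norm(
            (centre + a * np.cos(phis)[:, None] * u + b * np.sin(phis)[:, None] * v)
            - q2, axis=1
        )
        best = min(best, bl.min())
        mine = length([np.dot(p - centre, u), np.dot(p - centre, v)])
        assert mine == pytest.approx(best, abs=1e-6)

    def test_interior_solution_when_segment_crosses_area(self):
        q1 = np.array([0.0, 0.0, -0.1])
        q2 = np.array([0.0, 0.0, 0.1])
        p, phi = solve_via_ellipse(q1, q2, np.zeros(3),
                                   np.array([1.0, 0, 0]), np.array([0, 1.0, 0]),
                                   0.05, 0.05)
        assert np.isnan(phi)          # interior (inactive constraint)
        r = route_path([q1, p, q2])
        assert r.l_MTU == pytest.approx(0.2, rel=1e-10)


class TestActivation:
    def test_decay_to_basal(self):
        a = 0.6
        for _ in range(200):
            a = activation_step(a, 0.0, 0.05)
        assert a == pytest.approx(DEFAULT_CONSTANTS.basal_activity, abs=1e-6)

    def test_saturation_near_one(self):
        a = 0.1
        for _ in range(200):
            a = activation_step(a, 1.0, 0.05)
        assert a > 0.98

    def test_fixed_point_monotone_in_stimulation(self):
        finals = []
        for u in (0.1, 0.3, 0.6, 0.9):
            a = 0.2
            for _ in range(400):
                a = activation_step(a, u, 0.05)
            finals.append(a)
        assert np.all(np.diff(finals) > 0)

    def test_step_response_matches_reference_integrator(self):
        """Exact exponential update vs a high-accuracy ODE solve."""
        c = DEFAULT_CONSTANTS
        u = 0.7
        gamma0 = gamma_from_activity(0.1, c)
        sol = solve_ivp(lambda t, g: activation_rate(g, u, c),
                        (0.0, 0.35), [float(gamma0)],
                        rtol=1e-12, atol=1e-14, dense_output=True)
        a_ref = float(activity_from_gamma(sol.y[0, -1], c))
        a_step = 0.1
        for _ in range(7):
            a_step = activation_step(a_step, u, 0.05)
        assert a_step == pytest.approx(a_ref, rel=1e-8)

    def test_invalid_dt(self):
        with pytest.raises(ValueError):
            activation_step(0.1, 0.5, 0.0)


def _settle_isometric(p, activity, l_mtu, n=4000, dt=5e-5):
    l_ce = p.l_CE_opt
    for _ in range(n):
        tension, v = mtu_force(l_mtu, 0.0, l_ce, activity, p)
        l_ce += dt * v
    return mtu_force(l_mtu, 0.0, l_ce, activity, p)[0], l_ce


class TestContraction:
    def test_passive_slack_at_build_length(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        tension, _ = _settle_isometric(p, 0.0, 0.2)
        assert tension < 0.02 * p.F_max

    def test_fully_activated_isometric_reaches_fmax(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        tension, l_ce = _settle_isometric(p, 1.0, 0.2, n=8000)
        assert tension == pytest.approx(p.F_max, rel=0.02)
        # holding the fibre exactly at optimum gives F_max within 1%
        t_opt, _ = mtu_force(p.l_CE_opt + p.l_SEE_0 * 1.04, 0.0,
                             p.l_CE_opt, 1.0, p)
        assert t_opt == pytest.approx(p.F_max, rel=0.01)

    def test_eccentric_force_exceeds_isometric(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        _, l_ce = _settle_isometric(p, 0.8, 0.2, n=8000)
        t_iso, _ = mtu_force(0.2, 0.0, l_ce, 0.8, p)
        t_ecc, v = mtu_force(0.2, 0.08, l_ce, 0.8, p)
        assert t_ecc > t_iso
        assert v > 0.0

    def test_passive_force_grows_with_stretch(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        t1, _ = _settle_isometric(p, 0.0, 0.21, n=8000)
        t2, _ = _settle_isometric(p, 0.0, 0.23, n=8000)
        assert t2 > t1 > 0.0

    def test_tension_bounded(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        c = p.constants
        for _ in range(200):
            l_mtu = 0.2 * RNG.uniform(0.8, 1.25)
            v_mtu = RNG.normal(0, 0.3)
            l_ce = p.l_CE_opt * RNG.uniform(0.6, 1.5)
            act = RNG.uniform(0, 1)
            tension, _ = mtu_force(l_mtu, v_mtu, l_ce, act, p)
            bound = c.F_ecc * p.F_max + float(force_pee(l_ce, p)) \
                + abs(v_mtu) * 500.0
            assert 0.0 <= tension <= bound

    def test_vectorised_solver_matches_scalar(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        n = 300
        l_mtu = 0.2 * RNG.uniform(0.85, 1.2, n)
        v_mtu = RNG.normal(0, 0.2, n)
        l_ce = p.l_CE_opt * RNG.uniform(0.7, 1.4, n)
        act = RNG.uniform(0, 1, n)
        t_vec, v_vec = mtu_force_vec(
            l_mtu, v_mtu, l_ce, act,
            np.full(n, p.F_max), np.full(n, p.l_CE_opt),
            np.full(n, p.l_SEE_0), p.constants)
        for i in range(n):
            t_s, v_s = mtu_force(l_mtu[i], v_mtu[i], l_ce[i], act[i], p)
            assert t_vec[i] == pytest.approx(t_s, rel=1e-10, abs=1e-10)
            assert v_vec[i] == pytest.approx(v_s, rel=1e-10, abs=1e-10)

    def test_nonfinite_state_rejected(self):
        p = derive_mtu_params(8.0, 0.5, 0.2)
        with pytest.raises(ValueError):
            mtu_force(np.nan, 0.0, 0.1, 0.5, p)
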
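"""Forward-dynamics core: oracles on small models + invariants on the chain."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import spinesim as ss
from spinesim.geometry import Frame
from spinesim.ivd import BushingParams
from spinesim.ligament import LigamentParams
from spinesim.model import BodySpec, JointSpec, LigamentElement, ModelSpec
from spinesim.dynamics import CompiledModel, DynamicsConfig, SpineSimulation

from conftest import desk_config


PEND_I_COM = 0.01


def pendulum_model(length=0.5, mass=1.0, k_rod=3e5, gravity=9.81):
    """Planar pendulum: a pivot emulated by a stiff translational bushing
    with (numerically) free sagittal rotation."""
    base = BodySpec("base", 1.0, np.eye(3) * 1e-3, Frame())
    bob = BodySpec("bob", mass, np.eye(3) * PEND_I_COM,
                   Frame(np.array([0.0, 0.0, -length]), np.zeros(3)))
    joint = JointSpec("pivot", "base", "bob",
                      Frame(np.zeros(3), np.zeros(3)))
    model = ModelSpec(
        bodies=[base, bob], joints=[joint],
        ivds={"pivot": BushingParams(
            k_trans=[k_rod] * 3, k_rot=[50.0, 1e-8, 50.0],
            d_damp_force=0.0, d_damp_torque=0.0)},
        ligaments=[], muscles=[], gravity=gravity,
    )
    return model


def rotate_about_pivot(cm, y, angle):
    """Place the bob rotated by ``angle`` about the pivot's y axis."""
    y = y.copy()
    R = Rotation.from_rotvec([0.0, angle, 0.0])
    X = y[cm._sl_x].reshape(cm.nb, 3)
    X[0] = R.apply(X[0])
    TH = y[cm._sl_th].reshape(cm.nb, 3)
    TH[0] = np.array([0.0, angle, 0.0])
    y[cm._sl_x] = X.ravel()
    y[cm._sl_th] = TH.ravel()
    return y


class TestPendulumOracle:
    def test_period_matches_closed_form(self, pendulum_period):
        period, expected, n_crossings = pendulum_period
        assert n_crossings >= 3
        assert period == pytest.approx(expected, rel=1e-3)

    def test_rest_state_stays_at_rest(self):
        model = pendulum_model(gravity=0.0)
        sim = SpineSimulation(model, config=DynamicsConfig(
            method="split-rk4", fixed_dt=1e-3))
        cm = sim.compiled
        y0 = cm.build_state()
        sol = sim._solve(y0, 0.0, 0.2, np.zeros(0))
        assert np.allclose(sol.y[:, -1], y0, atol=1e-12)

    def test_halving_step_changes_trajectory_within_coarse_error(self):
        model = pendulum_model()
        finals = []
        for dt in (4e-4, 1e-4, 5e-5):
            sim = SpineSimulation(model, config=DynamicsConfig(
                method="split-rk4", fixed_dt=dt, output_rate=100.0))
            cm = sim.compiled
            y = rotate_about_pivot(cm, cm.build_state(), np.deg2rad(5.0))
            sol = sim._solve(y, 0.0, 1.0, np.zeros(0))
            finals.append(cm.joint_sagittal_angles(sol.y[:, -1])[0])
        err_coarse = abs(finals[0] - finals[2])
        err_fine = abs(finals[1] - finals[2])
        assert err_fine < err_coarse
        assert err_coarse < 1e-2  # degrees


def undamped_mini_chain():
    """Three vertebra-like bodies on undamped bushings with prestrained
    anterior threads; used for the energy-conservation oracle."""
    bodies = [BodySpec("base", 1.0, np.eye(3) * 1e-3, Frame())]
    joints = []
    ivds = {}
    z = 0.0
    for i in range(3):
        z += 0.04
        bodies.append(BodySpec(
            f"b{i}", 1.5, np.diag([2e-3, 2e-3, 1e-3]),
            Frame(np.array([0.0, 0.0, z]), np.zeros(3)), height=0.03))
        parent = "base" if i == 0 else f"b{i-1}"
        jname = f"j{i}"
        joints.append(JointSpec(
            jname, parent, f"b{i}",
            Frame(np.array([0.0, 0.0, z - 0.02]), np.zeros(3))))
        ivds[jname] = BushingParams(
            k_trans=[1e5, 1e5, 8e5], k_rot=[200.0, 270.0, 250.0],
            d_damp_force=0.0, d_damp_torque=0.0)
    ligaments = []
    for i in range(3):
        parent = "base" if i == 0 else f"b{i-1}"
        params = LigamentParams(
            name="ALL", eps_A=0.12, F_A=20.0, eps_B=0.26, F_B=60.0,
            l0=0.04 / 1.05, eps_init=0.05, d_damp=0.0)
        ligaments.append(LigamentElement(
            f"lig{i}", "ALL", f"j{i}", parent, f"b{i}",
            np.array([0.02, 0.0, 0.0]), np.array([0.02, 0.0, 0.0]),
            params))
    return ModelSpec(bodies=bodies, joints=joints, ivds=ivds,
                     ligaments=ligaments, muscles=[], gravity=9.81)


def two_body_ligament_model():
    """Fixed base + one vertebra joined by a (numerically) force-free
    bushing, spanned by a single prestrained ligament thread."""
    base = BodySpec("base", 1.0, np.eye(3) * 1e-3, Frame())
    body = BodySpec("b1", 1.0, np.eye(3) * 1e-3,
                    Frame(np.array([0.0, 0.0, 0.05]), np.zeros(3)))
    joint = JointSpec("j", "base", "b1",
                      Frame(np.array([0.0, 0.0, 0.025]), np.zeros(3)))
    params = LigamentParams(name="ALL", eps_A=0.12, F_A=30.0,
                            eps_B=0.26, F_B=80.0, l0=0.046,
                            eps_init=0.09, d_damp=0.0)
    lig = LigamentElement(
        name="ALL_j_l", ligament="ALL", joint="j",
        parent_body="base", child_body="b1",
        p_parent=np.array([0.03, 0.0, 0.0]),
        p_child=np.array([0.03, 0.0, 0.0]),
        params=params,
    )
    return ModelSpec(
        bodies=[base, body], joints=[joint],
        ivds={"j": BushingParams(k_trans=[1e-8] * 3, k_rot=[1e-8] * 3,
                                 d_damp_force=0.0, d_damp_torque=0.0)},
        ligaments=[lig], muscles=[], gravity=0.0,
    )


class TestVirtualWorkOracle:
    def test_ligament_generalized_torque_matches_potential_gradient(self):
        from spinesim.ligament import ligament_potential

        model = two_body_ligament_model()
        cm = CompiledModel(model)
        lig = model.ligaments[0]
        p_parent_w = model.body("base").frame.transform_point(lig.p_parent)
        p_joint = model.joint("j").frame.position
        p_child_local = lig.p_child

        def child_frame(angle):
            R = Rotation.from_rotvec([0.0, angle, 0.0])
            pos0 = model.body("b1").frame.position
            return (R.apply(pos0 - p_joint) + p_joint, R)

        def V(angle):
            pos, R = child_frame(angle)
            p_child_w = pos + R.apply(p_child_local)
            return ligament_potential(
                float(np.linalg.norm(p_child_w - p_parent_w)), lig.params)

        for angle in (0.0, 0.15, -0.2):
            y = cm.build_state()
            pos, R = child_frame(angle)
            X = y[cm._sl_x].reshape(cm.nb, 3)
            X[0] = pos + R.apply(cm.com_local[0])
            TH = y[cm._sl_th].reshape(cm.nb, 3)
            TH[0] = np.array([0.0, angle, 0.0])
            y[cm._sl_x] = X.ravel()
            y[cm._sl_th] = TH.ravel()
            dy = cm.rhs(0.0, y, np.zeros(0), ss.ControllerConfig())
            acc = dy[cm._sl_v].reshape(cm.nb, 3)[0]
            wdot = dy[cm._sl_w].reshape(cm.nb, 3)[0]
            F = cm.mass[0] * acc
            Rm = Rotation.from_rotvec(TH[0]).as_matrix()
            Iw = Rm @ cm.inertia_local[0] @ Rm.T
            tau_com = Iw @ wdot
            x_com = X[0]
            tau_joint = tau_com + np.cross(x_com - p_joint, F)
            h = 1e-6
            dVdth = (V(angle + h) - V(angle - h)) / (2 * h)
            assert tau_joint[1] == pytest.approx(-dVdth, rel=1e-5, abs=1e-8)


class TestChainInvariants:
    def test_newtons_third_law_at_perturbed_state(self, generic_model):
        cm = CompiledModel(generic_model)
        rng = np.random.default_rng(2)
        y = cm.build_state(preload=True)
        y[cm._sl_x] += rng.normal(0, 1e-3, 3 * cm.nb)
        y[cm._sl_th] += rng.normal(0, 0.01, 3 * cm.nb)
        y[cm._sl_v] = rng.normal(0, 0.05, 3 * cm.nb)
        y[cm._sl_w] = rng.normal(0, 0.2, 3 * cm.nb)
        F, T = cm.applied_wrench_sums(
            y, cm._m_lopt.copy(), ss.ControllerConfig())
        assert np.abs(F).max() < 1e-9
        assert np.abs(T).max() < 1e-9

    def test_upright_symmetric_model_has_no_lateral_forces(self, generic_model):
        cm = CompiledModel(generic_model)
        y = cm.build_state(preload=True)
        dy = cm.rhs(0.0, y, cm._m_lopt.copy(), ss.ControllerConfig())
        acc = dy[cm._sl_v].reshape(cm.nb, 3)
        assert np.abs(acc[:, 1] * cm.mass).max() < 1e-9
        wdot = dy[cm._sl_w].reshape(cm.nb, 3)
        # out-of-sagittal angular accelerations vanish as well
        assert np.abs(wdot[:, 0]).max() < 1e-9
        assert np.abs(wdot[:, 2]).max() < 1e-9

    def test_energy_conservation_undamped_mini_chain(self, mini_chain_energy):
        """< 0.1% mechanical-energy drift over 1 s free oscillation."""
        drift, E0 = mini_chain_energy
        assert drift < 1e-3 * max(E0, 1.0)


class TestSettling:
    def test_gravity_off_settles_near_build_pose(self, generic_model):
        import copy

        model = ss.build_generic_model()
        model.gravity = 0.0
        for name in model.ivds:
            model.ivds[name] = model.ivds[name].with_idp(0.0)
        sim = SpineSimulation(model, ss.ControllerConfig(),
                              desk_config(settle_max_time=8.0))
        state, phi_ref = sim.settle()
        cm = sim.compiled
        # prestrain and tone relax the column a few degrees; without
        # gravity it stays in the neighbourhood of the build pose
        assert abs(cm.lumbar_angle(state.y) - 22.5) < 5.0
        assert abs(cm.thoracic_angle(state.y) - 22.3) < 12.0
        X = state.y[cm._sl_x].reshape(cm.nb, 3)
        assert np.abs(X - cm.x0).max() < 0.05

    def test_settling_deepens_both_curvatures(self, settled, generic_sim):
        state, phi_ref = settled
        cm = generic_sim.compiled
        assert phi_ref > 22.5            # lumbar lordosis increased
        assert cm.thoracic_angle(state.y) > 22.3   # kyphosis increased
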
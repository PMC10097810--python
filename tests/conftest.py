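"""Shared fixtures.

The generic model and the (expensive) settled / flexion-run fixtures are
session-scoped so the end-to-end protocol is executed once and shared by
the analysis and acceptance tests.  Desk-scale integrator tolerances are
used for the protocol runs (documented in the methods note); analytic and
element-level tests use their own tolerances.
"""

from __future__ import annotations

import numpy as np
import pytest

import spinesim as ss
from spinesim.dynamics import DynamicsConfig, SpineSimulation


def desk_config(**kw) -> DynamicsConfig:
    """Integrator/protocol settings for desk-scale end-to-end runs."""
    defaults = dict(
        method="split-rk4", fixed_dt=5e-4,
        settle_rate_rot=2e-3, settle_rate_trans=2e-4,
        settle_max_time=15.0, settle_check_dt=0.25,
        flexion_max_time=40.0, output_rate=25.0,
    )
    defaults.update(kw)
    return DynamicsConfig(**defaults)


@pytest.fixture(scope="session")
def generic_model():
    return ss.build_generic_model()


@pytest.fixture(scope="session")
def generic_sim(generic_model):
    return SpineSimulation(generic_model, ss.ControllerConfig(), desk_config())


@pytest.fixture(scope="session")
def settled(generic_sim):
    state, phi_ref = generic_sim.settle()
    return state, phi_ref


@pytest.fixture(scope="session")
def flexion_run(generic_sim, settled):
    state, _ = settled
    return generic_sim.run_flexion(state.copy())


def descend_to_peak(sim, state, phi_ref, hold_for=1.0, max_time=20.0):
    """Drive the descent until the peak posture has been held briefly."""
    import spinesim.controller as ctr
    from spinesim.dynamics import SystemState

    sched = sim.make_target_schedule(state)
    y = state.y.copy()
    t, last_switch = 0.0, -np.inf
    cm = sim.compiled
    while t < max_time:
        if t - last_switch >= sim.config.control_dt:
            before = (sched.index, sched.phase)
            sched = ctr.update_phase(
                cm.lumbar_angle(y) - phi_ref, t, sched, sim.controller)
            if (sched.index, sched.phase) != before:
                last_switch = t
        if (sched.phase == "hold" and sched.hold_started is not None
                and t - sched.hold_started >= hold_for):
            break
        lam = sim._lambda_vector(sched)
        sol = sim._solve(y, t, t + 0.25, lam)
        y, t = sol.y[:, -1].copy(), t + 0.25
    return SystemState(y, t, phi_ref), sim._lambda_vector(sched)


@pytest.fixture(scope="session")
def cocontraction_states(generic_model, generic_sim, settled, flexion_run):
    """Settled and peak-flexed states with local stiffnesses per level.

    The "original" level reuses the session's settled state and flexion
    run (its controller config is the original preset); the lower and
    higher levels settle and descend independently.
    """
    from spinesim.dynamics import SystemState

    out = {}
    for preset in ("lower", "higher"):
        ctrl = ss.ControllerConfig.from_preset(preset)
        sim = SpineSimulation(generic_model, ctrl, desk_config())
        state, phi_ref = sim.settle()
        k_equ = ss.fsu_stiffness_local(sim, state, "L4/5")
        peak_state, lam_peak = descend_to_peak(sim, state, phi_ref)
        k_peak = ss.fsu_stiffness_local(sim, peak_state, "L4/5",
                                        lambdas=lam_peak)
        out[preset] = {
            "phi_lum_equ": phi_ref,
            "k_local_equ": k_equ,
            "dphi_lum_peak": sim.compiled.lumbar_angle(peak_state.y) - phi_ref,
            "k_local_peak": k_peak,
            "state": state,
            "sim": sim,
        }
    # original preset: state mid-hold of the shared flexion run
    sim = generic_sim
    state, phi_ref = settled
    run = flexion_run
    t_hold = next(t for t, k, _ in run.events if k == "hold")
    idx = int(np.searchsorted(run.times, t_hold + 1.0))
    peak_state = SystemState(run.states[idx].copy(), run.times[idx], phi_ref)
    sched = sim.make_target_schedule(state)
    lam_peak = np.array([sched.lambdas[-1][n]
                         for n in sim.compiled.muscle_names])
    out["original"] = {
        "phi_lum_equ": phi_ref,
        "k_local_equ": ss.fsu_stiffness_local(sim, state, "L4/5"),
        "dphi_lum_peak": sim.compiled.lumbar_angle(peak_state.y) - phi_ref,
        "k_local_peak": ss.fsu_stiffness_local(sim, peak_state, "L4/5",
                                               lambdas=lam_peak),
        "state": state,
        "sim": sim,
    }
    return out


@pytest.fixture(scope="session")
def pendulum_period():
    """Measured vs closed-form period of the stiff-rod pendulum oracle."""
    from test_dynamics import PEND_I_COM, pendulum_model, rotate_about_pivot
    from spinesim.dynamics import DynamicsConfig

    length, mass = 0.5, 1.0
    sim = SpineSimulation(pendulum_model(length, mass),
                          config=DynamicsConfig(method="split-rk4",
                                                fixed_dt=2e-4,
                                                output_rate=2000.0))
    cm = sim.compiled
    theta0 = np.deg2rad(2.0)
    y = rotate_about_pivot(cm, cm.build_state(), theta0)
    sol = sim._solve(y, 0.0, 4.6, np.zeros(0))
    angles = np.array([cm.joint_sagittal_angles(s)[0] for s in sol.y.T])
    sign = np.sign(angles)
    idx = np.where((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    crossings = [
        sol.t[i] + (sol.t[i + 1] - sol.t[i]) * angles[i]
        / (angles[i] - angles[i + 1]) for i in idx
    ]
    period = float(np.mean(np.diff(crossings)))
    I_pivot = PEND_I_COM + mass * length**2
    expected = 2 * np.pi * np.sqrt(I_pivot / (mass * 9.81 * length))         * (1.0 + theta0**2 / 16.0)
    return period, expected, len(crossings)


@pytest.fixture(scope="session")
def mini_chain_energy():
    """(drift, reference energy) of the undamped mini-chain oscillation."""
    from test_dynamics import undamped_mini_chain
    from spinesim.dynamics import DynamicsConfig

    model = undamped_mini_chain()
    sim = SpineSimulation(model, config=DynamicsConfig(
        method="split-rk4", fixed_dt=1e-4, output_rate=50.0))
    cm = sim.compiled
    y = cm.build_state()
    TH = y[cm._sl_th].reshape(cm.nb, 3)
    TH[-1, 1] += 0.05
    y[cm._sl_th] = TH.ravel()
    E0 = cm.mechanical_energy(y)
    sol = sim._solve(y, 0.0, 1.0, np.zeros(0))
    E1 = cm.mechanical_energy(sol.y[:, -1])
    return abs(E1 - E0), abs(E0)
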
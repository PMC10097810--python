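"""Spinal angles, load sharing and FSU stiffness post-processing."""

import numpy as np
import pytest

import spinesim as ss
from spinesim.analysis import (
    fsu_stiffness_local,
    fsu_stiffness_mean,
    load_sharing,
    spinal_angles,
    cocontraction_table,
)
from spinesim.dynamics import (
    CompiledModel,
    DynamicsConfig,
    RunResult,
    SpineSimulation,
    SystemState,
)
from spinesim.geometry import Frame
from spinesim.model import apply_joint_rotations


def synthetic_run(joint_names, coeffs, n=60, eval_to=-22.0, my_coeffs=None):
    """RunResult with exactly linear per-structure contributions."""
    angles = np.linspace(0.0, eval_to, n)
    nj = len(joint_names)
    wrenches = np.zeros((n, nj, 3, 6))
    for s, (a, b) in enumerate(coeffs):
        wrenches[:, 0, s, 2] = a + b * angles
    if my_coeffs is not None:
        for s, (a, b) in enumerate(my_coeffs):
            wrenches[:, 0, s, 4] = a + b * angles
    ja = np.tile(angles[:, None], (1, nj))
    return RunResult(
        times=np.linspace(0, 10, n),
        states=np.zeros((n, 2)),
        dphi_lum=angles.copy(),
        phi_lum=23.0 + angles,
        phi_tho=np.full(n, 25.0),
        joint_angles=ja,
        wrenches=wrenches,
        joint_names=list(joint_names),
    )


class TestSpinalAngles:
    def test_straight_column_zero_angles(self, generic_model):
        frames = {name: Frame() for name in ("S1", "L1", "T1", "T12")}
        sample = spinal_angles(frames, generic_model)
        assert sample.phi_lum == 0.0
        assert sample.phi_tho == 0.0

    def test_equal_lumbar_joint_rotations_add(self, generic_model):
        frames = {b.name: b.frame.copy() for b in generic_model.bodies}
        base = spinal_angles(frames, generic_model)
        delta = np.deg2rad(1.5)
        rot = {j: delta for j in ("L5/S1", "L4/5", "L3/4", "L2/3", "L1/2")}
        frames2 = apply_joint_rotations(generic_model, frames, rot)
        flexed = spinal_angles(frames2, generic_model)
        # five equal sagittal joint rotations tip L1 by five deltas
        assert base.phi_lum - flexed.phi_lum == pytest.approx(5 * 1.5, abs=1e-9)

    def test_generic_build_pose_recovers_generator_angles(self, generic_model):
        frames = {b.name: b.frame for b in generic_model.bodies}
        sample = spinal_angles(frames, generic_model)
        assert sample.phi_lum == pytest.approx(22.5, abs=1e-6)


class TestLoadSharing:
    def test_linear_contributions_recovered_exactly(self):
        coeffs = [(-300.0, 5.0), (40.0, -2.0), (60.0, -1.0)]
        run = synthetic_run(["L4/5"], coeffs)
        recs = load_sharing(run, "L4/5", -20.0, "F_z")
        for rec, (a, b) in zip(recs, coeffs):
            assert rec.fitted_value == pytest.approx(a + b * -20.0, abs=1e-10)
        assert sum(r.percentage for r in recs) == pytest.approx(100.0, abs=1e-9)

    def test_percentages_sum_to_hundred(self):
        run = synthetic_run(["L4/5"], [(-10.0, 1.0), (3.0, 0.5), (7.0, -1.5)])
        recs = load_sharing(run, "L4/5")
        assert sum(r.percentage for r in recs) == pytest.approx(100.0, abs=1e-9)

    def test_invariant_under_time_reparametrisation(self):
        coeffs = [(-300.0, 5.0), (40.0, -2.0), (60.0, -1.0)]
        run = synthetic_run(["L4/5"], coeffs)
        warped = synthetic_run(["L4/5"], coeffs)
        warped.times = np.sqrt(np.linspace(0.0, 100.0, warped.times.size))
        a = load_sharing(run, "L4/5")
        b = load_sharing(warped, "L4/5")
        for ra, rb in zip(a, b):
            assert ra.fitted_value == rb.fitted_value
            assert ra.percentage == rb.percentage

    def test_unreached_eval_angle_rejected(self):
        run = synthetic_run(["L4/5"], [(-10.0, 1.0), (0.1, 0.0), (0.1, 0.0)],
                            eval_to=-5.0)
        with pytest.raises(ValueError, match="reach"):
            load_sharing(run, "L4/5", -20.0)


class TestMeanStiffness:
    def test_constructed_slope_recovered(self):
        run = synthetic_run(
            ["L4/5"], [(0.0, 0.0)] * 3,
            my_coeffs=[(-1.0, 8.0), (0.0, 0.0), (0.0, 0.0)])
        assert fsu_stiffness_mean(run, "L4/5") == pytest.approx(8.0, abs=1e-10)

    def test_constant_torque_zero_stiffness(self):
        run = synthetic_run(
            ["L4/5"], [(0.0, 0.0)] * 3,
            my_coeffs=[(-5.0, 0.0), (0.0, 0.0), (0.0, 0.0)])
        assert fsu_stiffness_mean(run, "L4/5") == pytest.approx(0.0, abs=1e-12)

    def test_balanced_noise_leaves_slope_near_truth(self):
        rng = np.random.default_rng(9)
        run = synthetic_run(
            ["L4/5"], [(0.0, 0.0)] * 3,
            my_coeffs=[(-1.0, 8.0), (0.0, 0.0), (0.0, 0.0)])
        run.wrenches[:, 0, 0, 4] += rng.normal(0.0, 0.5, run.times.size)
        assert fsu_stiffness_mean(run, "L4/5") == pytest.approx(8.0, abs=0.2)


@pytest.fixture(scope="module")
def bushing_only_sim():
    model = ss.build_generic_model()
    model.ligaments = []
    model.muscles = []
    for name in model.ivds:
        model.ivds[name] = model.ivds[name].with_idp(0.0)
    sim = SpineSimulation(model, ss.ControllerConfig(),
                          DynamicsConfig(method="split-rk4"))
    state = SystemState(sim.compiled.build_state(), 0.0, 0.0)
    return sim, state


class TestLocalStiffness:
    def test_bushing_only_lumbar_joint_equals_preset(self, bushing_only_sim):
        sim, state = bushing_only_sim
        k = fsu_stiffness_local(sim, state, "L4/5", delta_deg=0.1)
        assert k == pytest.approx(270.0 * np.pi / 180.0, rel=1e-4)
        assert k == pytest.approx(4.712, abs=2e-3)

    def test_central_difference_second_order(self, bushing_only_sim):
        sim, state = bushing_only_sim
        k1 = fsu_stiffness_local(sim, state, "L3/4", delta_deg=0.4)
        k2 = fsu_stiffness_local(sim, state, "L3/4", delta_deg=0.2)
        assert k1 == pytest.approx(k2, rel=1e-3)

    def test_zero_perturbation_rejected(self, bushing_only_sim):
        sim, state = bushing_only_sim
        with pytest.raises(ValueError):
            fsu_stiffness_local(sim, state, "L4/5", delta_deg=0.0)


class TestCocontractionTable:
    def rows(self, k_equ):
        return {
            label: {
                "phi_lum_equ": 25.0,
                "k_local_equ": k,
                "dphi_lum_peak": -21.0,
                "k_local_peak": k + 2.0,
            }
            for label, k in zip(("lower", "original", "higher"), k_equ)
        }

    def test_identical_runs_zero_percent_differences(self):
        table = cocontraction_table(self.rows([5.7, 5.7, 5.7]))
        assert np.allclose(table["k_local_equ_pct"], 0.0)
        assert np.allclose(table["k_local_peak_pct"], 0.0)

    def test_percentages_recompute_from_raw_columns(self):
        table = cocontraction_table(self.rows([5.4, 5.7, 6.1]))
        for label in ("lower", "higher"):
            expected = 100.0 * (table.loc[label, "k_local_equ"]
                                / table.loc["original", "k_local_equ"] - 1.0)
            assert table.loc[label, "k_local_equ_pct"] == pytest.approx(expected)

    def test_missing_run_rejected(self):
        rows = self.rows([5.4, 5.7, 6.1])
        del rows["higher"]
        with pytest.raises(KeyError):
            cocontraction_table(rows)
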
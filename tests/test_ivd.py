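"""Bushing-element disc model: displacements, wrenches, energy conservation."""

import numpy as np
import pytest
from scipy.linalg import logm
from scipy.spatial.transform import Rotation

import spinesim as ss
from spinesim.ivd import (
    REGION_PRESETS,
    BushingParams,
    JointDisplacement,
    bushing_potential,
    bushing_wrench,
    idp_offset_force,
    proximal_mass,
    rotational_displacement,
)

RNG = np.random.default_rng(7)


# published stiffness table, re-stated independently of the module constants
TABLE = {
    "thoracic": ((100e3, 110e3, 1240e3), (172.5, 15.0, 149.0)),
    "lumbar": ((109e3, 130e3, 800e3), (200.0, 270.0, 250.0)),
    "lumbosacral": ((473e3, 523e3, 2420e3), (377.0, 575.0, 832.0)),
}


def test_region_presets_match_published_table():
    for region, (kt, kr) in TABLE.items():
        p = BushingParams.from_region(region)
        assert tuple(p.k_trans) == kt
        assert tuple(p.k_rot) == kr
        assert p.d_damp_force == 0.01 and p.d_damp_torque == 0.01


def test_lumbar_lateral_bending_is_raised_value_in_both_variants():
    # 200 Nm/rad (not the literature 93) for lumbar lateral bending,
    # in the generic and the individualised parameter sets alike
    generic = ss.build_generic_model()
    lm = ss.export_landmarks(generic)
    indiv = ss.individualise(lm, generic, tilt_deg=0.0)
    for model in (generic, indiv):
        for joint in ("T12/L1", "L1/2", "L2/3", "L3/4", "L4/5"):
            assert model.ivds[joint].k_rot[0] == 200.0


class TestRotationalDisplacement:
    def test_identity(self):
        assert np.allclose(rotational_displacement(np.eye(3)), 0.0)

    def test_single_axis(self):
        R = Rotation.from_rotvec([0.0, 0.1, 0.0]).as_matrix()
        assert np.allclose(rotational_displacement(R), [0.0, 0.1, 0.0])

    def test_matches_matrix_logarithm(self):
        for _ in range(10):
            rv = RNG.normal(0, 0.2, 3)
            R = Rotation.from_rotvec(rv).as_matrix()
            L = logm(R)
            expected = np.array([L[2, 1], L[0, 2], L[1, 0]])
            assert np.allclose(rotational_displacement(R), expected, atol=1e-10)

    def test_half_turn_rejected(self):
        R = Rotation.from_rotvec([0.0, np.pi, 0.0]).as_matrix()
        with pytest.raises(ValueError):
            rotational_displacement(R)


class TestBushingWrench:
    def test_pure_axial_compression_lumbar(self):
        p = BushingParams.from_region("lumbar")
        d = JointDisplacement(translation=[0.0, 0.0, -0.001])
        w = bushing_wrench(d, p)
        assert np.isclose(abs(w.force[2]), 800.0)
        assert np.allclose(w.torque, 0.0)

    def test_zero_displacement_zero_wrench(self):
        w = bushing_wrench(JointDisplacement(), BushingParams.from_region("thoracic"))
        assert np.allclose(w.force, 0.0) and np.allclose(w.torque, 0.0)

    def test_single_axis_rotation_reduces_to_identity_transform(self):
        p = BushingParams.from_region("lumbar")
        th = 0.15
        w = bushing_wrench(JointDisplacement(rotation=[0.0, th, 0.0]), p)
        assert np.allclose(w.torque, [0.0, -p.k_rot[1] * th, 0.0], atol=1e-12)

    def test_elastic_wrench_is_negative_potential_gradient(self):
        p = BushingParams.from_region("lumbar")
        for _ in range(5):
            tr = RNG.normal(0, 1e-3, 3)
            rv = RNG.normal(0, 0.15, 3)
            w = bushing_wrench(JointDisplacement(translation=tr, rotation=rv), p)
            # translations: direct gradient
            h = 1e-7
            for i in range(3):
                dp = tr.copy()
                dp[i] += h
                dm = tr.copy()
                dm[i] -= h
                Vp = bushing_potential(JointDisplacement(translation=dp, rotation=rv), p)
                Vm = bushing_potential(JointDisplacement(translation=dm, rotation=rv), p)
                grad = (Vp - Vm) / (2 * h)
                assert np.isclose(w.force[i], -grad, rtol=1e-6, atol=1e-8)
            # rotations: the Cartesian torque is minus the gradient of V with
            # respect to the orientation, i.e. -dV/dphi along any rotation
            # perturbation R -> exp(h n) R applied in the joint frame
            R0 = Rotation.from_rotvec(rv).as_matrix()
            h = 1e-6
            for i, n in enumerate(np.eye(3)):
                Rp = Rotation.from_rotvec(h * n).as_matrix() @ R0
                Rm = Rotation.from_rotvec(-h * n).as_matrix() @ R0
                dplus = JointDisplacement(
                    translation=tr, rotation=Rotation.from_matrix(Rp).as_rotvec())
                dminus = JointDisplacement(
                    translation=tr, rotation=Rotation.from_matrix(Rm).as_rotvec())
                grad = (bushing_potential(dplus, p) - bushing_potential(dminus, p)) / (2 * h)
                assert np.isclose(w.torque[i], -grad, rtol=1e-5, atol=1e-7)

    def test_axis_independence_with_diagonal_stiffness(self):
        p = BushingParams.from_region("thoracic")
        base = JointDisplacement(translation=[1e-4, 0, 0], rotation=[0.05, 0, 0])
        w0 = bushing_wrench(base, p)
        pert = JointDisplacement(translation=[1e-4, 5e-4, 0], rotation=[0.05, 0, 0])
        w1 = bushing_wrench(pert, p)
        assert np.isclose(w0.force[0], w1.force[0])
        assert np.isclose(w0.force[2], w1.force[2])

    def test_closed_rotation_path_does_no_work(self):
        """Elastic torque integrates to ~zero around a closed rotation loop."""
        p = BushingParams.from_region("lumbar")
        ts = np.linspace(0, 2 * np.pi, 4000)
        # closed loop in orientation space, not a single-axis excursion
        rvs = 0.2 * np.column_stack(
            [np.sin(ts), np.sin(2 * ts) * 0.5, 1.0 - np.cos(ts)])
        work = 0.0
        for a, b in zip(rvs[:-1], rvs[1:]):
            mid = 0.5 * (a + b)
            w = bushing_wrench(JointDisplacement(rotation=mid), p)
            Ra = Rotation.from_rotvec(a).as_matrix()
            Rb = Rotation.from_rotvec(b).as_matrix()
            drot = Rotation.from_matrix(Rb @ Ra.T).as_rotvec()  # spatial increment
            work += float(np.dot(w.torque, drot))
        V = bushing_potential(JointDisplacement(rotation=rvs[0]), p)
        assert abs(work) < 1e-6 * max(V, 1.0)


class TestIdpOffset:
    def test_total_proximal_mass_at_lumbosacral_joint(self, generic_model):
        m = generic_model
        expected = 0.0
        for b in m.bodies:
            if b.name in ("pelvis", "S1"):
                continue
            expected += b.mass + sum(pm for pm, _ in b.attached_point_masses)
        assert np.isclose(proximal_mass(m, "L5/S1"), expected)
        assert np.isclose(idp_offset_force(m, "L5/S1"), 9.81 * expected)

    def test_topmost_joint_carries_only_t1(self, generic_model):
        m = generic_model
        t1 = m.body("T1")
        expected = t1.mass + sum(pm for pm, _ in t1.attached_point_masses)
        assert np.isclose(proximal_mass(m, "T1/2"), expected)

    def test_unknown_joint_rejected(self, generic_model):
        with pytest.raises(KeyError):
            idp_offset_force(generic_model, "C1/2")

    def test_offsets_frozen_in_model(self, generic_model):
        for j, p in generic_model.ivds.items():
            assert np.isclose(p.idp_offset, idp_offset_force(generic_model, j))
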
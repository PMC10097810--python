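"""Generic builder and landmark individualisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import spinesim as ss
from spinesim.geometry import Frame
from spinesim.model import (
    GenericGeometry,
    LIGAMENT_JOINTS,
    VERTEBRAE,
    elongate_pair,
    joint_frames_from_endplates,
    scale_trunk_masses,
    trunk_slice_masses_from_volumes,
    vb_frames_from_endplates,
)


class TestStructuralCounts:
    def test_body_joint_and_dof_counts(self, generic_model):
        assert len(generic_model.bodies) == 20
        assert len(generic_model.joints) == 17
        assert generic_model.n_dof == 102

    def test_ligament_thread_count(self, generic_model):
        assert len(generic_model.ligaments) == 192
        assert all(l.joint in LIGAMENT_JOINTS for l in generic_model.ligaments)
        # twelve threads per level between T1/2 and L4/5, none at L5/S1
        for joint in LIGAMENT_JOINTS:
            assert sum(1 for l in generic_model.ligaments if l.joint == joint) == 12
        assert not any(l.joint == "L5/S1" for l in generic_model.ligaments)

    def test_chain_is_single_path(self, generic_model):
        order = generic_model.chain_order()
        assert order[0] == "pelvis" and order[-1] == "T1"
        assert len(order) == 19  # linea alba rides T12, outside the chain

    def test_self_intersecting_geometry_rejected(self):
        with pytest.raises(ValueError):
            ss.build_generic_model(
                geometry=GenericGeometry(lordosis_deg=200.0))


class TestMirrorSymmetry:
    def test_element_lateral_coordinates_in_pairs(self, generic_model):
        m = generic_model
        lig_y = sorted(round(float(l.p_parent[1]), 12) for l in m.ligaments)
        assert lig_y == sorted(-y for y in lig_y)
        mus_y = sorted(
            round(float(pp.point[1]), 12)
            for mus in m.muscles for pp in mus.path
        )
        assert mus_y == sorted(-y for y in mus_y)

    def test_frames_lie_in_sagittal_plane(self, generic_model):
        for b in generic_model.bodies:
            assert b.frame.position[1] == 0.0
            assert b.frame.rotvec[0] == 0.0 and b.frame.rotvec[2] == 0.0


class TestMassPlumbing:
    def test_trunk_point_masses_sum_to_fraction_of_body_weight(self, generic_model):
        total = sum(
            pm for b in generic_model.bodies for pm, _ in b.attached_point_masses
        )
        assert total == pytest.approx(29.4, rel=1e-12)

    def test_uniform_scaling(self):
        assert np.allclose(scale_trunk_masses([1.0, 1.0], 4.0), [2.0, 2.0])

    @given(st.lists(st.floats(0.1, 10.0), min_size=2, max_size=20),
           st.floats(0.5, 100.0))
    @settings(deadline=None, max_examples=100)
    def test_ratios_preserved(self, raw, target):
        out = scale_trunk_masses(raw, target)
        assert out.sum() == pytest.approx(target, rel=1e-12)
        ratios = out / out[0]
        expected = np.asarray(raw) / raw[0]
        assert np.allclose(ratios, expected, rtol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            scale_trunk_masses([], 10.0)

    def test_slice_masses_from_volumes(self):
        assert trunk_slice_masses_from_volumes([1000.0])[0] == pytest.approx(1.04)
        assert trunk_slice_masses_from_volumes([0.0])[0] == 0.0
        # synthetic slice volumes totalling 32.5 L give 33.8 kg in total
        vols = np.full(17, 32500.0 / 17)
        assert trunk_slice_masses_from_volumes(vols).sum() == pytest.approx(33.8)

    def test_negative_volume_rejected(self):
        with pytest.raises(ValueError):
            trunk_slice_masses_from_volumes([-1.0])


class TestBuildPoseAngles:
    def test_generator_reproduces_configured_curvatures(self, generic_model):
        frames = {b.name: b.frame for b in generic_model.bodies}
        sample = ss.spinal_angles(frames, generic_model)
        assert sample.phi_lum == pytest.approx(22.5, abs=1e-6)
        assert sample.phi_tho == pytest.approx(22.3, abs=1e-6)


def _landmarks_two_parallel_endplates():
    eps = {}
    for v in VERTEBRAE + ["S1"]:
        eps[(v, "sup")] = Frame(np.zeros(3), np.zeros(3))
        eps[(v, "inf")] = Frame(np.zeros(3), np.zeros(3))
    eps[("L5", "inf")] = Frame(np.array([0.0, 0.0, 0.04]), np.zeros(3))
    eps[("S1", "sup")] = Frame(np.array([0.0, 0.0, 0.0]), np.zeros(3))
    return ss.LandmarkSet(endplates=eps, muscle_points={}, ligament_points={})


class TestEndplateFrames:
    def test_joint_centre_is_endplate_midpoint(self):
        lm = _landmarks_two_parallel_endplates()
        frames = joint_frames_from_endplates(lm)
        assert frames["L5/S1"].position[2] == pytest.approx(0.02)

    def test_identical_orientations_pass_through(self):
        lm = _landmarks_two_parallel_endplates()
        rv = np.array([0.0, 0.2, 0.0])
        lm.endplates[("L5", "inf")] = Frame(np.array([0, 0, 0.04]), rv)
        lm.endplates[("S1", "sup")] = Frame(np.zeros(3), rv)
        assert np.allclose(joint_frames_from_endplates(lm)["L5/S1"].rotvec, rv)

    def test_random_perturbation_matches_brute_force_average(self):
        rng = np.random.default_rng(5)
        lm = _landmarks_two_parallel_endplates()
        for key in lm.endplates:
            lm.endplates[key] = Frame(rng.normal(0, 0.02, 3),
                                      rng.normal(0, 0.05, 3))
        jf = joint_frames_from_endplates(lm)
        vf = vb_frames_from_endplates(lm)
        ep = lm.endplates
        for v in ("T5", "L3"):
            expect = 0.5 * (ep[(v, "sup")].position + ep[(v, "inf")].position)
            assert np.allclose(vf[v].position, expect)
            expect_rv = 0.5 * (ep[(v, "sup")].rotvec + ep[(v, "inf")].rotvec)
            assert np.allclose(vf[v].rotvec, expect_rv)
        expect = 0.5 * (ep[("L5", "sup")].position + ep[("L4", "inf")].position)
        assert np.allclose(jf["L4/5"].position, expect)

    def test_missing_endplate_names_the_level(self):
        lm = _landmarks_two_parallel_endplates()
        del lm.endplates[("T7", "inf")]
        with pytest.raises(KeyError, match="T7"):
            joint_frames_from_endplates(lm)


class TestIndividualisation:
    def test_round_trip_reproduces_generic_attachments(self, generic_model):
        lm = ss.export_landmarks(generic_model)
        indiv = ss.individualise(lm, generic_model, tilt_deg=0.0)
        for mus0, mus1 in zip(generic_model.muscles, indiv.muscles):
            for pp0, pp1 in zip(mus0.path, mus1.path):
                w0 = generic_model.body(pp0.body).frame.transform_point(pp0.point)
                w1 = indiv.body(pp1.body).frame.transform_point(pp1.point)
                assert np.allclose(w0, w1, atol=1e-9)
        for l0, l1 in zip(generic_model.ligaments, indiv.ligaments):
            w0 = generic_model.body(l0.parent_body).frame.transform_point(l0.p_parent)
            w1 = indiv.body(l1.parent_body).frame.transform_point(l1.p_parent)
            assert np.allclose(w0, w1, atol=1e-9)
            assert l1.params.l0 == pytest.approx(l0.params.l0, rel=1e-9)

    def test_cap_pair_elongated_about_midpoint(self):
        p1 = np.array([0.0, 0.0, 0.0])
        p2 = np.array([0.0, 0.0, 0.0008])
        q1, q2 = elongate_pair(p1, p2, 0.008)
        assert np.linalg.norm(q2 - q1) == pytest.approx(0.008)
        assert np.allclose(0.5 * (q1 + q2), 0.5 * (p1 + p2))

    def test_two_degree_tilt_rotates_t1_about_pelvis(self, generic_model):
        lm = ss.export_landmarks(generic_model)
        indiv = ss.individualise(lm, generic_model, tilt_deg=2.0)
        pelvis = generic_model.body("pelvis").frame
        R = Rotation.from_rotvec(np.deg2rad(2.0) * np.array([0.0, 1.0, 0.0]))
        expected = pelvis.position + R.apply(
            generic_model.body("T1").frame.position - pelvis.position)
        assert np.allclose(indiv.body("T1").frame.position, expected, atol=1e-9)
        # the rotation moves T1 anteriorly (forward tilt)
        assert indiv.body("T1").frame.position[0] > \
            generic_model.body("T1").frame.position[0]

    def test_roster_mismatch_lists_missing_elements(self, generic_model):
        lm = ss.export_landmarks(generic_model)
        victim = generic_model.muscles[0].name
        del lm.muscle_points[(victim, 0)]
        with pytest.raises(ValueError, match=victim):
            ss.individualise(lm, generic_model)

    def test_slice_masses_override(self, generic_model):
        lm = ss.export_landmarks(generic_model)
        lm.slice_masses = list(np.linspace(1.0, 3.0, 17))
        indiv = ss.individualise(lm, generic_model, tilt_deg=0.0)
        total = sum(pm for b in indiv.bodies for pm, _ in b.attached_point_masses)
        assert total == pytest.approx(sum(lm.slice_masses))
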
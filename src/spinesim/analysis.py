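"""Post-processing: spinal angles, load sharing and FSU stiffness.

Spinal angles are endplate-frame Cobb-style angles: the lumbar lordosis
phi_lum is the sagittal angle between the superior endplate frames of S1
and L1 (lordosis positive), the thoracic kyphosis phi_tho the angle
between T12 and T1 (kyphosis positive).  In the generic builder the
endplates are parallel to their vertebra, so the generator's configured
curvature angles and this analysis agree by construction.

Load sharing at a joint decomposes the net transmitted wrench into the
IVD, ligament and muscle contributions.  Each structure's contribution
over the descent is fitted linearly against the joint's sagittal angle
change; the fits are evaluated at the -20 degree lumbar flexion angle and
the absolute fitted values normalised to percentages.

FSU stiffness: k_mean is the slope of the linear fit of the net sagittal
joint torque over the descent (Nm/deg, magnitude); k_local is the central
difference of the net torque under a small static sagittal perturbation
of the single joint with all element forces re-evaluated and muscle
activity frozen at the posture's value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .dynamics import RunResult, SpineSimulation, SystemState
from .geometry import Frame, sagittal_inclination
from .model import ModelSpec, apply_joint_rotations

STRUCTURES = ("IVD", "ligament", "muscle")


@dataclass
class AngleSample:
    phi_lum: float     # deg, lordosis positive
    phi_tho: float     # deg, kyphosis positive


def spinal_angles(body_frames: Dict[str, Frame], model: ModelSpec) -> AngleSample:
    """Characteristic spinal angles of a posed model (degrees)."""
    def tilt(body: str) -> float:
        return sagittal_inclination(body_frames[body].rotvec)

    phi_lum = np.rad2deg(tilt("S1") - tilt("L1"))
    phi_tho = np.rad2deg(tilt("T1") - tilt("T12"))
    return AngleSample(float(phi_lum), float(phi_tho))


@dataclass
class LoadShareRecord:
    joint: str
    structure: str
    fitted_value: float   # N (F_z) or Nm (M_y) at the evaluation angle
    percentage: float     # of the summed absolute fitted values


def _descent_mask(run: RunResult, eval_angle: float) -> np.ndarray:
    """Samples of the descent: from start until the evaluation angle."""
    reached = np.where(run.dphi_lum <= eval_angle + 0.05)[0]
    if reached.size == 0:
        raise ValueError(
            f"run never reaches the evaluation angle {eval_angle} deg "
            f"(min dphi_lum = {run.dphi_lum.min():.2f})"
        )
    end = reached[0]
    mask = np.zeros(run.times.size, dtype=bool)
    mask[: end + 1] = True
    return mask


def load_sharing(
    run: RunResult,
    joint: str,
    eval_angle: float = -20.0,
    component: str = "F_z",
) -> List[LoadShareRecord]:
    """Structure-wise load sharing at a joint, evaluated at ``eval_angle``.

    For each structure the contribution (F_z in N or M_y in Nm) is fitted
    linearly against the joint's sagittal angle change over the descent;
    the absolute fitted values at the evaluation lumbar angle give the
    percentage shares.
    """
    ji = run.joint_names.index(joint)
    comp = {"F_z": 2, "M_y": 4}[component]
    mask = _descent_mask(run, eval_angle)
    x = run.joint_angles[mask, ji] - run.joint_angles[0, ji]
    # evaluation point: the joint angle where the lumbar angle change
    # crosses the evaluation angle (interpolated along the descent)
    dphi = run.dphi_lum[mask]
    x_eval = float(np.interp(eval_angle, dphi[::-1], x[::-1]))
    records = []
    fitted = []
    for si, sname in enumerate(STRUCTURES):
        yv = run.wrenches[mask, ji, si, comp]
        A = np.vstack([x, np.ones_like(x)]).T
        coef, *_ = np.linalg.lstsq(A, yv, rcond=None)
        fitted.append(float(coef[0] * x_eval + coef[1]))
    total = sum(abs(f) for f in fitted)
    for sname, f in zip(STRUCTURES, fitted):
        records.append(LoadShareRecord(
            joint=joint, structure=sname, fitted_value=f,
            percentage=100.0 * abs(f) / total if total > 0 else 0.0,
        ))
    return records


def fsu_stiffness_mean(run: RunResult, joint: str,
                       eval_angle: float = -20.0) -> float:
    """Mean FSU stiffness (Nm/deg): slope of net M_y over the descent.

    The slope is taken from the first and last value pair of the linear
    fit of the net joint torque against the joint angle change.
    """
    ji = run.joint_names.index(joint)
    mask = _descent_mask(run, eval_angle)
    if mask.sum() < 2:
        raise ValueError("need at least two descent samples")
    x = run.joint_angles[mask, ji]
    my = run.total_wrench[mask, ji, 4]
    A = np.vstack([x, np.ones_like(x)]).T
    coef, *_ = np.linalg.lstsq(A, my, rcond=None)
    # first/last value pair of the fit reproduces the fitted slope exactly
    y0, y1 = coef[0] * x[0] + coef[1], coef[0] * x[-1] + coef[1]
    return float(abs((y1 - y0) / (x[-1] - x[0])))


def fsu_stiffness_local(
    sim: SpineSimulation,
    state: SystemState,
    joint: str,
    delta_deg: float = 0.1,
    lambdas: Optional[np.ndarray] = None,
) -> float:
    """Local FSU stiffness (Nm/deg) about a static posture.

    Central difference of the net sagittal joint torque under a +/- delta
    rotation of the single joint (superior subtree rotated rigidly about
    the joint's lateral axis), with all element forces re-evaluated and
    muscle activity frozen at the posture's value.
    """
    if delta_deg == 0:
        raise ValueError("perturbation must be nonzero")
    cm = sim.compiled
    ji = cm.joint_names.index(joint)
    lam = lambdas if lambdas is not None else (
        sim.upright_lambdas() if cm.nm else np.zeros(0))

    def net_my(angle_deg: float) -> float:
        y = _perturbed_state(sim, state, joint, angle_deg, lam)
        wr = cm.structure_wrenches(y, lam, sim.controller)
        return float(wr[ji].sum(axis=0)[4])

    d = delta_deg
    slope = (net_my(+d) - net_my(-d)) / (2.0 * d)
    return float(-slope)   # restoring torque: stiffness positive when stable


def _perturbed_state(sim: SpineSimulation, state: SystemState,
                     joint: str, angle_deg: float,
                     lambdas: Optional[np.ndarray] = None) -> np.ndarray:
    """State with one joint rotated sagittally; velocities zeroed.

    The muscles follow the perturbation quasi-statically with their
    equilibrium points held at the posture's targets: the fibres
    re-equilibrate against the perturbed paths and the calcium state sits
    at the tonic stretch-reflex fixed point, so the measured stiffness is
    the posture's sustained (tonic) stiffness, which the co-contraction
    level modulates.
    """
    cm = sim.compiled
    frames = cm.body_frames(state.y)
    # reported joint angles are flexion-negative; the internal rotation
    # about the left-pointing lateral axis is flexion-positive
    new_frames = apply_joint_rotations(
        sim.model, frames, {joint: -np.deg2rad(angle_deg)})
    y = state.y.copy()
    X = y[cm._sl_x].reshape(cm.nb, 3).copy()
    TH = y[cm._sl_th].reshape(cm.nb, 3).copy()
    for name, i in cm.index.items():
        f = new_frames[name]
        X[i] = f.transform_point(cm.com_local[i])
        TH[i] = f.rotvec
    y[cm._sl_x] = X.ravel()
    y[cm._sl_th] = TH.ravel()
    y[cm._sl_v] = 0.0
    y[cm._sl_w] = 0.0
    if cm.nm:
        from spinesim import controller as _ctrl
        from spinesim.muscle import activity_from_gamma

        cfg = sim.controller
        lam = lambdas if lambdas is not None else sim.upright_lambdas()
        u_open = np.where(cm._m_is_abd, cfg.u_open_abdominal, cfg.u_open_back)
        l_mtu, _ = cm.muscle_geometry(y)
        LCE = y[cm._sl_lce].copy()
        gam = y[cm._sl_gam].copy()
        for _ in range(60):
            u = np.asarray(_ctrl.stimulation(
                u_open, cfg.kappa, LCE, lam, cm._m_lopt, cfg.mix_weight))
            gam = u
            act = activity_from_gamma(gam, cm._m_const)
            LCE = cm.fibre_backward_euler(LCE, 0.25, l_mtu,
                                          np.zeros(cm.nm), act)
        y[cm._sl_lce] = LCE
        y[cm._sl_gam] = gam
    return y


@dataclass
class StiffnessEstimate:
    k_mean: float
    k_local: float
    posture: str   # "equ" | "peak"


def _peak_state(run: RunResult) -> np.ndarray:
    """State in the middle of the held peak posture."""
    idx = int(np.argmin(run.dphi_lum))
    return run.states[idx]


def cocontraction_table(
    runs: Dict[str, dict],
    joint: str = "L4/5",
) -> pd.DataFrame:
    """Activation-sensitivity report across co-contraction levels.

    ``runs`` maps the preset label (lower | original | higher) to a dict
    with keys ``phi_lum_equ``, ``k_local_equ``, ``dphi_lum_peak``,
    ``k_local_peak`` and optional ``shares_Fz`` / ``shares_My`` (structure
    -> percentage).  Percent differences are reported against 'original'.
    """
    for label in ("lower", "original", "higher"):
        if label not in runs:
            raise KeyError(f"missing co-contraction run {label!r}")
    ref = runs["original"]
    rows = []
    for label in ("lower", "original", "higher"):
        r = runs[label]
        row = {
            "level": label,
            "phi_lum_equ_deg": r["phi_lum_equ"],
            "k_local_equ": r["k_local_equ"],
            "k_local_equ_pct": 100.0 * (r["k_local_equ"] / ref["k_local_equ"] - 1.0),
            "dphi_lum_peak_deg": r.get("dphi_lum_peak", np.nan),
            "k_local_peak": r.get("k_local_peak", np.nan),
            "k_local_peak_pct": 100.0 * (
                r.get("k_local_peak", np.nan) / ref.get("k_local_peak", np.nan) - 1.0
            ) if ref.get("k_local_peak") else np.nan,
        }
        for comp in ("Fz", "My"):
            shares = r.get(f"shares_{comp}")
            if shares:
                for sname, pct in shares.items():
                    row[f"{comp}_{sname}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def load_share_frame(records: List[LoadShareRecord],
                     quantity: str) -> pd.DataFrame:
    """Long-format report table (joint, structure, quantity, value)."""
    rows = []
    for r in records:
        rows.append({"joint": r.joint, "structure": r.structure,
                     "quantity": f"{quantity}_fitted", "value": r.fitted_value})
        rows.append({"joint": r.joint, "structure": r.structure,
                     "quantity": f"{quantity}_percent", "value": r.percentage})
    return pd.DataFrame(rows)
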
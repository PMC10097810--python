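"""Intervertebral disc as a six-component linear bushing element.

Each intervertebral joint carries a diagonal 6x6 stiffness (three shear /
compression stiffnesses in N/m, three rotational stiffnesses in Nm/rad),
a small uniform damping on all displacement rates, and a constant axial
offset force standing in for the intradiscal pressure of the nucleus
pulposus.  Rotational displacement is the rotation vector of the relative
joint rotation; elastic torques computed in rotation-vector space are
mapped back to the Cartesian joint frame by the transposed inverse left
Jacobian, which makes the elastic torque the exact negative gradient of
V = 1/2 theta^T K theta (energy conservation).

Region presets reproduce the published thoracic / lumbar / lumbo-sacral
stiffness table; note the lumbar lateral-bending value is the raised
200 Nm/rad (not the literature 93 Nm/rad) in both model variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import left_jacobian_inv, matrix_to_rotvec

#: Diagonal stiffness presets per spinal region.  Translational entries in
#: N/m (anterior shear, lateral shear, compression); rotational entries in
#: Nm/rad (lateral bending, flexion, axial rotation).
REGION_PRESETS: dict[str, dict[str, tuple[float, float, float]]] = {
    "thoracic": {
        "k_trans": (100_000.0, 110_000.0, 1_240_000.0),
        "k_rot": (172.5, 15.0, 149.0),
    },
    "lumbar": {
        "k_trans": (109_000.0, 130_000.0, 800_000.0),
        "k_rot": (200.0, 270.0, 250.0),
    },
    "lumbosacral": {
        "k_trans": (473_000.0, 523_000.0, 2_420_000.0),
        "k_rot": (377.0, 575.0, 832.0),
    },
}

#: Uniform damping factor: 0.01 Ns/m on force components and 0.01 Nms/rad on
#: torque components (energy dissipation effectively neglected).
DEFAULT_DAMPING = 0.01


@dataclass
class BushingParams:
    """Stiffness, damping and pressure offset of one intervertebral joint."""

    k_trans: np.ndarray = field(
        default_factory=lambda: np.array(REGION_PRESETS["lumbar"]["k_trans"])
    )
    k_rot: np.ndarray = field(
        default_factory=lambda: np.array(REGION_PRESETS["lumbar"]["k_rot"])
    )
    d_damp_force: float = DEFAULT_DAMPING
    d_damp_torque: float = DEFAULT_DAMPING
    idp_offset: float = 0.0  # N, constant compressive axial preload

    def __post_init__(self) -> None:
        self.k_trans = np.asarray(self.k_trans, dtype=float).reshape(3)
        self.k_rot = np.asarray(self.k_rot, dtype=float).reshape(3)
        if np.any(self.k_trans <= 0) or np.any(self.k_rot <= 0):
            raise ValueError("bushing stiffnesses must be positive")

    @classmethod
    def from_region(cls, region: str, idp_offset: float = 0.0) -> "BushingParams":
        try:
            preset = REGION_PRESETS[region]
        except KeyError:
            raise KeyError(
                f"unknown IVD region {region!r}; expected one of "
                f"{sorted(REGION_PRESETS)}"
            ) from None
        return cls(
            k_trans=np.array(preset["k_trans"]),
            k_rot=np.array(preset["k_rot"]),
            idp_offset=idp_offset,
        )

    def with_idp(self, idp_offset: float) -> "BushingParams":
        return replace(self, idp_offset=idp_offset)


@dataclass
class JointDisplacement:
    """Six joint displacements and their rates in the parent joint frame.

    ``translation`` are D1..D3 (m), ``rotation`` D4..D6 are the components
    of the rotation vector of the relative joint rotation (rad).
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    translation_rate: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation_rate: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "translation_rate", "rotation_rate"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        if np.linalg.norm(self.rotation) >= np.pi:
            raise ValueError("joint rotation magnitude must stay below pi")


@dataclass
class IVDWrench:
    """Force/torque the disc applies on the superior vertebra, joint frame.

    The same wrench acts with opposite sign on the inferior vertebra
    (equal and opposite application on both adjacent bodies).  The axial
    component follows the F_z convention: a loaded disc pushes the superior
    vertebra cranially, so the transmitted force on the subjacent vertebra
    (-force) is compressive/negative.
    """

    force: np.ndarray
    torque: np.ndarray


def rotational_displacement(R_rel: np.ndarray) -> np.ndarray:
    """Rotation-vector components of a relative joint rotation matrix.

    Raises for rotations of half a turn or more, far outside the
    physiological intervertebral range.
    """
    rv = matrix_to_rotvec(np.asarray(R_rel, dtype=float))
    if np.linalg.norm(rv) >= np.pi - 1e-12:
        raise ValueError("relative joint rotation >= pi rad is outside range")
    return rv


def elastic_torque(rotation: np.ndarray, k_rot: np.ndarray) -> np.ndarray:
    """Cartesian joint torque of the rotational springs.

    tau = Jinv(theta)^T @ (-K theta): with theta_dot = Jinv(theta) @ omega
    this is the unique torque satisfying tau . omega = -dV/dt for
    V = 1/2 theta^T K theta, i.e. the conservative transform.
    """
    theta = np.asarray(rotation, dtype=float)
    return left_jacobian_inv(theta).T @ (-np.asarray(k_rot) * theta)


def bushing_wrench(disp: JointDisplacement, p: BushingParams) -> IVDWrench:
    """Total bushing wrench (elastic + damping + IDP offset), joint frame."""
    Jinv = left_jacobian_inv(disp.rotation)
    force = -p.k_trans * disp.translation - p.d_damp_force * disp.translation_rate
    force = force + np.array([0.0, 0.0, -p.idp_offset])
    torque = Jinv.T @ (
        -p.k_rot * disp.rotation - p.d_damp_torque * disp.rotation_rate
    )
    return IVDWrench(force=force, torque=torque)


def bushing_potential(disp: JointDisplacement, p: BushingParams) -> float:
    """Elastic energy stored in the bushing (damping and IDP excluded)."""
    return float(
        0.5 * np.sum(p.k_trans * disp.translation**2)
        + 0.5 * np.sum(p.k_rot * disp.rotation**2)
    )


def proximal_mass(model, joint: str) -> float:
    """Total body + point mass cranial to ``joint`` (linea alba included)."""
    joints = {j.name: j for j in model.joints}
    if joint not in joints:
        raise KeyError(f"unknown joint {joint!r}")
    # Walk the chain: bodies cranial to the joint are the child body and
    # everything above it, plus bodies welded onto those.
    cranial = set()
    child = joints[joint].child
    order = model.chain_order()
    cranial.update(order[order.index(child):])
    for b in model.bodies:
        if b.weld_to in cranial:
            cranial.add(b.name)
    total = 0.0
    for b in model.bodies:
        if b.name in cranial:
            total += b.mass + sum(m for m, _ in b.attached_point_masses)
    return total


def idp_offset_force(model, joint: str) -> float:
    """Constant IDP offset: weight of all mass located proximally (N)."""
    return model.gravity * proximal_mass(model, joint)
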
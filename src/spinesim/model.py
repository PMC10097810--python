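"""Model construction: generic parametric spine and landmark individualisation.

The articulated model is a single kinematic chain pelvis - S1 - L5 ... T1.
All 17 intervertebral joints (T1/2 ... L5/S1) have six degrees of freedom;
the pelvis is rigidly connected to S1 and spatially constrained, and a thin
cylindrical linea-alba body (0.1 g) is rigidly fixed to T12 as abdominal
muscle attachment site.  Ribs are considered by their mass only (lumped
into the owning vertebra).  This gives 20 rigid bodies and 102 DOF.

The generic builder lays the column out parametrically: target lumbar
lordosis and thoracic kyphosis angles (defaults 22.5 and 22.3 degrees) are
distributed across levels by per-level shares, vertebral and disc heights
follow a stature-scaled table, and the base inclination is solved so the
column is sagittally balanced (T1 vertically above the L5/S1 joint).
Seventeen trunk point masses (Pearsall-style slice distribution, scaled to
36% of body weight = 29.4 kg for the 50th-percentile 81.5 kg male) hang
anteriorly of their vertebrae.

Individualisation rebuilds the chain from endplate landmarks: vertebral
frames are the average of a vertebra's two endplates, joint frames the
average of the adjacent endplates of neighbouring vertebrae (orientation
averaged through rotation vectors), all attachments are re-expressed in
the local vertebral frames, the column is tilted 2 degrees forward about
the pelvis to restore sagittal balance, capsular-ligament rest spans are
elongated to 8 mm about their midpoints, and every muscle/ligament
characteristic length is re-derived from the new geometry.
"""

from __future__ import annotations

import csv
import importlib.resources
import io as _io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .geometry import Frame, average_rotvecs, matrix_to_rotvec, rotvec_to_matrix
from .ivd import BushingParams, idp_offset_force
from .ligament import (
    DEFAULT_DAMPING as LIG_DAMPING,
    PRESTRAIN,
    RAW_CHARACTERISTIC_POINTS,
    LigamentParams,
    init_rest_length,
    scale_characteristic_points,
)
from .muscle import Ellipse, MTUParams, derive_mtu_params

GRAVITY = 9.81

THORACIC = [f"T{i}" for i in range(1, 13)]
LUMBAR = [f"L{i}" for i in range(1, 6)]
VERTEBRAE = THORACIC + LUMBAR                     # cranial to caudal
CHAIN_BODIES = ["pelvis", "S1"] + LUMBAR[::-1] + THORACIC[::-1]  # caudal up


def joint_name(upper: str, lower: str) -> str:
    if upper[0] == lower[0]:
        return f"{upper}/{lower[1:]}"
    return f"{upper}/{lower}"


#: Joint names cranial to caudal: T1/2 ... T11/12, T12/L1, L1/2 ... L4/5, L5/S1
JOINTS: List[str] = [
    joint_name(VERTEBRAE[i], VERTEBRAE[i + 1]) for i in range(len(VERTEBRAE) - 1)
] + ["L5/S1"]

#: Joints that carry ligaments (T1/2 down to L4/5; none cross L5/S1).
LIGAMENT_JOINTS: List[str] = JOINTS[:-1]

LIGAMENT_TYPES = ["ALL", "PLL", "LF", "SSL", "ITV", "CAP"]

TRUNK_MASS_FRACTION = 29.4 / 81.5  # 36% of the 50th-percentile body weight


# ---------------------------------------------------------------------------
# domain types


@dataclass(eq=False)
class BodySpec:
    """One rigid body of the chain."""

    name: str
    mass: float
    inertia: np.ndarray                       # 3x3, local frame, about own COM
    frame: Frame                              # world pose at build
    attached_point_masses: List[Tuple[float, np.ndarray]] = field(default_factory=list)
    weld_to: Optional[str] = None             # rigid attachment (S1, linea alba)
    height: float = 0.0                       # craniocaudal vertebral height

    def __post_init__(self) -> None:
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)
        if self.mass <= 0:
            raise ValueError(f"body {self.name}: mass must be positive")
        if not np.allclose(self.inertia, self.inertia.T):
            raise ValueError(f"body {self.name}: inertia must be symmetric")
        if np.any(np.linalg.eigvalsh(self.inertia) <= 0):
            raise ValueError(f"body {self.name}: inertia must be positive definite")
        self.attached_point_masses = [
            (float(m), np.asarray(o, dtype=float).reshape(3))
            for m, o in self.attached_point_masses
        ]

    @property
    def total_mass(self) -> float:
        return self.mass + sum(m for m, _ in self.attached_point_masses)


@dataclass(eq=False)
class JointSpec:
    """Six-DOF intervertebral joint; its frame equals the bushing frame."""

    name: str
    parent: str
    child: str
    frame: Frame
    dof: int = 6


@dataclass(eq=False)
class PathPoint:
    """One muscle path point bound to a body (local coordinates)."""

    body: str
    point: np.ndarray
    ellipse: Optional[Ellipse] = None

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float).reshape(3)


@dataclass(eq=False)
class MuscleElement:
    name: str
    group: str
    path: List[PathPoint]
    params: MTUParams


@dataclass(eq=False)
class LigamentElement:
    """One ligament thread spanning a single joint."""

    name: str
    ligament: str            # ALL | PLL | LF | SSL | ITV | CAP
    joint: str
    parent_body: str         # caudal vertebra
    child_body: str          # cranial vertebra
    p_parent: np.ndarray     # local attachment on the caudal body
    p_child: np.ndarray
    params: LigamentParams

    def __post_init__(self) -> None:
        self.p_parent = np.asarray(self.p_parent, dtype=float).reshape(3)
        self.p_child = np.asarray(self.p_child, dtype=float).reshape(3)


@dataclass(eq=False)
class LandmarkSet:
    """Global-frame anatomical landmarks in the individualisation style."""

    endplates: Dict[Tuple[str, str], Frame]                    # (vertebra, sup|inf)
    muscle_points: Dict[Tuple[str, int], Tuple[str, np.ndarray]]
    ligament_points: Dict[Tuple[str, str], np.ndarray]         # (thread, parent|child)
    pelvis: Frame = field(default_factory=Frame)
    slice_masses: Optional[List[float]] = None

    def __post_init__(self) -> None:
        for key, frame in self.endplates.items():
            if not (np.all(np.isfinite(frame.position)) and np.all(np.isfinite(frame.rotvec))):
                raise ValueError(f"non-finite endplate landmark {key}")


@dataclass(eq=False)
class ModelSpec:
    """Complete articulated model."""

    bodies: List[BodySpec]
    joints: List[JointSpec]
    ivds: Dict[str, BushingParams]
    ligaments: List[LigamentElement]
    muscles: List[MuscleElement]
    gravity: float = GRAVITY
    meta: Dict = field(default_factory=dict)

    def body(self, name: str) -> BodySpec:
        for b in self.bodies:
            if b.name == name:
                return b
        raise KeyError(f"unknown body {name!r}")

    def joint(self, name: str) -> JointSpec:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"unknown joint {name!r}")

    def muscle(self, name: str) -> MuscleElement:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(f"unknown muscle {name!r}")

    @property
    def n_dof(self) -> int:
        return sum(j.dof for j in self.joints)

    def chain_order(self) -> List[str]:
        """Chain bodies caudal to cranial (welded bodies excluded)."""
        parents = {j.child: j.parent for j in self.joints}
        children = {j.parent: j.child for j in self.joints}
        root = next(iter(set(parents.values()) - set(parents)))
        order = [root]
        while order[-1] in children:
            order.append(children[order[-1]])
        # the root may ride on a welded base (S1 on the pelvis)
        base = []
        carrier = self.body(root).weld_to
        while carrier is not None:
            base.insert(0, carrier)
            carrier = self.body(carrier).weld_to
        return base + order

    def validate(self) -> None:
        names = {b.name for b in self.bodies}
        for j in self.joints:
            if j.parent not in names or j.child not in names:
                raise ValueError(f"joint {j.name}: unresolved body")
        for lig in self.ligaments:
            if lig.parent_body not in names or lig.child_body not in names:
                raise ValueError(f"ligament {lig.name}: unresolved body")
        for mus in self.muscles:
            for pp in mus.path:
                if pp.body not in names:
                    raise ValueError(f"muscle {mus.name}: unresolved body {pp.body}")


# ---------------------------------------------------------------------------
# elementary mass plumbing


def scale_trunk_masses(raw_slice_masses, target_total: float) -> np.ndarray:
    """Scale raw trunk-slice masses so they sum to ``target_total`` (kg)."""
    raw = np.asarray(raw_slice_masses, dtype=float)
    if raw.size == 0:
        raise ValueError("no slice masses given")
    if np.any(raw <= 0) or target_total <= 0:
        raise ValueError("slice masses and target must be positive")
    return raw * (target_total / raw.sum())


def trunk_slice_masses_from_volumes(slice_volumes, density: float = 1.04) -> np.ndarray:
    """Slice masses (kg) from CT slice volumes (cm^3) at a generic density.

    The default density of 1.04 g/cm^3 is prescribed uniformly to every
    voxel when converting segmental volumes into slice masses.
    """
    vol = np.asarray(slice_volumes, dtype=float)
    if np.any(vol < 0):
        raise ValueError("slice volumes must be non-negative")
    return vol * density * 1e-3  # g -> kg


# ---------------------------------------------------------------------------
# generic parametric geometry


@dataclass
class GenericGeometry:
    """Parameters of the generic 50th-percentile column layout.

    Heights and radii are given for a 1.78 m stature and scaled uniformly.
    Curvature angles are distributed over levels proportionally to the
    per-level shares below.
    """

    lordosis_deg: float = 22.5
    kyphosis_deg: float = 22.3
    #: vertebral body heights (m), T1..L5 cranial to caudal
    vb_heights: np.ndarray = field(default_factory=lambda: np.array(
        [0.016, 0.017, 0.017, 0.018, 0.018, 0.019, 0.019, 0.020, 0.021,
         0.022, 0.023, 0.024, 0.025, 0.026, 0.027, 0.027, 0.027]))
    #: disc heights (m) below each vertebra, T1/2..L5/S1
    disc_heights: np.ndarray = field(default_factory=lambda: np.array(
        [0.004, 0.004, 0.004, 0.0045, 0.0045, 0.005, 0.005, 0.0055, 0.0055,
         0.006, 0.006, 0.007, 0.009, 0.010, 0.011, 0.011, 0.011]))
    #: kyphosis shares over T1/2..T11/12 (normalised internally)
    kyphosis_shares: np.ndarray = field(default_factory=lambda: np.array(
        [0.5, 0.7, 0.9, 1.1, 1.2, 1.2, 1.1, 1.0, 0.9, 0.8, 0.6]))
    #: lordosis shares over L1/2..L5/S1 (normalised internally)
    lordosis_shares: np.ndarray = field(default_factory=lambda: np.array(
        [0.10, 0.13, 0.18, 0.26, 0.33]))
    #: Pearsall-style raw trunk slice mass distribution, T1..L5
    slice_mass_shape: np.ndarray = field(default_factory=lambda: np.array(
        [2.1, 2.1, 2.1, 2.1, 2.0, 2.0, 2.0, 1.9, 1.9, 1.8, 1.8, 1.7,
         1.7, 1.6, 1.6, 1.5, 1.5]))
    #: effective anterior centroid offsets of the trunk slices (m), T1..L5,
    #: relative to the spinal load line: chosen so the upright column sees
    #: small sagittal gravity moments (kyphosis-deepening in the thoracic,
    #: lordosis-deepening in the lumbar region), standing in for the trunk
    #: support (intra-abdominal pressure, rib cage) the model omits
    slice_offsets: np.ndarray = field(default_factory=lambda: np.array(
        [0.008, 0.011, 0.014, 0.016, 0.018, 0.020, 0.022, 0.023, 0.023,
         0.022, 0.020, 0.010, -0.015, -0.021, -0.025, -0.028, -0.030]))
    rib_mass_per_level: float = 0.18        # kg, T1..T12, lumped into the body
    #: gyration radius (m) of a trunk slice about its own centroid; the
    #: slice's distributed rotary inertia is carried by the owning
    #: vertebra (the slice rotates rigidly with it), while its mass and
    #: centroid offset remain an attached point mass
    slice_gyration_radius: float = 0.12
    spinous_offset_thoracic: float = 0.050  # m posterior of the body centre
    spinous_offset_lumbar: float = 0.058
    transverse_offset_thoracic: float = 0.030
    transverse_offset_lumbar: float = 0.038
    facet_offset: np.ndarray = field(default_factory=lambda: np.array([-0.022, 0.018, 0.0]))
    #: tilt of the facet normal from the cranial axis: near-horizontal
    #: capsular threads let the facets slide during flexion without
    #: excessive capsule strain
    facet_normal_tilt_deg: float = -70.0
    cap_span: float = 0.008                 # m, capsular thread length
    linea_alba_offset: float = 0.09         # m anterior of T12
    max_wedge_deg: float = 20.0             # self-intersection guard

    def validate(self) -> None:
        if np.any(self.vb_heights <= 0) or np.any(self.disc_heights <= 0):
            raise ValueError("vertebral and disc heights must be positive")
        wedges_deg = np.concatenate([
            self.kyphosis_deg * self.kyphosis_shares / self.kyphosis_shares.sum(),
            self.lordosis_deg * self.lordosis_shares / self.lordosis_shares.sum(),
        ])
        if np.any(np.abs(wedges_deg) > self.max_wedge_deg):
            raise ValueError(
                "per-level wedge angle exceeds the self-intersection guard; "
                "the requested curvature would fold the column"
            )


def _vb_radius(index: int) -> float:
    """Vertebral body radius (m), T1 (index 0) to L5 (index 16)."""
    return 0.013 + 0.010 * index / 16.0


def _cylinder_inertia(mass: float, radius: float, height: float) -> np.ndarray:
    ixy = mass * (3.0 * radius**2 + height**2) / 12.0
    iz = mass * radius**2 / 2.0
    return np.diag([ixy, ixy, iz])


def _level_tilts(geom: GenericGeometry, base_tilt: float) -> Dict[str, float]:
    """Sagittal inclination of each vertebra given the S1 base tilt (rad)."""
    lord = np.deg2rad(geom.lordosis_deg) * geom.lordosis_shares / geom.lordosis_shares.sum()
    kyph = np.deg2rad(geom.kyphosis_deg) * geom.kyphosis_shares / geom.kyphosis_shares.sum()
    tilts = {"S1": base_tilt}
    t = base_tilt
    for i, v in enumerate(LUMBAR[::-1]):          # L5 up to L1
        t -= lord[::-1][i]                         # lordosis: tilt back going up
        tilts[v] = t
    tilts["T12"] = tilts["L1"]                     # neutral thoracolumbar joint
    t = tilts["T12"]
    for i, v in enumerate(THORACIC[:-1][::-1]):   # T11 up to T1
        t += kyph[::-1][i]                         # kyphosis: tilt forward going up
        tilts[v] = t
    return tilts


def _stack_column(geom: GenericGeometry, scale: float, base_tilt: float):
    """Positions of body centres and joints for a given base inclination."""
    tilts = _level_tilts(geom, base_tilt)
    vb_h = geom.vb_heights * scale
    disc_h = geom.disc_heights * scale
    s1_height = 0.030 * scale
    centres: Dict[str, np.ndarray] = {}
    joints: Dict[str, np.ndarray] = {}
    centres["S1"] = np.array([0.0, 0.0, 0.08 * scale])
    # walk cranially: S1 -> L5 -> ... -> T1
    prev, prev_h = "S1", s1_height
    for idx in range(len(VERTEBRAE) - 1, -1, -1):
        v = VERTEBRAE[idx]
        jname = JOINTS[idx]  # joint below vertebra v
        d = disc_h[idx]
        z_prev = rotvec_to_matrix(np.array([0.0, tilts[prev], 0.0]))[:, 2]
        z_v = rotvec_to_matrix(np.array([0.0, tilts[v], 0.0]))[:, 2]
        p_joint = centres[prev] + z_prev * (prev_h / 2.0 + d / 2.0)
        joints[jname] = p_joint
        centres[v] = p_joint + z_v * (d / 2.0 + vb_h[idx] / 2.0)
        prev, prev_h = v, vb_h[idx]
    return centres, joints, tilts


def _solve_balanced_base(geom: GenericGeometry, scale: float) -> float:
    """Base tilt putting T1 vertically above the L5/S1 joint centre."""
    from scipy.optimize import brentq

    def offset(base):
        centres, joints, _ = _stack_column(geom, scale, base)
        return centres["T1"][0] - joints["L5/S1"][0]

    return float(brentq(offset, -0.6, 0.6, xtol=1e-12))


def load_muscle_roster(text: Optional[str] = None) -> List[dict]:
    """Read the packaged (or a user-supplied) muscle roster table."""
    if text is None:
        text = (
            importlib.resources.files("spinesim")
            .joinpath("data/muscles_generic.csv")
            .read_text()
        )
    lines = [ln for ln in text.splitlines() if not ln.startswith("#")]
    rows = list(csv.DictReader(_io.StringIO("\n".join(lines))))
    out = []
    for r in rows:
        entry = {
            "name": r["name"],
            "group": r["group"],
            "PCSA_cm2": float(r["PCSA_cm2"]),
            "m_ratio": float(r["m_ratio"]),
            "points": [],
        }
        for prefix in ("origin", "via1", "via2", "insertion"):
            body = r.get(f"{prefix}_body", "") or ""
            if body.strip():
                xyz = np.array([float(r[f"{prefix}_{c}"]) for c in "xyz"])
                entry["points"].append((body.strip(), xyz))
        if len(entry["points"]) < 2:
            raise ValueError(f"muscle {entry['name']}: need origin and insertion")
        out.append(entry)
    return out


def _mirror_point(p: np.ndarray) -> np.ndarray:
    return np.array([p[0], -p[1], p[2]])


def build_generic_model(
    anthro: Optional[dict] = None,
    geometry: Optional[GenericGeometry] = None,
    roster_text: Optional[str] = None,
) -> ModelSpec:
    """Construct the sagittally mirror-symmetric generic baseline model.

    ``anthro`` holds ``height`` (m) and ``body_mass`` (kg); defaults are the
    50th-percentile male (1.78 m, 81.5 kg).  Returns a model with 20 rigid
    bodies, 17 six-DOF joints (102 DOF), 192 ligament threads and the
    packaged muscle roster mirrored to both sides.
    """
    anthro = dict(anthro or {})
    height = float(anthro.get("height", 1.78))
    body_mass = float(anthro.get("body_mass", 81.5))
    if height <= 0 or body_mass <= 0:
        raise ValueError("height and body mass must be positive")
    geom = geometry or GenericGeometry()
    geom.validate()
    scale = height / 1.78

    base_tilt = _solve_balanced_base(geom, scale)
    centres, joint_pos, tilts = _stack_column(geom, scale, base_tilt)
    vb_h = geom.vb_heights * scale

    trunk_masses = scale_trunk_masses(
        geom.slice_mass_shape, TRUNK_MASS_FRACTION * body_mass
    )

    bodies: List[BodySpec] = [
        BodySpec(
            name="pelvis",
            mass=10.0,
            inertia=np.diag([0.08, 0.08, 0.08]),
            frame=Frame(np.zeros(3), np.zeros(3)),
            height=0.16 * scale,
        ),
        BodySpec(
            name="S1",
            mass=0.3,
            inertia=_cylinder_inertia(0.3, 0.025 * scale, 0.03 * scale),
            frame=Frame(centres["S1"], np.array([0.0, tilts["S1"], 0.0])),
            weld_to="pelvis",
            height=0.03 * scale,
        ),
    ]
    for idx, v in enumerate(VERTEBRAE):
        vb_mass = 0.05 + 0.01 * idx
        if v in THORACIC:
            vb_mass += geom.rib_mass_per_level   # ribs by their mass only
        r = _vb_radius(idx) * scale
        pm = (float(trunk_masses[idx]),
              np.array([geom.slice_offsets[idx] * scale, 0.0, 0.0]))
        rg = geom.slice_gyration_radius * scale
        slice_inertia = trunk_masses[idx] * np.diag(
            [rg**2 / 4.0, rg**2 / 4.0, rg**2 / 2.0])  # thin-disc slice
        bodies.append(
            BodySpec(
                name=v,
                mass=vb_mass,
                inertia=_cylinder_inertia(vb_mass, r, vb_h[idx]) + slice_inertia,
                frame=Frame(centres[v], np.array([0.0, tilts[v], 0.0])),
                attached_point_masses=[pm],
                height=vb_h[idx],
            )
        )
    # linea alba: thin cylinder (0.1 g) anterior of the column, welded to T12
    t12 = next(b for b in bodies if b.name == "T12")
    la_centre = t12.frame.transform_point(
        np.array([geom.linea_alba_offset * scale, 0.0, 0.0]))
    bodies.append(
        BodySpec(
            name="linea_alba",
            mass=1e-4,
            inertia=np.eye(3) * 1e-9,
            frame=Frame(la_centre, t12.frame.rotvec.copy()),
            weld_to="T12",
            height=0.25 * scale,
        )
    )

    joints: List[JointSpec] = []
    for idx, jname in enumerate(JOINTS):
        child = VERTEBRAE[idx]
        parent = VERTEBRAE[idx + 1] if idx + 1 < len(VERTEBRAE) else "S1"
        tilt_j = 0.5 * (tilts[parent] + tilts[child])
        joints.append(
            JointSpec(
                name=jname,
                parent=parent,
                child=child,
                frame=Frame(joint_pos[jname], np.array([0.0, tilt_j, 0.0])),
            )
        )

    model = ModelSpec(
        bodies=bodies,
        joints=joints,
        ivds={},
        ligaments=[],
        muscles=[],
        gravity=GRAVITY,
        meta={
            "variant": "generic",
            "height": height,
            "body_mass": body_mass,
            "base_tilt_rad": base_tilt,
            "lordosis_deg": geom.lordosis_deg,
            "kyphosis_deg": geom.kyphosis_deg,
        },
    )

    # IVD presets per region + frozen IDP offsets from proximal weight
    for jname in JOINTS:
        if jname == "L5/S1":
            region = "lumbosacral"
        elif jname in ("T12/L1", "L1/2", "L2/3", "L3/4", "L4/5"):
            region = "lumbar"
        else:
            region = "thoracic"
        model.ivds[jname] = BushingParams.from_region(region)
    for jname in JOINTS:
        model.ivds[jname] = model.ivds[jname].with_idp(idp_offset_force(model, jname))

    _add_generic_ligaments(model, geom, scale)
    _add_muscles_from_roster(model, load_muscle_roster(roster_text), scale)
    model.validate()
    return model


def _ligament_local_points(
    geom: GenericGeometry, scale: float, lig: str, side: int,
    idx_child: int, h_child: float, h_parent: float,
) -> Tuple[np.ndarray, np.ndarray]:
    """Local attachment points (child = cranial, parent = caudal body)."""
    r_child = _vb_radius(idx_child) * scale
    r_parent = _vb_radius(min(idx_child + 1, 16)) * scale
    thoracic = idx_child < 11
    y = side * (0.006 if lig in ("ALL", "PLL") else 0.004) * scale
    # the longitudinal ligaments functionally span the disc plus part of
    # the vertebral walls; the posterior elements (flavum, supraspinous,
    # intertransverse) run from process to process across the whole
    # segment, which keeps their strain per degree of flexion anatomical
    if lig == "ALL":
        pc = np.array([r_child, y, -h_child / 4.0])
        pp = np.array([r_parent, y, h_parent / 4.0])
    elif lig == "PLL":
        pc = np.array([-r_child, y, -h_child / 4.0])
        pp = np.array([-r_parent, y, h_parent / 4.0])
    elif lig == "LF":
        x = -(r_child + 0.015 * scale)
        pc = np.array([x, side * 0.008 * scale, 0.0])
        pp = np.array([x, side * 0.008 * scale, 0.0])
    elif lig == "SSL":
        x = -(geom.spinous_offset_thoracic if thoracic else geom.spinous_offset_lumbar) * scale
        pc = np.array([x, side * 0.003 * scale, 0.0])
        pp = np.array([x, side * 0.003 * scale, 0.0])
    elif lig == "ITV":
        yt = side * (geom.transverse_offset_thoracic if thoracic
                     else geom.transverse_offset_lumbar) * scale
        pc = np.array([-0.005 * scale, yt, 0.0])
        pp = np.array([-0.005 * scale, yt, 0.0])
    else:
        raise ValueError(lig)
    return pc, pp


def _add_generic_ligaments(model: ModelSpec, geom: GenericGeometry, scale: float) -> None:
    tilt = np.deg2rad(geom.facet_normal_tilt_deg)
    n_local = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
    for idx, jname in enumerate(LIGAMENT_JOINTS):
        child = model.joint(jname).child
        parent = model.joint(jname).parent
        cb, pb = model.body(child), model.body(parent)
        for lig in LIGAMENT_TYPES:
            for side, tag in ((1, "l"), (-1, "r")):
                if lig == "CAP":
                    # superior facet mid-point of the caudal vertebra; the
                    # partner sits 8 mm along the facet normal on the
                    # cranial vertebra.
                    mid_local = geom.facet_offset * scale * np.array([1.0, side, 1.0])
                    mid_local[2] = pb.height / 2.0
                    mid_w = pb.frame.transform_point(mid_local)
                    n_w = pb.frame.transform_direction(n_local)
                    partner_w = mid_w + geom.cap_span * n_w
                    pp = mid_local
                    pc = cb.frame.inverse_transform_point(partner_w)
                    dist = geom.cap_span
                else:
                    pc, pp = _ligament_local_points(
                        geom, scale, lig, side, idx, cb.height, pb.height)
                    dist = float(np.linalg.norm(
                        cb.frame.transform_point(pc) - pb.frame.transform_point(pp)))
                l0 = init_rest_length(dist, PRESTRAIN[lig])
                params = scale_characteristic_points(
                    RAW_CHARACTERISTIC_POINTS[lig], l0, n_threads=2,
                    name=lig, eps_init=PRESTRAIN[lig], d_damp=LIG_DAMPING,
                )
                model.ligaments.append(
                    LigamentElement(
                        name=f"{lig}_{jname}_{tag}",
                        ligament=lig,
                        joint=jname,
                        parent_body=parent,
                        child_body=child,
                        p_parent=pp,
                        p_child=pc,
                        params=params,
                    )
                )


def _muscle_build_length(model: ModelSpec, path: List[PathPoint]) -> float:
    pts = [model.body(pp.body).frame.transform_point(pp.point) for pp in path]
    return float(sum(np.linalg.norm(b - a) for a, b in zip(pts, pts[1:])))


def _add_muscles_from_roster(model: ModelSpec, roster: List[dict], scale: float) -> None:
    for row in roster:
        # roster rows are authored for the right side (y < 0); mirror to left
        for mirror, tag in ((True, "l"), (False, "r")):
            path = [
                PathPoint(body, scale * (_mirror_point(pt) if mirror else pt))
                for body, pt in row["points"]
            ]
            name = f"{row['name']}_{tag}"
            l_mtu = _muscle_build_length(model, path)
            params = derive_mtu_params(
                row["PCSA_cm2"], row["m_ratio"], l_mtu,
                name=name, group=row["group"],
            )
            model.muscles.append(
                MuscleElement(name=name, group=row["group"], path=path, params=params)
            )


# ---------------------------------------------------------------------------
# landmark-based individualisation


def joint_frames_from_endplates(landmarks: LandmarkSet) -> Dict[str, Frame]:
    """Joint frames as averages of the adjacent endplates of the neighbours.

    The joint between vertebrae U (cranial) and L (caudal) averages L's
    superior and U's inferior endplate; positions are averaged linearly and
    orientations through their rotation vectors.
    """
    frames: Dict[str, Frame] = {}
    order = VERTEBRAE + ["S1"]
    for i, upper in enumerate(order[:-1]):
        lower = order[i + 1]
        jname = JOINTS[i]
        for key in ((lower, "sup"), (upper, "inf")):
            if key not in landmarks.endplates:
                raise KeyError(
                    f"missing endplate landmark {key[1]!r} of {key[0]!r} "
                    f"needed for joint {jname}"
                )
        ep_lo = landmarks.endplates[(lower, "sup")]
        ep_up = landmarks.endplates[(upper, "inf")]
        frames[jname] = Frame(
            0.5 * (ep_lo.position + ep_up.position),
            average_rotvecs([ep_lo.rotvec, ep_up.rotvec]),
        )
    return frames


def vb_frames_from_endplates(landmarks: LandmarkSet) -> Dict[str, Frame]:
    """Vertebral body frames as the average of the own two endplates."""
    frames: Dict[str, Frame] = {}
    for v in VERTEBRAE + ["S1"]:
        for key in ((v, "sup"), (v, "inf")):
            if key not in landmarks.endplates:
                raise KeyError(f"missing endplate landmark {key[1]!r} of {v!r}")
        sup = landmarks.endplates[(v, "sup")]
        inf = landmarks.endplates[(v, "inf")]
        frames[v] = Frame(
            0.5 * (sup.position + inf.position),
            average_rotvecs([sup.rotvec, inf.rotvec]),
        )
    return frames


def _tilt_about_pelvis(frame_or_point, pelvis: Frame, angle_rad: float):
    """Rotate a frame or point about the pelvis lateral (y) axis."""
    axis = pelvis.transform_direction(np.array([0.0, 1.0, 0.0]))
    R = rotvec_to_matrix(axis * angle_rad)
    origin = pelvis.position
    if isinstance(frame_or_point, Frame):
        return Frame(
            origin + R @ (frame_or_point.position - origin),
            matrix_to_rotvec(R @ frame_or_point.matrix),
        )
    return origin + R @ (np.asarray(frame_or_point, dtype=float) - origin)


def elongate_pair(p1: np.ndarray, p2: np.ndarray, total: float) -> Tuple[np.ndarray, np.ndarray]:
    """Shift two points uniformly along their distance vector to span ``total``.

    The midpoint is preserved; used to elongate the 0.8 mm capsular rest
    span of the landmark pipeline to the anatomical 8 mm.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = p2 - p1
    dist = float(np.linalg.norm(d))
    if dist < 1e-12:
        raise ValueError("cannot elongate a degenerate point pair")
    mid = 0.5 * (p1 + p2)
    u = d / dist
    return mid - 0.5 * total * u, mid + 0.5 * total * u


def individualise(
    landmarks: LandmarkSet,
    baseline: ModelSpec,
    tilt_deg: float = 2.0,
    cap_total_span: float = 0.008,
) -> ModelSpec:
    """Build a subject-specific model from landmarks on the baseline roster.

    The kinematic chain is rebuilt from the endplate landmarks, muscle and
    ligament attachments are re-expressed in the local vertebral frames,
    the column is tilted ``tilt_deg`` forward about the pelvis to meet the
    sagittal-balance criterion, capsular threads are elongated to
    ``cap_total_span`` about their midpoints, and all length-dependent
    muscle/ligament parameters are re-derived for the new geometry.
    """
    # roster completeness check first: report every missing element at once
    missing = []
    for mus in baseline.muscles:
        for i in range(len(mus.path)):
            if (mus.name, i) not in landmarks.muscle_points:
                missing.append(f"muscle point {mus.name}[{i}]")
    for lig in baseline.ligaments:
        for end in ("parent", "child"):
            if (lig.name, end) not in landmarks.ligament_points:
                missing.append(f"ligament point {lig.name}:{end}")
    if missing:
        raise ValueError(
            "landmark roster does not match the baseline model; missing: "
            + ", ".join(missing[:20])
            + (f" ... ({len(missing)} total)" if len(missing) > 20 else "")
        )

    tilt = np.deg2rad(tilt_deg)
    pelvis = landmarks.pelvis

    vb_frames = {
        v: _tilt_about_pelvis(f, pelvis, tilt)
        for v, f in vb_frames_from_endplates(landmarks).items()
    }
    joint_frames = {
        j: _tilt_about_pelvis(f, pelvis, tilt)
        for j, f in joint_frames_from_endplates(landmarks).items()
    }
    mus_pts = {
        k: (body, _tilt_about_pelvis(p, pelvis, tilt))
        for k, (body, p) in landmarks.muscle_points.items()
    }
    lig_pts = {
        k: _tilt_about_pelvis(p, pelvis, tilt)
        for k, p in landmarks.ligament_points.items()
    }

    slice_masses = landmarks.slice_masses
    bodies: List[BodySpec] = []
    for b in baseline.bodies:
        if b.name == "pelvis":
            frame = pelvis.copy()
        elif b.name == "linea_alba":
            # anterior offset carried over from the baseline, bound to T12
            t12_old = baseline.body("T12").frame
            off_local = t12_old.inverse_transform_point(b.frame.position)
            frame = Frame(
                vb_frames["T12"].transform_point(off_local),
                vb_frames["T12"].rotvec.copy(),
            )
        else:
            frame = vb_frames[b.name].copy()
        pms = [(m, o.copy()) for m, o in b.attached_point_masses]
        if slice_masses is not None and b.name in VERTEBRAE:
            idx = VERTEBRAE.index(b.name)
            pms = [(float(slice_masses[idx]), o.copy()) for _, o in b.attached_point_masses]
        bodies.append(
            BodySpec(
                name=b.name,
                mass=b.mass,
                inertia=b.inertia.copy(),
                frame=frame,
                attached_point_masses=pms,
                weld_to=b.weld_to,
                height=b.height,
            )
        )

    joints = [
        JointSpec(j.name, j.parent, j.child, joint_frames[j.name].copy())
        for j in baseline.joints
    ]

    model = ModelSpec(
        bodies=bodies,
        joints=joints,
        ivds={},
        ligaments=[],
        muscles=[],
        gravity=baseline.gravity,
        meta=dict(baseline.meta, variant="individualised", tilt_deg=tilt_deg),
    )
    for jname, p in baseline.ivds.items():
        model.ivds[jname] = BushingParams(
            k_trans=p.k_trans.copy(), k_rot=p.k_rot.copy(),
            d_damp_force=p.d_damp_force, d_damp_torque=p.d_damp_torque,
        )
    for jname in model.ivds:
        model.ivds[jname] = model.ivds[jname].with_idp(idp_offset_force(model, jname))

    body_frame = {b.name: b.frame for b in model.bodies}
    for lig in baseline.ligaments:
        p_par_w = lig_pts[(lig.name, "parent")]
        p_chi_w = lig_pts[(lig.name, "child")]
        if lig.ligament == "CAP":
            p_par_w, p_chi_w = elongate_pair(p_par_w, p_chi_w, cap_total_span)
        dist = float(np.linalg.norm(p_chi_w - p_par_w))
        l0 = init_rest_length(dist, lig.params.eps_init)
        params = scale_characteristic_points(
            RAW_CHARACTERISTIC_POINTS[lig.ligament], l0,
            n_threads=lig.params.n_threads, name=lig.ligament,
            eps_init=lig.params.eps_init, d_damp=lig.params.d_damp,
        )
        model.ligaments.append(
            LigamentElement(
                name=lig.name,
                ligament=lig.ligament,
                joint=lig.joint,
                parent_body=lig.parent_body,
                child_body=lig.child_body,
                p_parent=body_frame[lig.parent_body].inverse_transform_point(p_par_w),
                p_child=body_frame[lig.child_body].inverse_transform_point(p_chi_w),
                params=params,
            )
        )

    for mus in baseline.muscles:
        path = []
        world = []
        for i, pp in enumerate(mus.path):
            body, p_w = mus_pts[(mus.name, i)]
            world.append(np.asarray(p_w, dtype=float))
            path.append(
                PathPoint(body, body_frame[body].inverse_transform_point(p_w),
                          ellipse=pp.ellipse)
            )
        l_mtu = float(sum(np.linalg.norm(b - a) for a, b in zip(world, world[1:])))
        params = derive_mtu_params(
            mus.params.PCSA, mus.params.m_ratio, l_mtu,
            name=mus.name, sigma=mus.params.sigma, group=mus.group,
        )
        model.muscles.append(
            MuscleElement(name=mus.name, group=mus.group, path=path, params=params)
        )

    model.validate()
    return model


def export_landmarks(model: ModelSpec) -> LandmarkSet:
    """Landmark set of a built model (the individualisation round-trip input).

    Capsular thread endpoints are exported at a 0.8 mm span about their
    midpoints, emulating the facet-surface spacing of the CT landmark
    pipeline before the 8 mm elongation.
    """
    endplates: Dict[Tuple[str, str], Frame] = {}
    for v in VERTEBRAE + ["S1"]:
        b = model.body(v)
        for side, sgn in (("sup", 1.0), ("inf", -1.0)):
            endplates[(v, side)] = Frame(
                b.frame.transform_point(np.array([0.0, 0.0, sgn * b.height / 2.0])),
                b.frame.rotvec.copy(),
            )
    muscle_points = {}
    for mus in model.muscles:
        for i, pp in enumerate(mus.path):
            muscle_points[(mus.name, i)] = (
                pp.body,
                model.body(pp.body).frame.transform_point(pp.point),
            )
    ligament_points = {}
    for lig in model.ligaments:
        p_par = model.body(lig.parent_body).frame.transform_point(lig.p_parent)
        p_chi = model.body(lig.child_body).frame.transform_point(lig.p_child)
        if lig.ligament == "CAP":
            p_par, p_chi = elongate_pair(p_par, p_chi, 0.0008)
        ligament_points[(lig.name, "parent")] = p_par
        ligament_points[(lig.name, "child")] = p_chi
    return LandmarkSet(
        endplates=endplates,
        muscle_points=muscle_points,
        ligament_points=ligament_points,
        pelvis=model.body("pelvis").frame.copy(),
    )


# ---------------------------------------------------------------------------
# posture utilities (forward kinematics on top of body frames)


def joint_world_frame(model: ModelSpec, joint: str,
                      body_frames: Dict[str, Frame]) -> Frame:
    """Joint frame in a given posture, carried by the parent body."""
    j = model.joint(joint)
    parent_build = model.body(j.parent).frame
    local = Frame(
        parent_build.inverse_transform_point(j.frame.position),
        matrix_to_rotvec(parent_build.matrix.T @ j.frame.matrix),
    )
    return body_frames[j.parent].compose(local)


def apply_joint_rotations(
    model: ModelSpec,
    body_frames: Dict[str, Frame],
    rotations: Dict[str, float],
) -> Dict[str, Frame]:
    """Rotate superior subtrees about joint lateral axes (sagittal posture).

    ``rotations[joint]`` is the additional rotation (rad, positive =
    extension with the y-left convention; flexion is negative) applied
    about the joint's current lateral axis.  Welded bodies follow their
    carrier.  Returns new body frames.
    """
    frames = {k: f.copy() for k, f in body_frames.items()}
    order = model.chain_order()
    welds = {b.name: b.weld_to for b in model.bodies if b.weld_to}
    for j in model.joints:
        ang = rotations.get(j.name, 0.0)
        if ang == 0.0:
            continue
        jw = joint_world_frame(model, j.name, frames)
        axis = jw.transform_direction(np.array([0.0, 1.0, 0.0]))
        R = rotvec_to_matrix(axis * ang)
        start = order.index(j.child)
        moving = set(order[start:])
        moving |= {w for w, host in welds.items() if host in moving}
        for name in moving:
            f = frames[name]
            frames[name] = Frame(
                jw.position + R @ (f.position - jw.position),
                matrix_to_rotvec(R @ f.matrix),
            )
    return frames


def muscle_world_points(
    model: ModelSpec, muscle: MuscleElement, body_frames: Dict[str, Frame]
) -> List[np.ndarray]:
    return [body_frames[pp.body].transform_point(pp.point) for pp in muscle.path]
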
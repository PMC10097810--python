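"""Readers/writers, synthetic landmark generation, run configuration, logging.

Formats: JSON for models, configurations and checkpoints (human-auditable,
floats round-trip exactly), CSV for landmark and report tables, HDF5 for
time series.  Every file carries a provenance block (package version,
configuration hash, seed) and a schema version.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .controller import COCONTRACTION_PRESETS, ControllerConfig
from .dynamics import DynamicsConfig, RunResult, SystemState
from .geometry import Frame
from .ivd import BushingParams
from .ligament import LigamentParams
from .model import (
    BodySpec,
    GenericGeometry,
    JointSpec,
    LandmarkSet,
    LigamentElement,
    ModelSpec,
    MuscleElement,
    PathPoint,
    build_generic_model,
    export_landmarks,
)
from .muscle import Ellipse, MTUParams, MuscleConstants

logger = logging.getLogger("spinesim")

SCHEMA_VERSION = 1


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _provenance(extra: Optional[dict] = None) -> dict:
    out = {"package": "spinesim", "version": __version__,
           "schema": SCHEMA_VERSION}
    out.update(extra or {})
    return out


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# model serialisation


def _frame_to_dict(f: Frame) -> dict:
    return {"position": f.position.tolist(), "rotvec": f.rotvec.tolist()}


def _frame_from_dict(d: dict) -> Frame:
    return Frame(np.array(d["position"]), np.array(d["rotvec"]))


def model_to_dict(model: ModelSpec) -> dict:
    def bushing(p: BushingParams) -> dict:
        return {
            "k_trans": p.k_trans.tolist(), "k_rot": p.k_rot.tolist(),
            "d_damp_force": p.d_damp_force, "d_damp_torque": p.d_damp_torque,
            "idp_offset": p.idp_offset,
        }

    def lig_params(p: LigamentParams) -> dict:
        return {k: getattr(p, k) for k in
                ("name", "eps_A", "F_A", "eps_B", "F_B", "l0",
                 "eps_init", "n_threads", "d_damp")}

    def ellipse(e: Optional[Ellipse]) -> Optional[dict]:
        if e is None:
            return None
        return {"centre": e.centre.tolist(), "axis_u": e.axis_u.tolist(),
                "axis_v": e.axis_v.tolist(), "a": e.a, "b": e.b}

    def mtu(p: MTUParams) -> dict:
        return {
            "name": p.name, "F_max": p.F_max, "l_CE_opt": p.l_CE_opt,
            "l_SEE_0": p.l_SEE_0, "m_ratio": p.m_ratio, "PCSA": p.PCSA,
            "sigma": p.sigma, "group": p.group,
            "constants": dataclasses.asdict(p.constants),
        }

    return {
        "provenance": _provenance(),
        "gravity": model.gravity,
        "meta": model.meta,
        "bodies": [
            {
                "name": b.name, "mass": b.mass,
                "inertia": b.inertia.tolist(),
                "frame": _frame_to_dict(b.frame),
                "point_masses": [[m, o.tolist()] for m, o in b.attached_point_masses],
                "weld_to": b.weld_to, "height": b.height,
            }
            for b in model.bodies
        ],
        "joints": [
            {"name": j.name, "parent": j.parent, "child": j.child,
             "frame": _frame_to_dict(j.frame), "dof": j.dof}
            for j in model.joints
        ],
        "ivds": {name: bushing(p) for name, p in model.ivds.items()},
        "ligaments": [
            {
                "name": l.name, "ligament": l.ligament, "joint": l.joint,
                "parent_body": l.parent_body, "child_body": l.child_body,
                "p_parent": l.p_parent.tolist(), "p_child": l.p_child.tolist(),
                "params": lig_params(l.params),
            }
            for l in model.ligaments
        ],
        "muscles": [
            {
                "name": m.name, "group": m.group,
                "path": [
                    {"body": pp.body, "point": pp.point.tolist(),
                     "ellipse": ellipse(pp.ellipse)}
                    for pp in m.path
                ],
                "params": mtu(m.params),
            }
            for m in model.muscles
        ],
    }


def model_from_dict(d: dict) -> ModelSpec:
    if "bodies" not in d or "joints" not in d:
        raise ValueError("not a spinesim model file (missing bodies/joints)")
    bodies = [
        BodySpec(
            name=b["name"], mass=b["mass"], inertia=np.array(b["inertia"]),
            frame=_frame_from_dict(b["frame"]),
            attached_point_masses=[(m, np.array(o)) for m, o in b["point_masses"]],
            weld_to=b["weld_to"], height=b["height"],
        )
        for b in d["bodies"]
    ]
    joints = [
        JointSpec(j["name"], j["parent"], j["child"],
                  _frame_from_dict(j["frame"]), j["dof"])
        for j in d["joints"]
    ]
    ivds = {
        name: BushingParams(
            k_trans=np.array(p["k_trans"]), k_rot=np.array(p["k_rot"]),
            d_damp_force=p["d_damp_force"], d_damp_torque=p["d_damp_torque"],
            idp_offset=p["idp_offset"],
        )
        for name, p in d["ivds"].items()
    }
    ligaments = [
        LigamentElement(
            name=l["name"], ligament=l["ligament"], joint=l["joint"],
            parent_body=l["parent_body"], child_body=l["child_body"],
            p_parent=np.array(l["p_parent"]), p_child=np.array(l["p_child"]),
            params=LigamentParams(**l["params"]),
        )
        for l in d["ligaments"]
    ]

    def ellipse(e):
        if e is None:
            return None
        return Ellipse(np.array(e["centre"]), np.array(e["axis_u"]),
                       np.array(e["axis_v"]), e["a"], e["b"])

    muscles = []
    for m in d["muscles"]:
        pdict = dict(m["params"])
        pdict["constants"] = MuscleConstants(**pdict["constants"])
        muscles.append(
            MuscleElement(
                name=m["name"], group=m["group"],
                path=[PathPoint(pp["body"], np.array(pp["point"]),
                                ellipse(pp["ellipse"])) for pp in m["path"]],
                params=MTUParams(**pdict),
            )
        )
    model = ModelSpec(bodies=bodies, joints=joints, ivds=ivds,
                      ligaments=ligaments, muscles=muscles,
                      gravity=d["gravity"], meta=d.get("meta", {}))
    model.validate()
    return model


def save_model(model: ModelSpec, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=1))


def load_model(path) -> ModelSpec:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    return model_from_dict(d)


def models_equal(a: ModelSpec, b: ModelSpec) -> bool:
    """Exact (bit-level) structural equality of two models."""
    da, db = model_to_dict(a), model_to_dict(b)
    da.pop("provenance"), db.pop("provenance")
    return da == db


# ---------------------------------------------------------------------------
# landmark CSV


def landmarks_to_frame(lm: LandmarkSet) -> pd.DataFrame:
    rows = []

    def add(level, ltype, side, xyz):
        rows.append({"level": level, "landmark_type": ltype, "side": side,
                     "x": xyz[0], "y": xyz[1], "z": xyz[2]})

    for (vert, side), f in sorted(lm.endplates.items()):
        add(vert, f"endplate_{side}_centre", "", f.position)
        add(vert, f"endplate_{side}_rotvec", "", f.rotvec)
    add("pelvis", "pelvis_centre", "", lm.pelvis.position)
    add("pelvis", "pelvis_rotvec", "", lm.pelvis.rotvec)
    for (name, idx), (body, p) in sorted(lm.muscle_points.items()):
        add(body, f"muscle:{name}:{idx}", "", p)
    for (name, end), p in sorted(lm.ligament_points.items()):
        add("", f"ligament:{name}:{end}", "", p)
    if lm.slice_masses is not None:
        for i, m in enumerate(lm.slice_masses):
            add(str(i), "slice_mass", "", (m, 0.0, 0.0))
    return pd.DataFrame(rows)


def save_landmarks(lm: LandmarkSet, path) -> None:
    landmarks_to_frame(lm).to_csv(path, index=False, float_format="%.17g")


def load_landmarks(path) -> LandmarkSet:
    df = pd.read_csv(path, keep_default_na=False)
    required = {"level", "landmark_type", "side", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"landmark file {path} lacks columns {sorted(required - set(df.columns))}"
        )
    endplates: Dict = {}
    muscle_points: Dict = {}
    ligament_points: Dict = {}
    pelvis_pos, pelvis_rot = np.zeros(3), np.zeros(3)
    slice_masses: Dict[int, float] = {}
    tmp_ep: Dict = {}
    for _, r in df.iterrows():
        xyz = np.array([r["x"], r["y"], r["z"]], dtype=float)
        lt = r["landmark_type"]
        if lt.startswith("endplate_"):
            _, side, kind = lt.split("_")
            tmp_ep.setdefault((r["level"], side), {})[kind] = xyz
        elif lt == "pelvis_centre":
            pelvis_pos = xyz
        elif lt == "pelvis_rotvec":
            pelvis_rot = xyz
        elif lt.startswith("muscle:"):
            _, name, idx = lt.split(":")
            muscle_points[(name, int(idx))] = (r["level"], xyz)
        elif lt.startswith("ligament:"):
            _, name, end = lt.split(":")
            ligament_points[(name, end)] = xyz
        elif lt == "slice_mass":
            slice_masses[int(r["level"])] = float(r["x"])
        else:
            raise ValueError(f"unknown landmark type {lt!r}")
    for key, parts in tmp_ep.items():
        if "centre" not in parts or "rotvec" not in parts:
            raise ValueError(f"incomplete endplate landmark {key}")
        endplates[key] = Frame(parts["centre"], parts["rotvec"])
    return LandmarkSet(
        endplates=endplates,
        muscle_points=muscle_points,
        ligament_points=ligament_points,
        pelvis=Frame(pelvis_pos, pelvis_rot),
        slice_masses=[slice_masses[i] for i in sorted(slice_masses)]
        if slice_masses else None,
    )


# ---------------------------------------------------------------------------
# synthetic landmark generator


def generate_synthetic_landmarks(
    lordosis_deg: float = 22.5,
    kyphosis_deg: float = 22.3,
    scale: float = 1.0,
    seed: int = 0,
    asymmetry: float = 0.0,
    noise: float = 0.0,
) -> LandmarkSet:
    """Parametric landmark set emulating the individualisation pipeline.

    Builds the parametric generic column at the requested curvature and
    stature scale and exports its landmarks; optional seeded Gaussian
    ``noise`` (m) on the attachment points and a lateral ``asymmetry``
    scale (m) emulate subject-specific irregularity.  Deterministic for a
    fixed seed; with both perturbations zero the set is exactly
    mirror-symmetric.
    """
    if not (0.0 < lordosis_deg < 80.0 and 0.0 < kyphosis_deg < 80.0):
        raise ValueError("curvature angles outside the physiologic range")
    geom = GenericGeometry(lordosis_deg=lordosis_deg, kyphosis_deg=kyphosis_deg)
    model = build_generic_model(
        {"height": 1.78 * scale, "body_mass": 81.5 * scale**3}, geom)
    lm = export_landmarks(model)
    rng = np.random.default_rng(seed)
    if noise > 0.0 or asymmetry > 0.0:
        for key in sorted(lm.muscle_points):
            body, p = lm.muscle_points[key]
            dp = rng.normal(0.0, max(noise, 1e-12), 3) if noise > 0 else np.zeros(3)
            dy = rng.normal(0.0, asymmetry) if asymmetry > 0 else 0.0
            lm.muscle_points[key] = (body, p + dp + np.array([0.0, dy, 0.0]))
        for key in sorted(lm.ligament_points):
            dp = rng.normal(0.0, max(noise, 1e-12), 3) if noise > 0 else np.zeros(3)
            dy = rng.normal(0.0, asymmetry) if asymmetry > 0 else 0.0
            lm.ligament_points[key] = lm.ligament_points[key] + dp + np.array([0.0, dy, 0.0])
    return lm


# ---------------------------------------------------------------------------
# checkpoints and results


def save_checkpoint(state: SystemState, path, extra: Optional[dict] = None) -> None:
    doc = {
        "provenance": _provenance(extra),
        "t": state.t,
        "phi_lum_ref": state.phi_lum_ref,
        "y": state.y.tolist(),
    }
    Path(path).write_text(json.dumps(doc))


def load_checkpoint(path) -> SystemState:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed checkpoint {path}: {exc}") from exc
    return SystemState(np.array(doc["y"]), doc["t"], doc["phi_lum_ref"])


RESULT_COLUMNS = ["time", "joint", "structure",
                  "F_x", "F_y", "F_z", "M_x", "M_y", "M_z"]
STRUCTURE_NAMES = ("IVD", "ligament", "muscle")


def result_to_hdf5(run: RunResult, path, extra: Optional[dict] = None) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["provenance"] = json.dumps(_provenance(extra))
        h5.attrs["phi_lum_ref"] = run.phi_lum_ref
        h5.attrs["joint_names"] = json.dumps(run.joint_names)
        h5.create_dataset("time", data=run.times)
        h5.create_dataset("states", data=run.states)
        h5.create_dataset("dphi_lum", data=run.dphi_lum)
        h5.create_dataset("phi_lum", data=run.phi_lum)
        h5.create_dataset("phi_tho", data=run.phi_tho)
        h5.create_dataset("joint_angles", data=run.joint_angles)
        h5.create_dataset("wrenches", data=run.wrenches)
        h5.create_dataset(
            "events",
            data=np.array([str(e) for e in run.events], dtype="S128"),
        )


def result_from_hdf5(path) -> RunResult:
    import h5py

    with h5py.File(path, "r") as h5:
        return RunResult(
            times=h5["time"][...],
            states=h5["states"][...],
            dphi_lum=h5["dphi_lum"][...],
            phi_lum=h5["phi_lum"][...],
            phi_tho=h5["phi_tho"][...],
            joint_angles=h5["joint_angles"][...],
            wrenches=h5["wrenches"][...],
            joint_names=json.loads(h5.attrs["joint_names"]),
            phi_lum_ref=float(h5.attrs["phi_lum_ref"]),
        )


def result_to_frame(run: RunResult) -> pd.DataFrame:
    """Long-format per-joint per-structure wrench table."""
    rows = []
    for ti, t in enumerate(run.times):
        for ji, jn in enumerate(run.joint_names):
            for si, sn in enumerate(STRUCTURE_NAMES):
                w = run.wrenches[ti, ji, si]
                rows.append([t, jn, sn, *w])
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Complete configuration of a simulation run."""

    model_path: str = ""
    variant: str = "generic"                 # generic | individualised
    cocontraction: str = "original"          # lower | original | higher
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    output_dir: str = "."
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cocontraction not in COCONTRACTION_PRESETS:
            raise ValueError(
                f"unknown co-contraction preset {self.cocontraction!r}"
            )
        ua, ub = COCONTRACTION_PRESETS[self.cocontraction]
        self.controller.u_open_abdominal = ua
        self.controller.u_open_back = ub

    def to_dict(self) -> dict:
        return {
            "model_path": self.model_path,
            "variant": self.variant,
            "cocontraction": self.cocontraction,
            "controller": dataclasses.asdict(self.controller),
            "dynamics": dataclasses.asdict(self.dynamics),
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = dict(d)
        kwargs["controller"] = ControllerConfig(**d.get("controller", {}))
        kwargs["dynamics"] = DynamicsConfig(**d.get("dynamics", {}))
        return cls(**kwargs)

    def hash(self) -> str:
        return config_hash(self.to_dict())


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1))


def load_config(path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))
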
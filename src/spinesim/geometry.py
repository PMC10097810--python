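"""Rotation-vector algebra and rigid frames.

The simulator parametrises every orientation by a rotation vector
(axis-angle, magnitude < pi).  Two non-trivial maps are needed:

* ``left_jacobian`` J(theta): relates rotation-vector rates to angular
  velocity, omega = J(theta) @ theta_dot (spatial convention).
* its inverse, used to differentiate the relative joint rotation, and its
  transpose, which maps torques defined in rotation-vector space back to
  Cartesian joint torques such that the elastic torque of a bushing is the
  exact negative gradient of its potential (energy conservation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

_EPS = 1e-10


def hat(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix of a 3-vector."""
    x, y, z = v
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rotvec_to_matrix(theta: np.ndarray) -> np.ndarray:
    """Rotation matrix of one rotation vector (or a stack of them)."""
    return Rotation.from_rotvec(np.asarray(theta, dtype=float)).as_matrix()


def matrix_to_rotvec(R: np.ndarray) -> np.ndarray:
    return Rotation.from_matrix(R).as_rotvec()


def left_jacobian(theta: np.ndarray) -> np.ndarray:
    """J(theta) with omega = J @ theta_dot (spatial angular velocity).

    Closed form: J = I + (1-cos t)/t^2 K + (t-sin t)/t^3 K^2, K = hat(theta).
    Series fallback below ~1e-5 rad keeps it smooth through the identity.
    """
    theta = np.asarray(theta, dtype=float)
    t = np.linalg.norm(theta)
    K = hat(theta)
    if t < 1e-5:
        return np.eye(3) + 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        + ((1.0 - np.cos(t)) / t**2) * K
        + ((t - np.sin(t)) / t**3) * (K @ K)
    )


def left_jacobian_inv(theta: np.ndarray) -> np.ndarray:
    """Inverse of ``left_jacobian``: theta_dot = Jinv @ omega."""
    theta = np.asarray(theta, dtype=float)
    t = np.linalg.norm(theta)
    K = hat(theta)
    if t < 1e-5:
        return np.eye(3) - 0.5 * K + K @ K / 12.0
    cot = 1.0 / t**2 - (1.0 + np.cos(t)) / (2.0 * t * np.sin(t))
    return np.eye(3) - 0.5 * K + cot * (K @ K)


def average_rotvecs(rotvecs: np.ndarray) -> np.ndarray:
    """Average orientations by their rotation vectors.

    Adequate for the small relative rotations between adjacent endplates;
    identical inputs return the common value exactly.
    """
    rv = np.atleast_2d(np.asarray(rotvecs, dtype=float))
    return rv.mean(axis=0)


@dataclass
class Frame:
    """Position + orientation (rotation vector) of a right-handed frame.

    Convention throughout the package: z cranial (endplate normal),
    x anterior, y left; lengths in metres, angles in radians.
    """

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotvec: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotvec = np.asarray(self.rotvec, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        return rotvec_to_matrix(self.rotvec)

    def transform_point(self, p_local: np.ndarray) -> np.ndarray:
        return self.position + self.matrix @ np.asarray(p_local, dtype=float)

    def inverse_transform_point(self, p_world: np.ndarray) -> np.ndarray:
        return self.matrix.T @ (np.asarray(p_world, dtype=float) - self.position)

    def transform_direction(self, d_local: np.ndarray) -> np.ndarray:
        return self.matrix @ np.asarray(d_local, dtype=float)

    def compose(self, other: "Frame") -> "Frame":
        """self o other: ``other`` expressed in ``self``'s coordinates."""
        R = self.matrix
        return Frame(
            self.position + R @ other.position,
            matrix_to_rotvec(R @ other.matrix),
        )

    def copy(self) -> "Frame":
        return Frame(self.position.copy(), self.rotvec.copy())


def frames_equal(a: Frame, b: Frame, tol: float = 0.0) -> bool:
    if tol == 0.0:
        return bool(
            np.array_equal(a.position, b.position)
            and np.array_equal(a.rotvec, b.rotvec)
        )
    return bool(
        np.allclose(a.position, b.position, atol=tol)
        and np.allclose(a.rotvec, b.rotvec, atol=tol)
    )


def sagittal_inclination(rotvec: np.ndarray) -> float:
    """Signed anterior lean (rad) of a frame's z-axis in the sagittal plane.

    Positive when the z-axis tips anteriorly (+x); the angle spinal-angle
    definitions are built from.
    """
    z = rotvec_to_matrix(np.asarray(rotvec, dtype=float))[:, 2]
    return float(np.arctan2(z[0], z[2]))
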
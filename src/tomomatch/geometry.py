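"""Euler-angle conventions, rotation matrices and SO(3) sampling.

Template matching searches a discrete set of orientations, so two things
matter here: a well-defined Euler convention (and the conversion between the
native anticlockwise ZXZ triplets and the clockwise ZYZ triplets used by
RELION/XMIPP/FREALIGN), and a quasi-uniform cover of the rotation group at a
prescribed angular increment.  The increment itself follows from the Crowther
criterion: to resolve a particle of diameter ``d`` at resolution ``r`` the
rotational sampling must be at least ``delta_alpha = 1 / (r * d)`` radians,
because a point at radius ``d/2`` then moves by about one Nyquist voxel per
rotation step.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "EulerConvention",
    "EulerTriplet",
    "AngularSamplingSpec",
    "OrientationSet",
    "crowther_increment",
    "generate_orientation_set",
    "euler_to_matrix",
    "matrix_to_euler",
    "to_relion_euler",
    "geodesic_distance",
    "quaternions_from_matrices",
]

# Angle below which the middle Euler angle is treated as gimbal-locked (deg).
_GIMBAL_EPS_DEG = 1e-8


class EulerConvention(enum.Enum):
    """Supported Euler-angle conventions.

    ZXZ_ANTICLOCKWISE — intrinsic z-x-z rotations, angles positive
    anticlockwise when viewed from the positive axis (the native
    template-matching convention).

    ZYZ_CLOCKWISE — intrinsic z-y-z rotations with all three angles negated
    (clockwise-positive), the convention of RELION, XMIPP, SPIDER and
    FREALIGN.
    """

    ZXZ_ANTICLOCKWISE = "zxz_anticlockwise"
    ZYZ_CLOCKWISE = "zyz_clockwise"


@dataclass(frozen=True)
class EulerTriplet:
    """Three Euler angles in degrees under an explicit convention."""

    phi: float
    theta: float
    psi: float
    convention: EulerConvention = EulerConvention.ZXZ_ANTICLOCKWISE

    def __post_init__(self) -> None:
        for name in ("phi", "theta", "psi"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"Euler angle {name!r} must be finite")
        if not isinstance(self.convention, EulerConvention):
            raise ValueError(f"unknown Euler convention: {self.convention!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.phi, self.theta, self.psi)


def _rot_z(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_x(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_y(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def euler_to_matrix(t: EulerTriplet) -> np.ndarray:
    """Active rotation matrix of an Euler triplet.

    ZXZ_ANTICLOCKWISE maps to ``Rz(phi) @ Rx(theta) @ Rz(psi)``;
    ZYZ_CLOCKWISE to ``Rz(-phi) @ Ry(-theta) @ Rz(-psi)``.
    """
    if t.convention is EulerConvention.ZXZ_ANTICLOCKWISE:
        return _rot_z(t.phi) @ _rot_x(t.theta) @ _rot_z(t.psi)
    if t.convention is EulerConvention.ZYZ_CLOCKWISE:
        return _rot_z(-t.phi) @ _rot_y(-t.theta) @ _rot_z(-t.psi)
    raise ValueError(f"unknown Euler convention: {t.convention!r}")


def _decompose_zyz(matrix: np.ndarray) -> tuple[float, float, float]:
    """Anticlockwise ZYZ angles (degrees) with theta in [0, 180].

    Gimbal lock (theta ~ 0 or 180) is resolved by placing the whole in-plane
    rotation on psi and setting phi = 0.
    """
    r = np.asarray(matrix, dtype=float)
    cos_theta = min(1.0, max(-1.0, r[2, 2]))
    theta = math.degrees(math.acos(cos_theta))
    if theta < _GIMBAL_EPS_DEG:
        # R = Rz(phi + psi): all in-plane rotation goes to psi
        return 0.0, 0.0, math.degrees(math.atan2(r[1, 0], r[0, 0]))
    if 180.0 - theta < _GIMBAL_EPS_DEG:
        # R = Rz(phi - psi) @ Ry(180)
        return 0.0, 180.0, math.degrees(math.atan2(r[1, 0], -r[0, 0]))
    phi = math.degrees(math.atan2(r[1, 2], r[0, 2]))
    psi = math.degrees(math.atan2(r[2, 1], -r[2, 0]))
    return phi, theta, psi


def matrix_to_euler(matrix: np.ndarray, convention: EulerConvention) -> EulerTriplet:
    """Decompose a proper rotation matrix into Euler angles.

    The middle angle is returned in [0, 180] degrees for both conventions.
    """
    r = np.asarray(matrix, dtype=float)
    if r.shape != (3, 3):
        raise ValueError("rotation matrix must be 3x3")
    if convention is EulerConvention.ZYZ_CLOCKWISE:
        # R = Rz(-phi) Ry(-theta) Rz(-psi)  <=>  R.T = Rz(psi) Ry(theta) Rz(phi)
        psi, theta, phi = _decompose_zyz(r.T)
        # gimbal tie-break: the in-plane rotation goes on psi, phi = 0
        if theta < _GIMBAL_EPS_DEG:
            phi, psi = 0.0, psi + phi
        elif 180.0 - theta < _GIMBAL_EPS_DEG:
            # Rz(a) Ry(180) Rz(c) = Rz(a - c) Ry(180)
            phi, psi = 0.0, psi - phi
        return EulerTriplet(phi, theta, psi, EulerConvention.ZYZ_CLOCKWISE)
    if convention is EulerConvention.ZXZ_ANTICLOCKWISE:
        # Rz(phi) Rx(theta) Rz(psi) = Rz(phi - 90) Ry(theta) Rz(psi + 90)
        phi, theta, psi = _decompose_zyz(r)
        if theta < _GIMBAL_EPS_DEG or 180.0 - theta < _GIMBAL_EPS_DEG:
            return EulerTriplet(phi, theta, psi, EulerConvention.ZXZ_ANTICLOCKWISE)
        return EulerTriplet(phi + 90.0, theta, psi - 90.0, EulerConvention.ZXZ_ANTICLOCKWISE)
    raise ValueError(f"unknown Euler convention: {convention!r}")


def to_relion_euler(t: EulerTriplet) -> EulerTriplet:
    """Convert a native anticlockwise ZXZ triplet to clockwise ZYZ.

    The rotation is carried over exactly: the triplet is expanded to a
    rotation matrix and re-decomposed under the ZYZ convention with all
    angles negated, as expected by RELION-style software.
    """
    if t.convention is not EulerConvention.ZXZ_ANTICLOCKWISE:
        raise ValueError("input must be in the ZXZ_ANTICLOCKWISE convention")
    return matrix_to_euler(euler_to_matrix(t), EulerConvention.ZYZ_CLOCKWISE)


# --------------------------------------------------------------------------
# Angular sampling


@dataclass(frozen=True)
class AngularSamplingSpec:
    """Crowther-criterion sampling: increment = 1 / (r * d) radians."""

    particle_diameter: float  # Angstrom
    target_resolution: float  # 1/Angstrom
    increment_rad: float

    @property
    def increment_deg(self) -> float:
        return math.degrees(self.increment_rad)


def crowther_increment(particle_diameter: float, target_resolution: float) -> AngularSamplingSpec:
    """Angular increment required to resolve a particle of diameter ``d``
    (Angstrom) at target resolution ``r`` (1/Angstrom).

    A voxel at the maximal radius d/2 moves by roughly one Nyquist-sampled
    voxel when the particle rotates by the returned increment, so finer
    sampling cannot be exploited at that resolution.
    """
    if particle_diameter <= 0:
        raise ValueError("particle diameter must be positive")
    if target_resolution <= 0:
        raise ValueError("target resolution must be positive")
    return AngularSamplingSpec(
        particle_diameter=particle_diameter,
        target_resolution=target_resolution,
        increment_rad=1.0 / (target_resolution * particle_diameter),
    )


@dataclass
class OrientationSet:
    """Ordered list of ZXZ-anticlockwise Euler triplets covering SO(3).

    Indices are stable: the i-th entry is the orientation referenced by
    angle-index i in score volumes produced by matching.
    """

    increment_deg: float
    angles_deg: np.ndarray  # (n, 3) phi, theta, psi in degrees
    provenance: str = "generated"
    _quaternions: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.angles_deg = np.atleast_2d(np.asarray(self.angles_deg, dtype=float))
        if self.angles_deg.size == 0 or self.angles_deg.shape[1] != 3:
            raise ValueError("orientation set must be a nonempty (n, 3) array")

    def __len__(self) -> int:
        return self.angles_deg.shape[0]

    def __getitem__(self, i: int) -> EulerTriplet:
        phi, theta, psi = self.angles_deg[i]
        return EulerTriplet(phi, theta, psi, EulerConvention.ZXZ_ANTICLOCKWISE)

    def matrices(self) -> np.ndarray:
        """(n, 3, 3) stack of rotation matrices."""
        return np.stack([euler_to_matrix(self[i]) for i in range(len(self))])

    def quaternions(self) -> np.ndarray:
        """(n, 4) unit quaternions (w, x, y, z); cached."""
        if self._quaternions is None:
            self._quaternions = quaternions_from_matrices(self.matrices())
        return self._quaternions

    def save(self, path: str | Path) -> None:
        """Write one 'phi theta psi' line per orientation (degrees, ZXZ)."""
        header = f"# tomomatch orientation set, increment {self.increment_deg:.6f} deg, zxz_anticlockwise"
        np.savetxt(path, self.angles_deg, fmt="%.6f", header=header, comments="")

    @classmethod
    def load(cls, path: str | Path) -> "OrientationSet":
        path = Path(path)
        increment = float("nan")
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "increment" in first:
            increment = float(first.split("increment")[1].split()[0])
        angles = np.loadtxt(path, comments="#", ndmin=2)
        return cls(increment_deg=increment, angles_deg=angles, provenance="loaded")


def generate_orientation_set(increment_deg: float) -> OrientationSet:
    """Deterministic quasi-uniform cover of SO(3) at a given increment.

    The first two ZXZ angles determine the direction onto which the template
    z-axis is rotated; these directions are taken from a Fibonacci spiral
    lattice on the sphere with ``ceil(4*pi / increment^2)`` points, giving a
    near-constant angular spacing close to the increment.  The in-plane
    angle psi is sampled on a uniform ring [0, 360) at the same increment.
    """
    if not 0.0 < increment_deg <= 180.0:
        raise ValueError("increment must be in (0, 180] degrees")
    inc_rad = math.radians(increment_deg)
    n_sphere = max(1, round(4.0 * math.pi / inc_rad**2))
    n_psi = max(1, round(360.0 / increment_deg))

    k = np.arange(n_sphere)
    z = 1.0 - 2.0 * (k + 0.5) / n_sphere
    golden = math.pi * (3.0 - math.sqrt(5.0))
    azimuth = k * golden
    sin_theta = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    ux = sin_theta * np.cos(azimuth)
    uy = sin_theta * np.sin(azimuth)
    uz = z
    # unit direction u = Rz(phi) Rx(theta) zhat = (sin t sin p, -sin t cos p, cos t)
    theta = np.degrees(np.arccos(np.clip(uz, -1.0, 1.0)))
    phi = np.degrees(np.arctan2(ux, -uy))
    psi = np.arange(n_psi) * (360.0 / n_psi)

    angles = np.empty((n_sphere * n_psi, 3))
    angles[:, 0] = np.repeat(phi, n_psi)
    angles[:, 1] = np.repeat(theta, n_psi)
    angles[:, 2] = np.tile(psi, n_sphere)
    return OrientationSet(increment_deg=increment_deg, angles_deg=angles)


# --------------------------------------------------------------------------
# Metric helpers


def quaternions_from_matrices(matrices: np.ndarray) -> np.ndarray:
    """Unit quaternions (w, x, y, z) for a stack of rotation matrices."""
    m = np.asarray(matrices, dtype=float)
    single = m.ndim == 2
    m = m.reshape(-1, 3, 3)
    n = m.shape[0]
    q = np.empty((n, 4))
    # branch on the largest diagonal term for numerical stability
    tr = np.einsum("nii->n", m)
    for i in range(n):
        r = m[i]
        if tr[i] > 0:
            s = math.sqrt(tr[i] + 1.0) * 2.0
            q[i] = [0.25 * s, (r[2, 1] - r[1, 2]) / s, (r[0, 2] - r[2, 0]) / s, (r[1, 0] - r[0, 1]) / s]
        elif r[0, 0] >= r[1, 1] and r[0, 0] >= r[2, 2]:
            s = math.sqrt(1.0 + r[0, 0] - r[1, 1] - r[2, 2]) * 2.0
            q[i] = [(r[2, 1] - r[1, 2]) / s, 0.25 * s, (r[0, 1] + r[1, 0]) / s, (r[0, 2] + r[2, 0]) / s]
        elif r[1, 1] >= r[2, 2]:
            s = math.sqrt(1.0 + r[1, 1] - r[0, 0] - r[2, 2]) * 2.0
            q[i] = [(r[0, 2] - r[2, 0]) / s, (r[0, 1] + r[1, 0]) / s, 0.25 * s, (r[1, 2] + r[2, 1]) / s]
        else:
            s = math.sqrt(1.0 + r[2, 2] - r[0, 0] - r[1, 1]) * 2.0
            q[i] = [(r[1, 0] - r[0, 1]) / s, (r[0, 2] + r[2, 0]) / s, (r[1, 2] + r[2, 1]) / s, 0.25 * s]
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    return q[0] if single else q


def geodesic_distance(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Bi-invariant SO(3) geodesic distance in degrees.

    ``2 * arccos(|<q1, q2>|)`` for unit quaternions; broadcasts over leading
    dimensions.
    """
    dot = np.abs(np.sum(np.asarray(q1) * np.asarray(q2), axis=-1))
    return np.degrees(2.0 * np.arccos(np.clip(dot, -1.0, 1.0)))
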
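"""Muscle-tendon path geometry: lengths and moment arms along a gait cycle.

Two geometry backends are supported per muscle-tendon unit:

* ``path`` — the unit's via-point chain is posed through the model's
  kinematic chain and the muscle-tendon length is the summed Euclidean
  distance between consecutive points;
* ``surface`` — a fitted polynomial :class:`LengthSurface` maps joint
  angles directly to muscle-tendon length (used for muscles whose
  published geometry relies on wrapping surfaces).

Moment arms use the tendon-excursion method, r = -dL^MT/dq, evaluated by
central finite differences so that both backends share one code path.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import JointKinematics, MusculoskeletalModel

__all__ = [
    "LengthSurface",
    "MomentArmProfile",
    "muscle_tendon_length",
    "moment_arm",
    "mtu_length_trajectory",
    "moment_arm_trajectory",
    "joint_excursion",
    "fit_length_surface",
    "FD_STEP",
]

#: central finite-difference step (rad) for moment arms; chosen so both
#: truncation and rounding error stay below ~1e-8 m in double precision.
FD_STEP = 1e-4


def _rotation_matrix(axis, angle: float) -> np.ndarray:
    """Rodrigues rotation about a (normalized) axis."""
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    c, s = np.cos(angle), np.sin(angle)
    x, y, z = ax
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return np.eye(3) + s * K + (1.0 - c) * (K @ K)


def _segment_transforms(model: MusculoskeletalModel, q: dict) -> dict:
    """World (R, t) per segment for joint-angle map ``q`` (rad)."""
    root = model.segments[0].name
    frames = {root: (np.eye(3), np.zeros(3))}
    for j in model.joints:
        Rp, tp = frames[j.parent]
        if j.articulated:
            if j.name not in q:
                raise KeyError(
                    f"joint '{j.name}' is articulated but missing from the "
                    "joint-angle map"
                )
            angle = j.default_angle + j.sign * float(q[j.name])
            if j.range is not None and not (
                j.range[0] <= float(q[j.name]) <= j.range[1]
            ):
                warnings.warn(
                    f"joint '{j.name}' angle {float(q[j.name]):.4f} rad outside "
                    f"declared range {j.range}; extrapolating",
                    stacklevel=3,
                )
        else:
            angle = j.default_angle
        Rj = _rotation_matrix(j.axis, angle)
        t = tp + Rp @ np.asarray(j.location_in_parent, dtype=float)
        frames[j.child] = (Rp @ Rj, t)
    return frames


@dataclass
class LengthSurface:
    """Polynomial map from joint angles (rad) to muscle-tendon length (m).

    Coefficients form a tensor-product polynomial: ``coeffs[i, j, ...]``
    multiplies ``q1**i * q2**j * ...`` for the joints in ``joints`` order.
    """

    muscle: str
    joints: list[str]
    coeffs: np.ndarray
    domain: list[tuple[float, float]] = field(default_factory=list)
    max_residual: float = 0.0

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != len(self.joints):
            raise ValueError(
                f"surface '{self.muscle}': coefficient tensor rank "
                f"{self.coeffs.ndim} != number of joints {len(self.joints)}"
            )

    def __call__(self, q: dict) -> float:
        x = []
        for k, jname in enumerate(self.joints):
            v = float(q[jname])
            if self.domain and not (self.domain[k][0] <= v <= self.domain[k][1]):
                warnings.warn(
                    f"surface '{self.muscle}': joint '{jname}' angle {v:.4f} "
                    f"outside fitted domain {self.domain[k]}; extrapolating",
                    stacklevel=2,
                )
            x.append(v)
        total = 0.0
        for idx in itertools.product(*(range(n) for n in self.coeffs.shape)):
            term = self.coeffs[idx]
            for xk, p in zip(x, idx):
                term *= xk**p
            total += term
        return total

    def to_dict(self) -> dict:
        return {
            "muscle": self.muscle,
            "joints": list(self.joints),
            "coeffs": self.coeffs.tolist(),
            "domain": [list(d) for d in self.domain],
            "max_residual": float(self.max_residual),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LengthSurface":
        return cls(
            muscle=d["muscle"],
            joints=list(d["joints"]),
            coeffs=np.asarray(d["coeffs"], dtype=float),
            domain=[tuple(x) for x in d.get("domain", [])],
            max_residual=float(d.get("max_residual", 0.0)),
        )


@dataclass
class MomentArmProfile:
    """Flexion/extension moment arm of one muscle at one joint over a cycle."""

    muscle: str
    joint: str
    gait_percent: np.ndarray
    r: np.ndarray  # m, signed: positive = flexor
    r_mean_normalized: float  # cycle average of r / L_o (signed)

    @property
    def r_mean_normalized_abs(self) -> float:
        """Magnitude of the normalized cycle-averaged moment arm."""
        return abs(self.r_mean_normalized)


def muscle_tendon_length(model: MusculoskeletalModel, unit_name: str, q: dict) -> float:
    """Muscle-tendon length L^MT (m) at joint-angle map ``q`` (rad)."""
    unit = model.unit(unit_name)
    if unit.geometry_backend == "surface":
        L = float(model.surfaces[unit.name](q))
    else:
        frames = _segment_transforms(model, q)
        pts = []
        for p in unit.path:
            R, t = frames[p.segment]
            pts.append(R @ np.asarray(p.location, dtype=float) + t)
        pts = np.asarray(pts)
        L = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if not np.isfinite(L) or L <= 0.0:
        raise ValueError(
            f"unit '{unit_name}': non-positive or non-finite length {L} at {q}"
        )
    return L


def moment_arm(
    model: MusculoskeletalModel, unit_name: str, q: dict, joint: str
) -> float:
    """Moment arm r = -dL^MT/dq_joint (m) by central finite difference.

    Positive values mark flexors under the convention that flexion angles
    increase.  Returns exactly 0 for a unit whose length does not depend
    on the joint.
    """
    model.joint(joint)  # raises KeyError for unknown joints
    qp = dict(q)
    qm = dict(q)
    qp[joint] = float(q[joint]) + FD_STEP
    qm[joint] = float(q[joint]) - FD_STEP
    Lp = muscle_tendon_length(model, unit_name, qp)
    Lm = muscle_tendon_length(model, unit_name, qm)
    if Lp == Lm:
        return 0.0
    return -(Lp - Lm) / (2.0 * FD_STEP)


def _q_series(model: MusculoskeletalModel, kin: JointKinematics) -> list[dict]:
    """Per-sample joint-angle maps (rad) from kinematics stored in degrees."""
    names = model.articulated_joints
    for n in names:
        if n not in kin.angles:
            raise KeyError(
                f"kinematics of subject '{kin.subject_id}' lack joint '{n}'"
            )
    rad = {n: np.radians(kin.angles[n]) for n in names}
    return [{n: rad[n][i] for n in names} for i in range(kin.gait_percent.size)]


def mtu_length_trajectory(
    model: MusculoskeletalModel, unit_name: str, kin: JointKinematics
) -> np.ndarray:
    """L^MT (m) at every sample of the gait grid."""
    return np.array(
        [muscle_tendon_length(model, unit_name, q) for q in _q_series(model, kin)]
    )


def moment_arm_trajectory(
    model: MusculoskeletalModel, unit_name: str, kin: JointKinematics, joint: str
) -> MomentArmProfile:
    """Moment-arm profile of one unit at one joint across the gait cycle."""
    unit = model.unit(unit_name)
    r = np.array(
        [moment_arm(model, unit_name, q, joint) for q in _q_series(model, kin)]
    )
    return MomentArmProfile(
        muscle=unit.parent_muscle,
        joint=joint,
        gait_percent=kin.gait_percent.copy(),
        r=r,
        r_mean_normalized=float(np.mean(r) / unit.L_o),
    )


def joint_excursion(kin: JointKinematics, joint: str) -> float:
    """Joint excursion: max minus min joint angle over the cycle (degrees)."""
    if joint not in kin.angles:
        raise KeyError(
            f"kinematics of subject '{kin.subject_id}' lack joint '{joint}'"
        )
    a = kin.angles[joint]
    return float(np.max(a) - np.min(a))


def fit_length_surface(
    muscle: str,
    joints: list[str],
    samples,
    degree: int,
) -> LengthSurface:
    """Least-squares tensor-product polynomial fit of L^MT(q).

    Parameters
    ----------
    samples:
        Sequence of ``(q, L)`` pairs where ``q`` is a joint-angle map (or
        a sequence ordered like ``joints``) in radians and ``L`` the
        muscle-tendon length in meters.
    degree:
        Per-joint polynomial degree; the fit needs at least
        ``(degree + 1) ** len(joints)`` well-spread samples.
    """
    X = []
    y = []
    for q, L in samples:
        if isinstance(q, dict):
            x = [float(q[j]) for j in joints]
        else:
            x = [float(v) for v in np.atleast_1d(q)]
        X.append(x)
        y.append(float(L))
    X = np.asarray(X)
    y = np.asarray(y)
    shape = tuple(degree + 1 for _ in joints)
    n_coef = int(np.prod(shape))
    powers = list(itertools.product(*(range(degree + 1) for _ in joints)))
    A = np.ones((len(y), n_coef))
    for col, idx in enumerate(powers):
        for k, p in enumerate(idx):
            A[:, col] *= X[:, k] ** p
    if len(y) < n_coef:
        raise np.linalg.LinAlgError(
            f"need at least {n_coef} samples for degree {degree} over "
            f"{len(joints)} joint(s); got {len(y)}"
        )
    sol, _, rank, sv = np.linalg.lstsq(A, y, rcond=None)
    if rank < n_coef:
        cond = sv[0] / sv[-1] if sv[-1] > 0 else np.inf
        raise np.linalg.LinAlgError(
            f"rank-deficient length-surface fit for '{muscle}': rank {rank} "
            f"< {n_coef} coefficients (condition number {cond:.3g}); spread "
            "the samples over the domain or lower the degree"
        )
    coeffs = sol.reshape(shape)
    resid = A @ sol - y
    domain = [(float(X[:, k].min()), float(X[:, k].max())) for k in range(len(joints))]
    return LengthSurface(
        muscle=muscle,
        joints=list(joints),
        coeffs=coeffs,
        domain=domain,
        max_residual=float(np.max(np.abs(resid))),
    )
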
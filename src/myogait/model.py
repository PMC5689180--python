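"""Domain types for musculoskeletal models and gait kinematics.

All internal quantities are SI: meters, radians, seconds, newtons.  File
readers convert degrees/millimeters at the boundary (see :mod:`myogait.io`).
Joint-angle trajectories live on a fixed 101-sample grid spanning 0-100 %
of one gait cycle, which makes cross-subject averaging and comparison
trivial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAIT_GRID",
    "PathPoint",
    "MuscleTendonUnit",
    "Joint",
    "Segment",
    "MusculoskeletalModel",
    "JointKinematics",
    "HomologMap",
    "ModelValidationError",
    "RIGID_TENDON_RATIO",
]

#: Gait-cycle percentage grid: 0, 1, ..., 100.
GAIT_GRID = np.arange(101, dtype=float)

#: Units with optimal-fiber-length / tendon-slack-length above this ratio
#: are treated as rigid-tendon actuators (short or absent external tendon).
RIGID_TENDON_RATIO = 2.0

class ModelValidationError(ValueError):
    """A model, unit or kinematics object violates a structural invariant."""


@dataclass(frozen=True)
class PathPoint:
    """A fixed point of a muscle path, expressed in a body-segment frame."""

    segment: str
    location: tuple[float, float, float]

    def __post_init__(self):
        if len(self.location) != 3:
            raise ModelValidationError(
                f"path point on segment '{self.segment}' needs a 3-vector location"
            )


@dataclass
class MuscleTendonUnit:
    """One actuator: a muscle fiber in series with a tendon.

    Parameters follow the standard Hill-type muscle parameterization:
    maximum isometric force ``F_o`` (N), optimal fiber length ``L_o`` (m),
    maximum shortening velocity ``V_max`` (optimal fiber lengths / s),
    pennation angle at optimal fiber length ``alpha_o`` (rad), and tendon
    slack length ``L_s`` (m).  ``L_o_sd`` / ``L_s_sd`` carry reported
    standard deviations used by the sensitivity analysis.
    """

    name: str
    F_o: float
    L_o: float
    V_max: float
    alpha_o: float
    L_s: float
    path: list[PathPoint] = field(default_factory=list)
    parent_muscle: str = ""
    #: reported SDs for the sensitivity analysis; None = not reported
    L_o_sd: float | None = None
    L_s_sd: float | None = None
    #: geometry backend: "path" (via-point chain) or "surface" (fitted length surface)
    geometry_backend: str = "path"
    #: set by readers when path geometry was simplified (e.g. wrap objects skipped)
    geometry_approximate: bool = False

    def __post_init__(self):
        if not self.parent_muscle:
            self.parent_muscle = self.name
        self.validate()

    def validate(self) -> None:
        if self.F_o <= 0:
            raise ModelValidationError(f"unit '{self.name}': F_o must be > 0")
        if self.L_o <= 0:
            raise ModelValidationError(f"unit '{self.name}': L_o must be > 0")
        if self.L_s < 0:
            raise ModelValidationError(f"unit '{self.name}': L_s must be >= 0")
        if not (0.0 <= self.alpha_o < math.pi / 2):
            raise ModelValidationError(
                f"unit '{self.name}': alpha_o must be in [0, pi/2)"
            )
        if self.V_max <= 0:
            raise ModelValidationError(f"unit '{self.name}': V_max must be > 0")
        if self.geometry_backend == "path" and len(self.path) < 2:
            raise ModelValidationError(
                f"unit '{self.name}': path needs at least 2 points"
            )

    @property
    def rigid_tendon(self) -> bool:
        """True when the tendon is treated as inextensible (L_o/L_s > 2)."""
        return self.L_s == 0.0 or self.L_o / self.L_s > RIGID_TENDON_RATIO


@dataclass
class Joint:
    """A revolute (hinge) joint between two segments.

    Only the sagittal flexion/extension angle is articulated; the joint
    rotates the child frame about ``axis`` (unit 3-vector in the parent
    frame) located at ``location_in_parent``.  ``sign`` maps the
    user-facing flexion angle onto the rotation (+1: flexion increases the
    rotation angle).  ``default_angle`` is used when kinematics do not
    drive the joint (locked degrees of freedom).
    """

    name: str
    parent: str
    child: str
    location_in_parent: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    sign: float = 1.0
    default_angle: float = 0.0
    articulated: bool = True
    range: tuple[float, float] | None = None  # rad, optional declared range


@dataclass
class Segment:
    """A rigid body segment of the kinematic chain."""

    name: str


@dataclass
class MusculoskeletalModel:
    """A kinematic chain plus its muscle-tendon actuators.

    ``segments`` is an ordered chain (e.g. pelvis -> femur -> tibia ->
    foot); each joint connects consecutive segments.  The first segment is
    the ground/root frame.  ``units`` are individual actuators; a muscle
    represented by several units groups them through ``parent_muscle``.
    """

    species: str
    segments: list[Segment]
    joints: list[Joint]
    units: list[MuscleTendonUnit]
    #: fitted length surfaces keyed by unit name (backend "surface")
    surfaces: dict = field(default_factory=dict)
    #: cycle duration metadata in seconds, keyed use: elastic-tendon integration
    cycle_duration: float = 1.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        seg_names = [s.name for s in self.segments]
        if len(set(seg_names)) != len(seg_names):
            raise ModelValidationError("duplicate segment names")
        joint_names = [j.name for j in self.joints]
        if len(set(joint_names)) != len(joint_names):
            raise ModelValidationError("duplicate joint names")
        known = set(seg_names)
        # chain connectivity: every joint's parent must already be reachable
        reachable = {seg_names[0]} if seg_names else set()
        for j in self.joints:
            if j.parent not in known or j.child not in known:
                raise ModelValidationError(
                    f"joint '{j.name}' references unknown segment"
                )
            if j.parent not in reachable:
                raise ModelValidationError(
                    f"joint '{j.name}': parent '{j.parent}' not connected to root"
                )
            if j.child in reachable:
                raise ModelValidationError(
                    f"joint '{j.name}': chain is not acyclic at '{j.child}'"
                )
            reachable.add(j.child)
        for u in self.units:
            u.validate()
            if u.geometry_backend == "surface" and u.name not in self.surfaces:
                raise ModelValidationError(
                    f"unit '{u.name}': surface backend but no fitted surface"
                )
            for p in u.path:
                if p.segment not in known:
                    raise ModelValidationError(
                        f"unit '{u.name}': path point on unknown segment "
                        f"'{p.segment}'"
                    )

    @property
    def muscles(self) -> dict[str, list[MuscleTendonUnit]]:
        """Units grouped by anatomical parent muscle (insertion order)."""
        groups: dict[str, list[MuscleTendonUnit]] = {}
        for u in self.units:
            groups.setdefault(u.parent_muscle, []).append(u)
        return groups

    def unit(self, name: str) -> MuscleTendonUnit:
        for u in self.units:
            if u.name == name:
                return u
        raise KeyError(f"no muscle-tendon unit named '{name}'")

    def joint(self, name: str) -> Joint:
        for j in self.joints:
            if j.name == name:
                return j
        raise KeyError(f"no joint named '{name}'")

    @property
    def articulated_joints(self) -> list[str]:
        return [j.name for j in self.joints if j.articulated]


@dataclass
class JointKinematics:
    """Per-subject joint-angle trajectories over one normalized gait cycle.

    Angles are stored in degrees (the conventional unit of gait data) on
    the uniform 101-sample 0-100 % grid, cycle starting at heel strike.
    """

    subject_id: str
    angles: dict[str, np.ndarray]
    speed: float = float("nan")  # m/s, metadata
    cycle_duration: float = 1.0  # s, metadata for elastic-tendon integration
    cycle_convention: str = "heel-strike-start"
    gait_percent: np.ndarray = field(default_factory=lambda: GAIT_GRID.copy())

    def __post_init__(self):
        gp = np.asarray(self.gait_percent, dtype=float)
        if gp[0] != 0.0 or gp[-1] != 100.0 or np.any(np.diff(gp) <= 0):
            raise ModelValidationError(
                "gait_percent must increase strictly from 0 to 100"
            )
        self.gait_percent = gp
        for name, a in self.angles.items():
            a = np.asarray(a, dtype=float)
            if a.shape != gp.shape:
                raise ModelValidationError(
                    f"angle trajectory '{name}' length {a.size} != grid "
                    f"length {gp.size}"
                )
            self.angles[name] = a

    @property
    def joints(self) -> list[str]:
        return list(self.angles)


@dataclass
class HomologMap:
    """Pairs of homologous mouse and human muscle names.

    ``group`` classifies each pair as upper_leg (thigh) or lower_leg
    (shank) for the fat-fraction regressions.
    """

    pairs: list[tuple[str, str]]
    groups: dict[tuple[str, str], str] = field(default_factory=dict)

    VALID_GROUPS = ("upper_leg", "lower_leg")

    def __post_init__(self):
        if len(set(self.pairs)) != len(self.pairs):
            raise ModelValidationError("duplicate homolog pairs")
        for pair, g in self.groups.items():
            if g not in self.VALID_GROUPS:
                raise ModelValidationError(
                    f"unknown group label '{g}' for pair {pair}"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)
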
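"""Seeded generators for models, gait cohorts and fat-fraction data.

These generators make every pipeline stage testable without downloading
published models or motion captures.  They are pure functions of their
spec (including the seed): identical inputs give byte-identical outputs.

Gait trajectories are sums of sinusoidal harmonics over the gait cycle
plus a per-subject Gaussian offset (truncated at +/- 3 SD so that preset
bounds hold by construction).  Species presets are caricatures of mouse
and human treadmill walking: they encode only coarse anchors — the mouse
knee stays strongly flexed (> 90 deg) with a small range of motion while
the human knee stays below 70 deg flexion with a large range; walking
speeds 0.2 vs 1.25 m/s; cohort sizes 16 vs 5 — and leave waveform details
as editable parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .geometry import LengthSurface
from .model import (
    GAIT_GRID,
    HomologMap,
    Joint,
    JointKinematics,
    MusculoskeletalModel,
    MuscleTendonUnit,
    PathPoint,
    Segment,
)

__all__ = [
    "JointWave",
    "GaitSpec",
    "ModelSpec",
    "synth_gait",
    "synth_model",
    "synth_fat_fraction",
    "species_presets",
    "preset_model",
    "preset_homolog_map",
]

#: operating center of the synthetic hinge joints (rad); synthetic gait
#: angles oscillate around 90 deg where the toy-hinge length map is steepest.
_Q_CENTER = math.pi / 2


@dataclass(frozen=True)
class JointWave:
    """One joint's trajectory shape: offset + sum of sinusoidal harmonics.

    ``harmonics`` lists ``(k, relative_amplitude, relative_phase)`` terms;
    the angle at gait percent t is
    ``offset + sum_k amplitude * rel * sin(2 pi k t / 100 + phase + rph)``.
    """

    offset_deg: float
    amplitude_deg: float
    phase_rad: float = 0.0
    harmonics: tuple = ((1, 1.0, 0.0),)

    @property
    def peak_amplitude_deg(self) -> float:
        """Upper bound of the oscillatory part (sum of |amplitudes|)."""
        return self.amplitude_deg * sum(abs(a) for _, a, _ in self.harmonics)


@dataclass(frozen=True)
class GaitSpec:
    """Specification of a synthetic gait cohort."""

    joints: dict  # joint name -> JointWave
    n_subjects: int = 1
    subject_noise_sd: float = 0.0  # deg, SD of the per-subject offset
    seed: int = 0
    species: str = "generic"
    speed: float = float("nan")  # m/s, metadata
    cycle_duration: float = 1.0  # s, metadata

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, w in self.joints.items():
            if w.amplitude_deg < 0:
                raise ValueError(f"joint '{name}': amplitude must be >= 0")


@dataclass(frozen=True)
class ModelSpec:
    """Specification of a synthetic musculoskeletal model.

    ``rigid_fraction`` of the muscles get a short tendon (L_o/L_s = 3,
    i.e. above the rigid-tendon threshold of 2); the rest get a long
    compliant tendon with L_s/L_o drawn from ``tendon_ratio_range``.
    Geometry backends: ``toy_hinge`` (two-point path across one hinge,
    with the analytic length map L(q) = sqrt(p^2 + d^2 - 2 p d cos q)),
    ``via_points`` (three-point path) or ``linear_surface`` (fitted
    length surface linear in the joint angle).
    """

    n_muscles: int = 25
    rigid_fraction: float = 0.4
    geometry: str = "toy_hinge"
    alpha_o_range: tuple = (0.0, math.radians(20.0))
    F_o_range: tuple = (5.0, 50.0)         # N
    L_o_range: tuple = (0.008, 0.015)      # m
    V_max_range: tuple = (8.0, 12.0)       # L_o / s
    tendon_ratio_range: tuple = (2.0, 4.0)  # L_s / L_o for compliant units
    moment_arm_norm_range: tuple = (0.2, 0.5)  # |slope| / L_o (surface backend)
    sd_fraction_L_o: float = 0.1
    sd_fraction_L_s: float = 0.05
    seed: int = 0
    species: str = "generic"
    cycle_duration: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.rigid_fraction <= 1.0):
            raise ValueError("rigid_fraction must lie in [0, 1]")
        for name in ("F_o_range", "L_o_range", "V_max_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive and ordered")


def synth_gait(spec: GaitSpec) -> list[JointKinematics]:
    """Generate a seeded cohort of per-subject gait cycles.

    Per-subject offsets are drawn once per (subject, joint) in joint
    order from N(0, subject_noise_sd), truncated at +/- 3 SD.
    """
    rng = np.random.default_rng(spec.seed)
    t = GAIT_GRID
    joint_names = list(spec.joints)
    out = []
    for s in range(spec.n_subjects):
        offsets = rng.normal(0.0, spec.subject_noise_sd, size=len(joint_names))
        if spec.subject_noise_sd > 0:
            offsets = np.clip(
                offsets, -3 * spec.subject_noise_sd, 3 * spec.subject_noise_sd
            )
        angles = {}
        for j, off in zip(joint_names, offsets):
            w = spec.joints[j]
            y = np.full_like(t, w.offset_deg + off)
            for k, rel, rph in w.harmonics:
                y = y + w.amplitude_deg * rel * np.sin(
                    2 * np.pi * k * t / 100.0 + w.phase_rad + rph
                )
            angles[j] = y
        out.append(
            JointKinematics(
                subject_id=f"{spec.species}-{s + 1:02d}",
                angles=angles,
                speed=spec.speed,
                cycle_duration=spec.cycle_duration,
            )
        )
    return out


_SEGMENTS = ("pelvis", "femur", "tibia", "foot")
_JOINTS = ("hip", "knee", "ankle")


def _chain() -> tuple[list[Segment], list[Joint]]:
    """Pelvis -> femur -> tibia -> foot chain with three sagittal hinges.

    Consecutive joints are separated along the parent segment's x-axis so
    that path points of different joints never interact.
    """
    segments = [Segment(s) for s in _SEGMENTS]
    joints = [
        Joint(name=j, parent=_SEGMENTS[i], child=_SEGMENTS[i + 1],
              location_in_parent=(0.5 if i else 0.0, 0.0, 0.0))
        for i, j in enumerate(_JOINTS)
    ]
    return segments, joints


def synth_model(spec: ModelSpec) -> MusculoskeletalModel:
    """Generate a seeded synthetic model satisfying all unit invariants.

    The requested ``rigid_fraction`` is met exactly: the first
    ``round(n_muscles * rigid_fraction)`` muscles get L_o/L_s = 3 (> 2).
    Muscles are assigned round-robin to the hip, knee and ankle joints.
    """
    rng = np.random.default_rng(spec.seed)
    segments, joints = _chain()
    n_rigid = int(round(spec.n_muscles * spec.rigid_fraction))
    units = []
    surfaces = {}
    for i in range(spec.n_muscles):
        name = f"m{i + 1:02d}"
        joint = joints[i % len(_JOINTS)]
        L_o = rng.uniform(*spec.L_o_range)
        F_o = rng.uniform(*spec.F_o_range)
        V_max = rng.uniform(*spec.V_max_range)
        alpha_o = rng.uniform(*spec.alpha_o_range)
        rigid = i < n_rigid
        L_s = L_o / 3.0 if rigid else L_o * rng.uniform(*spec.tendon_ratio_range)
        L_ref = L_s + L_o * math.cos(alpha_o)  # MTU length at the neutral pose

        if spec.geometry == "linear_surface":
            slope = rng.uniform(*spec.moment_arm_norm_range) * L_o
            slope *= rng.choice([-1.0, 1.0])
            surfaces[name] = LengthSurface(
                muscle=name,
                joints=[joint.name],
                coeffs=np.array([L_ref - slope * _Q_CENTER, slope]),
                domain=[(-math.pi, 2 * math.pi)],  # linear map: safe to evaluate widely
            )
            path, backend = [], "surface"
        else:
            # two-point (or three-point) chain across one hinge: origin at
            # radius p on the parent ray, insertion at radius d on the child
            # ray, so L(q) = sqrt(p^2 + d^2 - 2 p d cos q); radii chosen so
            # the MTU length at q = 90 deg equals L_ref
            if spec.geometry == "via_points":
                # extra via point adds p/2 of constant length on the parent
                p = d = 2.0 * L_ref / (1.0 + math.sqrt(5.0))
            else:
                p = d = L_ref / math.sqrt(2.0)
            jx = joint.location_in_parent[0]
            path = [PathPoint(joint.parent, (jx + p, 0.0, 0.0)),
                    PathPoint(joint.child, (d, 0.0, 0.0))]
            if spec.geometry == "via_points":
                path.insert(1, PathPoint(joint.parent, (jx + p / 2, 0.0, 0.0)))
            elif spec.geometry != "toy_hinge":
                raise ValueError(f"unknown geometry '{spec.geometry}'")
            backend = "path"
        units.append(
            MuscleTendonUnit(
                name=name, F_o=F_o, L_o=L_o, V_max=V_max, alpha_o=alpha_o,
                L_s=L_s, L_o_sd=spec.sd_fraction_L_o * L_o,
                L_s_sd=spec.sd_fraction_L_s * L_s, path=path,
                parent_muscle=name, geometry_backend=backend,
            )
        )
    return MusculoskeletalModel(
        species=spec.species, segments=segments, joints=joints, units=units,
        surfaces=surfaces, cycle_duration=spec.cycle_duration,
    )


def synth_fat_fraction(
    excursions: dict, slope: float, intercept: float,
    noise_sd: float = 0.0, seed: int = 0,
) -> dict:
    """Fat fractions linear in excursion plus Gaussian noise, clamped to [0, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = {}
    for muscle, E in excursions.items():
        f = slope * E + intercept + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        out[muscle] = float(min(max(f, 0.0), 1.0))
    return out


def species_presets() -> tuple[GaitSpec, GaitSpec]:
    """Editable mouse-like and human-like gait presets.

    Anchors: the mouse knee stays above 90 deg flexion with a small range
    while the human knee peaks below 70 deg; treadmill speeds 0.2 and
    1.25 m/s; cohort sizes 16 and 5.  With 2 deg subject noise truncated
    at 3 SD, the knee bounds hold by construction
    (112 - 14 - 6 = 92 > 90; 38 + 25 + 6 = 69 < 70).
    """
    mouse = GaitSpec(
        joints={
            "hip": JointWave(20.0, 12.0, 0.0, ((1, 1.0, 0.0), (2, 0.3, 0.8))),
            "knee": JointWave(112.0, 14.0, 1.0),
            "ankle": JointWave(95.0, 28.0, 0.5, ((1, 1.0, 0.0), (2, 0.25, 1.2))),
        },
        n_subjects=16,
        subject_noise_sd=2.0,
        seed=0,
        species="mouse",
        speed=0.2,
        cycle_duration=0.35,
    )
    human = GaitSpec(
        joints={
            "hip": JointWave(15.0, 22.0, 0.3, ((1, 1.0, 0.0), (2, 0.2, 0.5))),
            "knee": JointWave(38.0, 25.0, 1.2),
            "ankle": JointWave(95.0, 14.0, 0.8, ((1, 1.0, 0.0), (2, 0.3, 1.0))),
        },
        n_subjects=5,
        subject_noise_sd=2.0,
        seed=1,
        species="human",
        speed=1.25,
        cycle_duration=1.1,
    )
    return mouse, human


def preset_model(species: str, seed: int | None = None) -> MusculoskeletalModel:
    """Synthetic 25-muscle model caricaturing one species' architecture.

    The mouse variant uses small optimal fiber lengths, small normalized
    moment arms and 10/25 rigid-tendon muscles; the human variant larger
    fibers, larger normalized moment arms and 3/25 rigid-tendon muscles.
    Both use the fitted-length-surface backend so cross-species homologs
    share the same kinematic structure.
    """
    if species == "mouse":
        spec = ModelSpec(
            n_muscles=25, rigid_fraction=10 / 25, geometry="linear_surface",
            L_o_range=(0.006, 0.014), F_o_range=(1.0, 10.0),
            moment_arm_norm_range=(0.08, 0.25),
            seed=11 if seed is None else seed,
            species="mouse", cycle_duration=0.35,
        )
    elif species == "human":
        spec = ModelSpec(
            n_muscles=25, rigid_fraction=3 / 25, geometry="linear_surface",
            L_o_range=(0.06, 0.14), F_o_range=(200.0, 1500.0),
            moment_arm_norm_range=(0.25, 0.55),
            seed=12 if seed is None else seed,
            species="human", cycle_duration=1.1,
        )
    else:
        raise ValueError(f"unknown species preset '{species}'")
    return synth_model(spec)


def preset_homolog_map() -> HomologMap:
    """Homolog map pairing the 25 like-named preset muscles.

    The first 13 pairs are tagged upper_leg, the remaining 12 lower_leg.
    """
    pairs = [(f"m{i + 1:02d}", f"m{i + 1:02d}") for i in range(25)]
    groups = {
        p: ("upper_leg" if i < 13 else "lower_leg") for i, p in enumerate(pairs)
    }
    return HomologMap(pairs=pairs, groups=groups)
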
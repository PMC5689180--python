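"""Fiber-excursion pipeline: the dual-activation excursion statistic.

The headline quantity is the fiber excursion E of a muscle over one gait
cycle: the maximum fiber length at minimum activation (a = 0.05) minus the
minimum fiber length at maximal activation (a = 1), normalized by the
optimal fiber length.  Running both activation extremes brackets the fiber
length changes any intermediate activation profile could produce.  For a
muscle represented by several muscle-tendon units the unit excursions are
averaged (unweighted).

:func:`run_cohort` applies the statistic to every subject of a cohort and
also tabulates joint excursions (max - min joint angle) and cycle-averaged
moment arms normalized by optimal fiber length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curves import CurveSet
from .dynamics import simulate_fiber_trajectory
from .geometry import joint_excursion, moment_arm_trajectory, mtu_length_trajectory
from .model import JointKinematics, MusculoskeletalModel

__all__ = [
    "ExcursionResult",
    "CohortTable",
    "muscle_excursion",
    "run_cohort",
    "average_kinematics",
    "ACTIVATION_LOW",
    "ACTIVATION_HIGH",
]

log = logging.getLogger(__name__)

ACTIVATION_LOW = 0.05
ACTIVATION_HIGH = 1.0


@dataclass
class ExcursionResult:
    """Normalized dual-activation fiber excursion of one muscle, one subject."""

    muscle: str
    subject_id: str
    E: float                 # (max L_M at a=0.05 − min L_M at a=1) / L_o, unit-averaged
    L_max_low_act: float     # m, max fiber length at a=0.05 (first unit)
    L_min_high_act: float    # m, min fiber length at a=1 (first unit)
    n_units: int = 1


@dataclass
class CohortTable:
    """Tidy per-subject result tables for one species cohort."""

    species: str
    excursions: pd.DataFrame      # species, subject_id, muscle, E
    joint_excursions: pd.DataFrame  # species, subject_id, joint, excursion_deg
    moment_arms: pd.DataFrame     # species, subject_id, muscle, joint, r_mean_normalized
    failures: list = field(default_factory=list)

    def excursion_means(self) -> pd.Series:
        """Cohort-mean excursion per muscle."""
        return self.excursions.groupby("muscle", sort=False)["E"].mean()


def _unit_excursion(
    model: MusculoskeletalModel,
    curves: CurveSet,
    kin: JointKinematics,
    unit_name: str,
    mode: str = "auto",
) -> tuple[float, float, float]:
    """(normalized excursion, max L_M at low a, min L_M at high a) for one unit."""
    unit = model.unit(unit_name)
    L_MT = mtu_length_trajectory(model, unit_name, kin)
    lo = simulate_fiber_trajectory(
        unit, curves, L_MT, ACTIVATION_LOW, mode=mode,
        cycle_duration=kin.cycle_duration, gait_percent=kin.gait_percent,
    )
    hi = simulate_fiber_trajectory(
        unit, curves, L_MT, ACTIVATION_HIGH, mode=mode,
        cycle_duration=kin.cycle_duration, gait_percent=kin.gait_percent,
    )
    L_max = float(np.max(lo.L_M))
    L_min = float(np.min(hi.L_M))
    return (L_max - L_min) / unit.L_o, L_max, L_min


def muscle_excursion(
    model: MusculoskeletalModel,
    curves: CurveSet,
    kin: JointKinematics,
    muscle: str,
    mode: str = "auto",
) -> ExcursionResult:
    """Dual-activation fiber excursion of one muscle for one subject.

    Each of the muscle's units is simulated at a = 0.05 and a = 1; the
    unit excursion is (max fiber length at 0.05 − min fiber length at 1)
    normalized by that unit's optimal fiber length, and the muscle value
    is the unweighted mean over units.
    """
    units = model.muscles.get(muscle)
    if not units:
        raise KeyError(f"no muscle named '{muscle}' in the model")
    Es, L_maxes, L_mins = [], [], []
    for u in units:
        try:
            E, L_max, L_min = _unit_excursion(model, curves, kin, u.name, mode)
        except Exception as e:
            raise RuntimeError(
                f"simulation failed for muscle '{muscle}', unit '{u.name}', "
                f"subject '{kin.subject_id}': {e}"
            ) from e
        Es.append(E)
        L_maxes.append(L_max)
        L_mins.append(L_min)
    return ExcursionResult(
        muscle=muscle,
        subject_id=kin.subject_id,
        E=float(np.mean(Es)),
        L_max_low_act=L_maxes[0],
        L_min_high_act=L_mins[0],
        n_units=len(units),
    )


def run_cohort(
    model: MusculoskeletalModel,
    curves: CurveSet,
    cohort: list[JointKinematics],
    muscles: list[str] | None = None,
    joints: list[str] | None = None,
    mode: str = "auto",
) -> CohortTable:
    """Per-subject excursions, joint excursions and normalized moment arms.

    Moment arms are the cycle average of the signed moment arm divided by
    the unit's optimal fiber length, unit-averaged per muscle.  Failures
    for individual subject x muscle combinations are collected and the run
    continues.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if muscles is None:
        muscles = list(model.muscles)
    if joints is None:
        joints = model.articulated_joints
    exc_rows, joint_rows, ma_rows = [], [], []
    failures = []
    for kin in cohort:
        for j in joints:
            joint_rows.append(
                {"species": model.species, "subject_id": kin.subject_id,
                 "joint": j, "excursion_deg": joint_excursion(kin, j)}
            )
        for m in sorted(muscles):
            try:
                res = muscle_excursion(model, curves, kin, m, mode=mode)
            except Exception as e:  # collected, run continues
                failures.append(str(e))
                log.warning("%s", e)
                continue
            exc_rows.append(
                {"species": model.species, "subject_id": kin.subject_id,
                 "muscle": m, "E": res.E, "n_units": res.n_units}
            )
            for j in joints:
                profiles = [
                    moment_arm_trajectory(model, u.name, kin, j)
                    for u in model.muscles[m]
                ]
                r_norm = float(np.mean([p.r_mean_normalized for p in profiles]))
                if all(np.all(p.r == 0.0) for p in profiles):
                    continue  # muscle does not cross this joint
                ma_rows.append(
                    {"species": model.species, "subject_id": kin.subject_id,
                     "muscle": m, "joint": j,
                     "r_mean_normalized": r_norm,
                     "r_mean_normalized_abs": abs(r_norm)}
                )
    return CohortTable(
        species=model.species,
        excursions=pd.DataFrame(
            exc_rows, columns=["species", "subject_id", "muscle", "E", "n_units"]
        ),
        joint_excursions=pd.DataFrame(
            joint_rows, columns=["species", "subject_id", "joint", "excursion_deg"]
        ),
        moment_arms=pd.DataFrame(
            ma_rows,
            columns=["species", "subject_id", "muscle", "joint",
                     "r_mean_normalized", "r_mean_normalized_abs"],
        ),
        failures=failures,
    )


def average_kinematics(cohort: list[JointKinematics]) -> JointKinematics:
    """Samplewise mean trajectory across a cohort (subject_id 'cohort-mean')."""
    if not cohort:
        raise ValueError("empty cohort")
    joint_sets = {tuple(sorted(k.joints)) for k in cohort}
    if len(joint_sets) != 1:
        raise ValueError("cohort subjects have mixed joint sets")
    joints = cohort[0].joints
    angles = {
        j: np.mean([k.angles[j] for k in cohort], axis=0) for j in joints
    }
    speeds = [k.speed for k in cohort if np.isfinite(k.speed)]
    return JointKinematics(
        subject_id="cohort-mean",
        angles=angles,
        speed=float(np.mean(speeds)) if speeds else float("nan"),
        cycle_duration=float(np.mean([k.cycle_duration for k in cohort])),
    )
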
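"""Joint excursions and cycle-averaged normalized moment arms.

Uses the toy-hinge analytic model, where the moment arm has the closed
form r = -dL/dq = -p d sin(q) / L(q), to show the tendon-excursion method
(central finite differences on the muscle-tendon length) and the two
cycle-level summaries the comparison pipeline uses.
"""

import numpy as np

from myogait import (
    GAIT_GRID,
    JointKinematics,
    joint_excursion,
    moment_arm,
    moment_arm_trajectory,
    ModelSpec,
    synth_model,
)

model = synth_model(ModelSpec(n_muscles=3, geometry="toy_hinge", seed=4))
kin = JointKinematics(
    subject_id="demo",
    angles={
        "hip": 90 + 15 * np.sin(2 * np.pi * GAIT_GRID / 100.0),
        "knee": 95 + 25 * np.sin(2 * np.pi * GAIT_GRID / 100.0 + 1.0),
        "ankle": 90 + 20 * np.sin(2 * np.pi * GAIT_GRID / 100.0 + 0.5),
    },
)

for j in ("hip", "knee", "ankle"):
    print(f"{j}: joint excursion {joint_excursion(kin, j):.1f} deg")

print()
for unit in model.units:
    jname = {"pelvis": "hip", "femur": "knee", "tibia": "ankle"}[
        unit.path[0].segment
    ]
    profile = moment_arm_trajectory(model, unit.name, kin, jname)
    q = {k: np.radians(v[0]) for k, v in kin.angles.items()}
    r0 = moment_arm(model, unit.name, q, jname)
    print(
        f"{unit.name} @ {jname}: r(heel strike) = {r0 * 1000:+.2f} mm, "
        f"cycle-average r/L_o = {profile.r_mean_normalized:+.3f}"
    )

print("\nNegative r/L_o marks an extensor under the flexion-positive sign")
print("convention; the comparison stage uses the magnitude of the cycle")
print("average, normalized by optimal fiber length.")
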
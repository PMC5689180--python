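"""One-at-a-time sensitivity of fiber excursions to model parameters.

On a small synthetic model driven by the cohort-mean gait, perturbs the
optimal fiber length and tendon slack length by +/- 1 SD and sets the
tendon reference strain to its stiff (2 %) and compliant (9 %) extremes,
reporting the mean +/- SD absolute excursion change across muscles (in
units of optimal fiber length).
"""

from myogait import (
    GaitSpec,
    JointWave,
    ModelSpec,
    average_kinematics,
    default_curves,
    sensitivity_analysis,
    synth_gait,
    synth_model,
)

model = synth_model(ModelSpec(
    n_muscles=6, rigid_fraction=0.5, geometry="linear_surface", seed=21,
))
cohort = synth_gait(GaitSpec(
    joints={
        "hip": JointWave(90.0, 15.0),
        "knee": JointWave(95.0, 25.0, 1.0),
        "ankle": JointWave(90.0, 20.0, 0.5),
    },
    n_subjects=8, subject_noise_sd=2.0, seed=22,
))
mean_kin = average_kinematics(cohort)

reports = sensitivity_analysis(model, default_curves(), mean_kin)
print(f"{'parameter':<14} {'mean |dE|':>10} {'SD':>8}   (fractions of L_o)")
for r in reports:
    print(f"{r.parameter:<14} {r.mean_delta:>10.4f} {r.sd_delta:>8.4f}")
print("\nSmall deltas mean the excursion estimates are robust to plausible")
print("architecture-parameter variability; rigid-tendon muscles are exactly")
print("insensitive to the tendon strain parameter.")
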
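# Methods

This note documents the model, its numerical treatment, the synthetic-data
generators, and the design choices made where the design was genuinely
open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Muscle-tendon model

Each actuator is a lumped Hill-type muscle-tendon unit: a contractile
element (activation-scaled active force-length curve, force-velocity
scaling) in parallel with a passive elastic element, in series with a
nonlinear elastic tendon. Pennation follows the constant-height
convention, L^M sin α = L_o sin α_o, with α clamped at 84° near degenerate
poses. Internally everything is SI (m, rad, s, N); gait files carry
degrees, and readers convert at the boundary.

Normalized constitutive curves (module `myogait.curves`):

| curve | form | anchors |
|---|---|---|
| active force-length | Gaussian `exp(-(l-1)^2 / 0.45)` | f_L(1) = 1 |
| passive force-length | exponential above l = 1 | f_P(l ≤ 1) = 0, f_P(1.7) = 1 |
| force-velocity | Hill hyperbola (shortening), saturating eccentric branch | f_V(-1) = 0, f_V(0) = 1, sup f_V = 1.4 |
| tendon force-strain | quadratic toe to ε_o/3, then linear | f̃^T(0) = 0, f̃^T(ε_o) = 1 exactly |

The tendon reference strain ε_o defaults to 0.049 (strain at which the
tendon carries the maximum isometric force) with an admissible range of
0.02-0.09; it is the one curve parameter exposed throughout (CurveSet
constructor, sensitivity driver). The Hill shortening curvature constant
is a_f = 0.25 (slope 5 at v = 0). The eccentric branch plateaus at 1.4
with slope 2·(1 + 1/a_f) at v = 0: the stiff eccentric response of the
standard curve family. Slope continuity at v = 0 was considered and
rejected — a shallow eccentric branch exaggerates tracking lag during
lengthening. All curves have closed-form inverses where the solvers need
them (tests assert round-trips to 1e-10), and scalar fast paths mirror the
array versions for the integration inner loop.

Activation is floored at 0.05 everywhere to avoid the numerical
singularity of the equilibrium inversion as activation approaches zero;
the floor value is also the "minimum activation" case of the excursion
statistic.

## Fiber-length solvers

**Rigid tendon** (applied when L_o/L_s > 2, i.e. essentially no external
tendon): L^M = sqrt((L^MT − L_s)² + (L_o sin α_o)²), floored at 0.01 L_o.
The rule threshold is exposed as `model.RIGID_TENDON_RATIO`.

**Static (quasi-static) equilibrium**: at zero fiber velocity, solve
F_o [a f_L(l) + f_P(l)] cos α = F_o f̃^T(ε) for L^M by Brent's method on
the bracket [0.01 L_o, sqrt(L^MT² + (L_o sin α_o)²)]. Converged states
satisfy |F^T − F^M cos α| < 1e-6 F_o (asserted over 1000 randomized solves
in the acceptance suite). When the bracket has no sign change (e.g. the
whole muscle-tendon unit shorter than the tendon slack length) the nearer
boundary is returned flagged `unbracketed`, not silently.

**Elastic tendon**: the fiber velocity is recovered from the equilibrium
constraint by inverting the force-velocity curve,
f_V = (f̃^T(ε)/cos α − f_P) / (a f_L), clamped to the invertible range
[0, 1.4), and dL^M/dt = ṽ V_max L_o is integrated by fixed-step RK4 on the
101-sample grid, initialized from the static solution at sample 0.
Normalized lengthening velocity is additionally capped at 1.5 (the curve
inverse blows up at the eccentric plateau); every clamp and floor event is
counted on the trajectory and logged by the CLI at info level.

The substep count is stiffness-aware. Linearizing the ODE around
equilibrium gives a relaxation rate λ ≈ k_T V_max L_o / (L_s · a · 5),
with k_T the tendon linear-limb slope; low activation with a stiff tendon
makes the system stiff, and a fixed substep count produces clamp-
oscillation artifacts that corrupt the low-activation fiber-length maxima
(observed as spurious ~0.007 L_o excursion inflation before the guard was
added). The integrator therefore uses `ceil(3 λ dt)` substeps per sample
(minimum 10) and, above 400 substeps/sample, falls back to the samplewise
static solution — in that regime the relaxation time is negligible against
the cycle, so the quasi-static limit is the accurate one.

Cycle durations are metadata (defaults: mouse-like 0.35 s, human-like
1.1 s presets), used only by the elastic integrator through the
force-velocity coupling. At walking rates with full activation and very
compliant tendons the dynamic trajectory genuinely lags the quasi-static
one (the shallow Hill force-velocity curve requires a force imbalance to
move the fiber); tests assert quasi-static agreement within 0.02 L_o only
on deliberately slow inputs, and the rigid/elastic excursion agreement at
the L_o/L_s = 2 rule boundary (< 0.02 L_o) at both species cadences.

## Geometry

Two backends per unit. *Path*: the kinematic chain is posed by composing
hinge rotations (Rodrigues) and L^MT is the summed distance over the
via-point chain; only sagittal flexion/extension joints articulate, all
other degrees of freedom stay locked at their default angles. *Surface*: a
tensor-product polynomial L^MT(q) fitted by least squares
(`fit_length_surface`, rank checked with a condition diagnostic, max
residual stored), intended for muscles whose published geometry uses
wrapping surfaces that this package deliberately does not implement.

Moment arms use the tendon-excursion method, r = −∂L^MT/∂q, as a central
finite difference with step 1e-4 rad on either backend; at that step both
truncation and rounding errors sit below ~1e-8 m in double precision
(verified against the toy-hinge closed form to 1e-6 m). Sign convention:
flexion angles increase, so flexors have positive moment arms. A unit
whose length does not depend on a joint returns exactly 0. Cycle-level
summaries store the signed cycle average of r/L_o; cross-species
comparisons use its magnitude, since the scientific comparison is about
the size of moment arms, not their direction.

## Excursion pipeline

Per muscle and subject, every unit is simulated at a = 0.05 and a = 1 over
the same prescribed L^MT series; the unit excursion is (max L^M at 0.05 −
min L^M at 1)/L_o and multi-unit muscles average their units unweighted.
Extrema are taken over the raw 101-sample cycle without smoothing. The
monotone activation ordering of static solutions (lower activation, less
tendon stretch, longer fiber) makes E nonnegative and at least as large as
either single-activation range; both properties are asserted over
randomized suites. Joint excursions are max − min of the joint angle in
degrees. `run_cohort` collects per-subject failures and continues,
reporting them in the table's `failures` list.

## Statistics

Cross-species comparisons run one two-sample t-test per homologous muscle
pair across subjects, then Holm-Bonferroni over the family at α = 0.05
(step-down; adjusted p = running max of (m−i+1)·p_(i), capped at 1;
delegated to statsmodels and pinned by a hand-worked example in the
tests). Welch's unequal-variance test is the default — cohorts are small
and unequal (16 vs 5 in the presets) — with the equal-variance variant
switchable. One calibration caveat, measured rather than assumed: at
n = (16, 5) the Welch-Satterthwaite df approximation is anti-conservative
in the far tail (rejection at p ≤ α/25 runs about twice nominal), so a
25-test Holm family under the null rejects something in roughly 9-10 % of
replicates instead of ≤ 5 %. The familywise-error calibration test
therefore uses the equal-variance variant — exact for the
equal-distribution, equal-variance null the generator draws — and
separately bounds the Welch variant's inflation. For real comparisons with
a genuine effect this liberality is immaterial next to the effect sizes of
interest, but users testing near-null differences at n ≤ 5 should prefer
`equal_var=True`.

Fat-fraction regressions are ordinary least squares per muscle group
(upper vs lower leg, fitted separately because proximal muscles are more
affected in Duchenne muscular dystrophy), with the reported p the slope
F-test. Exclusion and merge lists are data, not code: merges average the
excursions of several heads into one predictor before fitting (e.g. when
imaging reports one fat fraction for the whole peroneus), exclusions drop
outliers or muscles without imaging data; each group needs n ≥ 3 after
filtering. A constant response returns slope 0, r² = 0, p = 1 rather than
a 0/0.

The sensitivity driver re-runs the excursion pipeline on cohort-mean
kinematics with one parameter perturbed at a time: L_o ± 1 SD, L_s ± 1 SD
(per-unit reported SDs; units without a reported SD are skipped with a
warning, while an SD of exactly 0 yields a delta of exactly 0), and ε_o at
0.02 and 0.09. Excursion changes are compared in meters and normalized by
the *nominal* L_o, then summarized as mean ± SD across the compared
muscle set. Rigid-tendon muscles are exactly insensitive to ε_o (the
tendon curve is never evaluated), which the tests assert.

## Synthetic data

The generators exist so every stage runs end-to-end offline; they are pure
functions of (spec, seed) and their outputs always pass the model
validators.

* `synth_gait`: per joint, angle(t) = offset + Σ_k amplitude·rel_k·
  sin(2πkt/100 + phase) + per-subject Gaussian offset (truncated at
  ±3 SD; one draw per subject × joint in joint order, so tests can
  reproduce the draws).
* `synth_model`: pelvis→femur→tibia→foot chain with sagittal hinges;
  muscles assigned round-robin to hip/knee/ankle; the requested
  rigid-tendon fraction is met exactly by construction (rigid units get
  L_o/L_s = 3, compliant ones L_s/L_o ∈ [2, 4]). Geometry: `toy_hinge`
  two-point paths realizing the analytic L(q) = sqrt(p² + d² − 2pd cos q)
  oracle, `via_points` three-point paths, or `linear_surface` length maps;
  attachment radii are solved so the neutral-pose (q = 90°) length equals
  L_s + L_o cos α_o.
* `synth_fat_fraction`: fraction = clamp(slope·E + intercept + noise, 0, 1).
* `species_presets`: caricatures of mouse and human treadmill walking that
  encode only coarse anchors — the mouse knee stays above 90° flexion with
  a small range while the human knee peaks below 70° (bounds hold by
  construction given the 3-SD truncation: 112−14−6 = 92; 38+25+6 = 69),
  walking speeds 0.2 vs 1.25 m/s, cycle durations 0.35 vs 1.1 s, cohort
  sizes 16 vs 5. `preset_model` pairs them with 25-muscle models (10/25
  rigid-tendon mouse, 3/25 human; mouse fibers ~1 cm vs human ~10 cm;
  normalized moment arms 0.08-0.25 vs 0.25-0.55).

What the generators emulate: cohort sizes, per-subject kinematic
variability, the rigid/compliant tendon split, species-scale architecture
and moment arms, and a linear excursion→fat-fraction structure. What they
do not: real waveform shapes (no digitized gait data), 3-D wrapping
geometry, muscle redundancy/co-articulation, EMG-derived activations, or
measurement noise models. Tests passing on synthetic cohorts therefore
validate the machinery and its invariants, not anatomical values; analyses
of real species differences require the published musculoskeletal models
and motion data as inputs.

## Problem sizes and determinism

Default problem sizes were chosen to keep a full run desk-scale: 101-point
gait grid; preset cohorts of 16 + 5 subjects × 25 muscles × 2 activations
(the full two-species pipeline runs in well under a minute on one CPU);
randomized acceptance suites of 1000 static solves, 1000 null-cohort
replicates and 500 regression replicates. All randomness flows through
integer seeds into `numpy.random.default_rng`; the CLI records a config
hash and seed in a manifest, and the acceptance suite asserts byte-level
reproducibility of the preset pipeline.

## Known limitations

* No wrapping surfaces, conditional/moving path points, or non-sagittal
  articulation; `.osim` reading is a parameter-and-fixed-path subset that
  flags affected muscles `geometry_approximate`, and fitted length
  surfaces are the intended substitute backend.
* No activation dynamics (activation is constant by design — the statistic
  brackets all profiles), no fiber damping, no skeletal forward dynamics.
* The elastic integrator is explicit; extremely stiff cases fall back to
  the quasi-static solution rather than failing, which is accurate for
  length trajectories but does not resolve sub-relaxation-time force
  transients.
* Welch small-sample calibration as described under Statistics.
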
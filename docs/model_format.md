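# Native model format

Musculoskeletal models are YAML (or JSON — any mapping `yaml.safe_load`
accepts) documents with the top-level keys below. Lengths are meters
unless the header declares millimeters; angles on file are always degrees.

```yaml
format: myogait-model        # optional marker
units:                       # optional; defaults shown
  length: m                  # "m" or "mm" (mm values are scaled by 1e-3 on load)
  angle: deg                 # always degrees on file
species: mouse               # free-form label used in result tables
cycle_duration: 0.35         # s, metadata for the elastic-tendon integrator

segments: [pelvis, femur, tibia, foot]   # ordered chain; first = root frame

joints:                      # connect consecutive reachable segments
  - name: hip
    parent: pelvis
    child: femur
    location_in_parent: [0.0, 0.0, 0.0]  # joint center in the parent frame
    axis: [0, 0, 1]                      # rotation axis in the parent frame
    sign: 1                              # +1: flexion increases the rotation
    default_angle_deg: 0.0               # pose used when locked / not driven
    articulated: true                    # false = locked degree of freedom
    range_deg: [-30, 120]                # optional; outside -> warning

muscles:
  - name: vastus_lateralis               # anatomical muscle (groups units)
    units:
      - name: vastus_lateralis_1
        F_o: 10.0            # N, maximum isometric force
        L_o: 0.010           # m, optimal fiber length
        V_max: 10.0          # optimal fiber lengths / s
        alpha_o_deg: 5.0     # pennation at optimal fiber length
        L_s: 0.003           # m, tendon slack length
        L_o_sd: 0.001        # m, optional reported SD (sensitivity analysis)
        L_s_sd: 0.0005       # m, optional; omit when not reported
        path:                # >= 2 fixed points, proximal to distal
          - {segment: femur, location: [0.01, 0.02, 0.0]}
          - {segment: tibia, location: [0.01, -0.03, 0.0]}
        # alternatively, a fitted length surface replaces the path:
        # surface:
        #   joints: [knee]
        #   coeffs: [0.05, -0.012]        # tensor-product polynomial
        #   domain: [[0.0, 2.5]]          # rad, per joint
        #   max_residual: 1.2e-6          # m, from the fit
```

Validation on load: positive `F_o`, `L_o`, `V_max`; `L_s >= 0`;
`0 <= alpha_o < 90 deg`; every path point references a known segment;
joints form a connected acyclic chain from the root; units with a
`surface` key use the surface geometry backend. Missing required
parameters fail naming the unit. `write_model` emits this format with full
float precision (round-trips preserve parameters to at least 12
significant digits).
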
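# wristkin

Carpal-bone kinematics from wrist CT, for biomechanics and hand-surgery
research groups studying ligament injuries in cadaver (or in-silico) wrist
series. The package implements the full measurement chain used in
scapholunate (SL) ligament transection studies:

1. **Segmentation** — Hounsfield thresholding, 26-connected components,
   marching cubes and Taubin smoothing turn CT-like volumes into closed
   per-bone surfaces (radius, ulna, 8 carpals, 5 metacarpals).
2. **Coordinate frames** — a radius-anchored referential frame (origin at
   the ulnar-notch midpoint; Y along the longitudinal inertia axis of the
   radius cropped 60 mm proximal to the styloid, proximal-positive; Z
   dorsal; X = Y × Z radial) plus per-bone object frames built from the
   volumetric centre and solid inertia axes, with sign-consistent
   eigenvector orientation across poses.
3. **Kinematics** — each pose's radius is ICP-registered to the neutral
   radius; every bone's rigid transform relative to its own neutral is
   expressed in the referential frame and factored intrinsically as
   `R = Rx(α)·Rz(γ)·Ry(β)`: α = flexion(+)/extension(−),
   γ = ulnar(+)/radial(−) deviation, β = pronation(+)/supination(−);
   translations are the centroid motion along the referential axes (mm).
4. **Statistics** — per pose × channel, a Shapiro–Wilk gate chooses
   two-way ANOVA + Tukey HSD (parametric) or Kruskal–Wallis + Dunn
   (rank-based), with per-bone transected − intact mean-difference
   contrasts at α = 0.05.

Because cadaver CT series are rarely shared, the package includes a
first-class **synthetic wrist generator**: superellipsoid bones posed by a
carpal-row model (proximal row gets half the global pose angle, distal row
and metacarpals the full angle), per-specimen random pose amplitudes,
condition-specific effect increments (e.g. +11.71° scaphoid flexion after
transection), vertex noise and optional voxelization to Hounsfield-like
NIfTI volumes — all with exact ground-truth transforms, so the entire
pipeline can be validated end to end. See `docs/methods.md` for the model
and its assumptions.

## Worked example

Simulate the default study design (21 specimens, 5 poses, intact vs
SL-transected) at the motion-record level and test the flexion rotations:

```python
from wristkin import synthetic as syn
from wristkin.stats import compare_conditions

cohort = syn.simulate_motion_records(21, seed=7)     # 2520 motion records
res = compare_conditions(cohort, poses=["flexion"], channels=["rot_x_deg"])[0]
print(f"flexion / rot_x: omnibus {res.test_name}, p = {res.p_value:.2e}")
for c in res.condition_contrasts:
    if c["bone"] in ("scaphoid", "lunate", "mc1"):
        print(f"  {c['bone']:9s} diff = {c['estimate']:+6.2f} deg  "
              f"adj p = {c['adjusted_p']:.4f}")
```

prints

```
flexion / rot_x: omnibus kruskal_wallis, p = 4.97e-02
  lunate    diff =  +0.88 deg  adj p = 1.0000
  mc1       diff =  +5.36 deg  adj p = 0.1544
  scaphoid  diff = +11.67 deg  adj p = 0.0001
```

i.e. the scaphoid's injected 11.71° extra palmar flexion after transection
is recovered (estimate +11.67°) and is the only significant proximal-row
contrast, while the lunate is essentially unaffected — the motion pattern
this analysis is designed to detect.

The same study through the full mesh pipeline (generation → frames →
registration → decomposition → stats), from the shell:

```bash
wristkin run-all --simulate --n 4 --seed 1 --out run/
# run/cohort.csv        480 motion records (4 x 15 bones x 4 poses x 2 conditions)
# run/stats/...         condition contrasts + omnibus results
# run/run_log.jsonl     parameters and seed, sufficient to reproduce byte-for-byte
```

Stage-by-stage commands (`wristkin simulate|segment|frames|kinematics|stats`)
operate on STL/PLY meshes, NIfTI-1 volumes, JSON landmark/frame files and
CSV cohorts; left hands are mirrored into right-hand convention at load
time.

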
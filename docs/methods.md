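# Methods

`wristkin` quantifies how the carpal bones, metacarpals and ulna move
relative to the radius across wrist poses, and how that motion changes after
transection of the scapholunate (SL) interosseous ligament. This note
describes the model and the numerical choices; it is the companion to the
API documentation in the module docstrings.

## Coordinate systems

**Referential frame.** All motion is expressed in a radius-anchored frame:

* origin — midpoint between the palmar and dorsal edges of the distal
  radius at the ulnar notch (supplied as landmarks);
* Y — the longitudinal inertia axis (smallest principal moment) of the
  radius cropped to 60 mm proximal to the radial styloid tip, oriented
  proximally (from the styloid toward the cropped volumetric centre);
* Z — the unit normal of the plane spanned by Y and the vector from the
  origin to the cropped radius' volumetric centre, signed dorsally
  (positive dot product with the palmar→dorsal notch-edge vector);
* X = Y × Z, pointing radially for a right hand.

Left hands are reflected through the YZ-plane (with face winding flipped)
before any frame is built, so one sign convention serves both sides.

The 60 mm crop is two-pass: the cut plane is placed along the longitudinal
axis of the *uncropped* radius, and the axis and volumetric centre are then
re-derived from the cropped mesh. Whether the original workflow re-derived
the axis after cropping is not documented anywhere we know of; re-deriving
is the self-consistent choice (the frame depends only on the geometry that
defines it).

**Object frames.** Each bone's frame has its volumetric (solid, uniform
density) centroid as origin and its solid inertia axes as axes, sorted by
ascending moment so axis 1 is the longitudinal axis. Eigenvector signs are
fixed by positive dot product against a reference triad — the referential
axes at neutral, the bone's own neutral axes in every other pose — and
right-handedness is restored by flipping the third axis when needed. This
keeps axes "pointing the same way" across poses without vertex
correspondence. A surface-shell inertia tensor would be an alternative
reading of an inertia-axis frame; the solid interpretation is used because
the same workflow uses *volumetric* centres as origins.

All mass properties are evaluated exactly from the closed surface by the
divergence theorem (per-face signed tetrahedra against the origin; the
second-moment matrix of each tetrahedron has the closed form
`V/20·(aaᵀ+bbᵀ+ccᵀ+ssᵀ)`, `s = a+b+c`). Principal-axis extraction refuses
to proceed when the smallest eigenvalue gap is below `1e-6·trace`
(degenerate inertia is an error, never a silent arbitrary basis).

## Kinematics

For each specimen and condition, the neutral scan is the reference. Every
pose's radius is registered to the neutral radius (centroid + principal-axis
initialization, then point-to-point ICP with a Kabsch update per sweep,
stopping when the RMS nearest-neighbour distance changes by < 1e-6 mm), and
all of that pose's object frames are mapped through the alignment. The
bone's motion is the rigid transform taking its neutral frame to its aligned
pose frame, conjugated into referential coordinates.

Rotations are factored intrinsically as **X → Z → Y**:
`R = Rx(α)·Rz(γ)·Ry(β)` with α = flexion(+)/extension(−),
γ = ulnar(+)/radial(−) deviation, β = pronation(+)/supination(−).
The anatomical axis-to-motion mapping fixes which axis carries which motion
but not a factorization order; X-first is chosen so the clinically primary
motion is extracted first, and for the small off-primary angles observed the
order effect is second order. Angles are reported in degrees, α and β in
(−180, 180], γ in [−90, 90]; near gimbal lock (|cos γ| < 1e-8) β is set to 0
and the residual is absorbed into α. Translations are the motion of the
bone's volumetric centroid along the referential axes (radial+, proximal+,
dorsal+; palmar translation is negative Z).

Each condition (intact / transected) uses its own neutral scan as reference,
so condition effects appear as differences between conditions of
pose-relative motion, not as differences of absolute position.

## Synthetic wrist generator

Real study data of this kind (cadaver CT series) are typically not publicly
deposited, so the package ships a generator that emulates the study design
with exact ground truth: 21 specimens × 5 poses (neutral, flexion,
extension, ulnar and radial deviation) × 2 conditions, i.e. 105
transected-condition scans.

* **Shapes.** The 15 bones are superellipsoids
  (`((|x/a|^p+|y/b|^p)^{q/p}+|z/c|^q)=1`, built by radially mapping a
  subdivided icosphere; the radial closed form follows from degree-1
  homogeneity). Semi-axes are pairwise distinct so inertia axes are
  unambiguous; exponents 1.8–2.4 give bone-like blobs. The layout is
  anatomically inspired (forearm proximal, two carpal rows, five
  metacarpals) with no bone overlap, which keeps voxelization and
  segmentation well-posed.
* **Pose model.** A carpal-row model: the forearm is fixed (the ulna gets a
  small fixed 1° offset — it is the least-moving bone), the proximal row
  receives a configurable share (default 0.5) of the global pose angle, the
  distal row and metacarpals the full angle. Rotations act about each
  bone's neutral centroid, so ground-truth translations are exactly the
  injected translation effects. Global pose amplitudes are drawn per
  specimen **and per condition** — each scan is an independent physical
  repositioning "to maximal extent", and in the emulated design the intact
  and transected series were acquired in separate sessions — as
  N(60, 8²)° flexion, N(50, 8²)° extension, N(30, 5²)° ulnar and
  N(20, 4²)° radial deviation. With all dispersions set to zero the intact
  and transected geometries coincide exactly, which is the generator's
  null invariant.
* **Transection effects.** Condition increments are composed after the
  intact pose transform, per (bone, pose, axis, channel). The default
  configuration encodes only the effects the source study reports
  significant: the two printed rotation magnitudes (+11.71° scaphoid
  flexion; 9.13° further extension of the fifth metacarpal), a 5°
  placeholder for the first-metacarpal flexion increase, and 5 mm / 3 mm
  placeholder translations (palmar for trapezoid and metacarpals in
  flexion, proximal for mc2–4 in extension and mc4–5 in ulnar deviation,
  ulnar for mc1–2 in ulnar deviation; nothing in radial deviation) — the
  translation magnitudes are not printed in the source, so these are
  design values, chosen large enough to be detectable at n = 21. Each
  increment gets a per-specimen deviation (sd 4° / 1.5 mm).
* **Noise.** I.i.d. Gaussian vertex noise (default sd 0.05 mm) emulates
  segmentation surface error. The record-level simulator
  (`simulate_motion_records`) bypasses meshing and adds Gaussian
  measurement noise (0.1°, 0.05 mm) directly to the ground-truth records;
  it shares `pose_model` with the mesh path and exists so that
  1000-replicate statistical experiments don't need 10⁵ mesh
  reconstructions.
* **Voxelization.** Optional CT-like volumes: voxel centres inside a bone
  get 700 HU, background −50 HU, optional Gaussian intensity noise,
  0.5 mm isotropic spacing by default (the slice thickness of the emulated
  scans), ≥ 2-voxel margins, NIfTI-1 affine as the single index→mm map.
  Containment is computed by a z-column parity rasterizer (triangle
  crossings per voxel column, with a deterministic sub-voxel jitter to
  avoid edge-exact ties).

What the generator does **not** emulate: real bone geometry (cortical
shells, articular facets), ligament mechanics, bone–bone contact, CT
artefacts, or segmentation failure modes beyond additive surface noise.
Passing the end-to-end tests therefore demonstrates that the *pipeline*
recovers known kinematics from mesh/volume input under realistic noise — it
does not validate segmentation quality on clinical CT.

## Segmentation stage

Hounsfield-window threshold (default [300, ∞) for the synthetic contrast),
26-connected components in decreasing size order (bones are compact; looser
connectivity risks splitting thin necks), marching cubes at level 0.5 on the
2-voxel-padded volume (a component touching the unpadded boundary is a hard
error rather than a silently capped surface), then Taubin smoothing
(λ = 0.5, µ from the pass-band via 1/λ + 1/µ = k). Taubin is used instead of
plain Laplacian smoothing because Laplacian shrinkage would bias the
volumetric centres that anchor every object frame. Components are assigned
to named bones by seed points (a seed inside exactly one component claims
it; two seeds in one component is a "fused bones" error; seeds in no
component fall back to greedy nearest-centroid).

## Statistics

Per pose × channel, every (bone × condition) group is Shapiro–Wilk tested;
only if **all** groups pass (p > α, and n ≥ 3) does the parametric branch
run — two-way ANOVA (type-II, condition × bone) with Tukey HSD for
bone-vs-bone pairs and t contrasts per bone — otherwise the rank branch
runs: Kruskal–Wallis per factor, Dunn's z pairs (Bonferroni by default,
Holm optional) and Mann–Whitney condition contrasts. The all-groups gate is
deliberately conservative; with 30 groups it routes most channels to the
rank branch even for normal data.

Per-bone condition contrasts report the mean difference transected − intact
with both the raw p-value and a family-adjusted p across the 15 bones.
Bone-vs-bone comparisons are computed within condition and within carpal-row
family (proximal row, distal row, metacarpals), on the referential-frame
channel values, and only when that family's omnibus test is significant at
α = 0.05; α is not additionally corrected across poses or channels,
mirroring the reporting convention of this literature.

The comparison is **unpaired by default** (matching a plain two-way ANOVA
with condition as a factor); `paired=True` switches the condition contrasts
to within-specimen differences (paired t / Wilcoxon). Because the generator
redraws pose amplitudes per condition, the unpaired analysis is calibrated:
under zero injected effects the per-contrast type-I rate sits at α (the
acceptance suite verifies 3–7% over 200 null cohorts).

## Problem sizes and numerical choices

* Default mesh resolution is icosphere subdivision 3 (642 vertices/bone),
  which keeps voxel-scale experiments cheap. Experiments whose bands are
  sensitive to discretization noise run at higher resolution: the noisy
  parameter-recovery experiment at subdivision 4, the referential-frame
  stability check at subdivision 5 (~10⁴ vertices — the density of a real
  segmented radius; coarser meshes understate the stability of the real
  pipeline).
* Noise-free end-to-end recovery is exact to ≈ 1e-10°; the 1e-3° bound in
  the tests is pure safety margin.
* The null-calibration and power simulations use the record-level
  simulator (200 and 100 cohorts of n = 21).
* ICP: 200-iteration cap, 1e-6 mm RMS-change stop, registration failure
  declared only above 0.5 mm residual RMS.
* Rigid-transform invariants are enforced at 1e-9 (orthonormality,
  det = +1); products of long transform chains are re-projected onto SO(3)
  via SVD.
* CSV output uses fixed `%.9g` formatting so reruns with the same seed are
  byte-identical.

## Known limitations

* The plane-cut cap triangulates the cut polygon as a centroid fan, which
  assumes star-shaped cross-sections — true for the synthetic bones and
  for a radius shaft, not for arbitrary meshes.
* The styloid/notch landmarks are inputs; the built-in styloid heuristic
  is a labelled approximation, not a detector.
* Bone-vs-bone "relative motion" is computed as differences of
  referential-frame components, not as composed relative transforms
  between bone pairs.
* The generator's effect translations and the mc1 rotation placeholder are
  design values, not published magnitudes; conclusions about those
  channels only exercise the machinery.
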
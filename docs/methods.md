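# Methods

## Problem and model

After bimaxillary orthognathic surgery (Le Fort I osteotomy of the maxilla
plus bilateral sagittal split of the mandible), the clinical question is how
closely the achieved bone positions match the 3D virtual plan. This package
quantifies that per segment — maxilla, distal (tooth-bearing) mandibular
segment, and the two proximal (condyle-bearing) segments — as rigid-body
motions, reported in clinically meaningful components.

The core abstraction is the **segment triangle**: three cephalometric
landmarks per segment, identified once on the preoperative model, forming an
oriented triangle that encodes the segment's position and orientation.
Vertex order is a fixed convention per segment (maxilla: mesial cusp 16,
upper incisor, mesial cusp 26; distal mandible: mesial cusp 46, lower
incisor, mesial cusp 36; proximal: condor, C-point, gonion), so point
correspondence is never ambiguous. The triangle rides along with the segment
through planning and surgery; because it is transferred by software rather
than re-identified, repeated landmark-identification error does not
accumulate across states.

Two motions are derived per segment:

* **surgical displacement** — preoperative → postoperative;
* **surgical accuracy** — planned → postoperative (zero for a perfectly
  executed plan).

Proximal segments are not planned preoperatively, so they yield only
displacement-derived rotational measures (autorotation, flare).

## Rigid fit

With exact point correspondence the least-squares rigid motion between two
triangles has the closed-form Kabsch/SVD solution: for centred vertex
matrices S (source) and G (target), the cross-covariance H = SᵀG with SVD
H = U diag(s) Vᵀ gives R = V diag(1, 1, det(VUᵀ)) Uᵀ and t = ḡ − R s̄. The
sign correction on the smallest singular direction forbids reflections
(det R = +1 always); scaling is never modelled — the outputs are pure
translations and rotations. The fit is validated against an independent
closed-form quaternion solver (Horn's method) and recovers 1000 random rigid
motions to < 1e-9 in the test suite.

A note on reflections: three landmarks are necessarily coplanar, so the
mirror image of a triangle is always reachable *exactly* by a proper
rotation. The reflection guard therefore guarantees a proper transform (and
is exercised by mirrored targets) but cannot, and does not, promise a
non-zero residual for mirrored triangles.

Degenerate (collinear) landmark triples — area ≤ 1e-6 mm² — are a hard
error: valid dental/ramus landmark triples are never collinear, so collinear
input means the landmarks are unusable, not that a warning should be logged.

## Anatomical frame and decomposition

The reporting frame emulates the natural head position and is built from the
cranial reference landmarks:

* **up/down axis** — unit normal of the Frankfort plane, fitted by least
  squares through both porions and all available orbitale points (one
  orbitale suffices; with three points the plane is exact), oriented toward
  nasion (cranially);
* **left/right axis** — left porion → right porion, projected into the
  plane;
* **anterior/posterior axis** — completes the right-handed set; checked to
  point toward nasion;
* origin — sella (the origin affects no reported quantity; rotations are
  origin-free and translations are reported for a stated reference point).

Sign conventions: anterior, patient-right and cranial translations are
positive; positive pitch/roll/yaw are right-hand rotations about the
left-right / anterior / cranial axes respectively, i.e. anti-clockwise as
seen from the patient's right, from anterior, and from above.

Rotations are factored by the intrinsic yaw → roll → pitch Euler sequence
(about the up/down, then anterior/posterior, then left/right axis).  Any
fixed order is equally defensible at surgical magnitudes: the discrepancy
between Euler conventions is second order (≈ θᵢθⱼ/2 rad), which is ≈ 0.16°
worst-case when all three angles reach 3° and shrinks quadratically below
that — an order of magnitude under the ≈ 0.6° observer variation of the
measurements themselves, though not below 0.01° (a regression test records
the measured sensitivity). The singular configuration of this sequence is
|roll| = 90°, far outside the surgical range; it raises an explicit
gimbal-lock error rather than wrapping silently.

Translations of a rigid motion depend on the reference point when the
rotation is non-zero. Reports therefore state the displacement of the
segment-triangle centroid (preoperative centroid for displacement, planned
centroid for accuracy): a segment rotated purely about its own centre
reports zero translation. `decompose` exposes this as the optional `about`
point; without it the raw translation vector is decomposed.

Proximal-segment **autorotation** is defined as the rotation about the
left/right axis (the condylar hinge direction) and **flare** as the rotation
about the up/down axis (lateral swing of the gonial region). These are
declared conventions of this package — the terms have no universal
operational definition — and use the same Euler sequence and signs as the
six-component reports.

## Registration stand-ins

Where postoperative triangles are not given directly, segment motions are
recovered from images at desk scale:

* **Volume registration** (maxilla, distal segment, cranial base):
  SimpleITK rigid registration, normalised cross-correlation metric by
  default (mutual information selectable), three resolution levels (shrink
  4/2/1, smoothing 2/1/0 voxels), dense sampling, linear interpolation,
  regular-step gradient descent with fixed iteration caps — fully
  deterministic for identical inputs. A fixed-image mask restricts the
  metric to a surgically unaffected subvolume (the cranial base) when whole
  models are registered. On 0.4 mm phantoms, known motions are recovered
  well within half a voxel (0.2 mm) and 0.5°.
* **Surface registration** (proximal segments): trimmed point-to-point
  iterative closest point — nearest-neighbour correspondences, the worst 10%
  of pairs discarded each iteration, rigid Kabsch update, convergence when
  the RMS distance changes by < 1e-6 mm (cap 200 iterations). Trimming makes
  the fit robust to partial overlap, mirroring incompletely segmented
  condylar surfaces. Hand-written because no available ICP implementation
  exposes deterministic worst-pair trimming.

In registration mode the accuracy motion is computed as
D ∘ P⁻¹, where D is the registered preop→postop motion (initialised at the
plan P); this avoids resampling the planned state.

## Observer reliability statistics

The validation design repeats the landmark-dependent steps per patient:
observer 1 twice (four weeks apart) and observer 2 once. Per report
component:

* **observer variation** — mean over patients of the absolute
  between-session difference, with a percentile-bootstrap 95% CI (10,000
  resamples by default, seeded, over patients). Bootstrap is used because no
  distributional form is defensible at n = 10.
* **ICC(2,1)** — two-way random-effects, absolute-agreement, single-measures
  intraclass correlation (computed from the ANOVA mean squares via
  pingouin), with F-distribution CIs. Absolute agreement is the appropriate
  form here: the sessions measure the same physical quantity, so systematic
  offsets between raters must count as disagreement. Zero between-patient
  variance makes the ICC undefined and raises; missing cells are refused
  rather than imputed.

## Synthetic data

The generator produces everything the pipeline consumes without any CT data:

* **Phantom skull** — the cephalometric constellation at realistic adult
  positions (porion separation ≈ 84 mm, dental arches ≈ 50–60 mm below
  sella) with seeded per-landmark jitter (SD 0.4 mm), so bilateral symmetry
  holds only within noise; per-segment intensity structures are Gaussian
  blob clusters (teeth along a Bezier dental arch, ramus blobs, a cranial
  scatter), and per-segment meshes are blobby icosphere clusters. Blob
  clusters are rendered onto voxel grids analytically in any pose, so
  registration ground truth carries no interpolation error. The bundled
  volume is a 64³ field of view at 0.4 mm around the cranial base.
* **Simulated surgery** — planned state = plan applied to the preoperative
  segment; postoperative state = plan composed with an execution error drawn
  from the error model, its rotation acting about the planned segment
  centroid (so injected translation/rotation components read back exactly in
  the reports). Landmark-identification noise is added independently per
  state. Error-model defaults (AP error −0.5 ± 1.5 mm, LR ± 0.6 mm,
  UD ± 1.8 mm; pitch ± 3°, roll/yaw ± 1.2°; landmark noise 0.1 mm) emulate
  the dispersion reported for wafer-transferred bimaxillary surgery.
* **Observer sessions** — re-draw identification noise around the true
  landmark positions and rerun the full direct-mode analysis per session.

What the phantom does *not* emulate: CBCT physics (beam hardening, metal
streak artefacts), occlusal surfaces, soft tissue, and real bone topology.
Passing registration tests therefore demonstrate algorithmic correctness on
well-conditioned mono-modal images, not clinical robustness to artefacts.

## Problem sizes and numerical choices

Test and demonstration runs use 64³ voxel volumes (0.4 mm) for cranial-base
registration, ≈ 90×70×40 grids at 0.8 mm for per-segment volumes, blobby
meshes of ≈ 1000 vertices, 10-patient cohorts and 3 observer sessions —
sizes at which the complete analysis of a cohort takes seconds while leaving
the subvoxel-accuracy margins wide. Printed tables round half-up to 2
decimals (computation is double precision throughout); rigid transforms are
validated to 1e-9 orthonormality at construction; bootstrap and all
generators run off explicit seeds, and identical inputs produce
byte-identical report files.

## Known limitations

* The bundled clinical reference cohort ships only as per-patient report
  components; the underlying per-session observer measurements are not
  available, so the reliability tables of the original validation can be
  reproduced only as distributional properties on synthetic grids, not
  numerically. (Two cells of the published distal-segment summary are also
  internally inconsistent with their own per-patient column — the
  left/right mean/absolute-mean pair — and one vertical mean differs by one
  unit in the last printed decimal from recomputation; these are documented
  where tested.)
* Proximal-segment measures are the least reliable outputs, both clinically
  and in simulation: small triangles give landmark noise more rotational
  leverage, and surface registration depends on surface integrity.
* Equivalence with any commercial planning system's registration algorithm
  is not claimed; only the half-voxel accuracy property is.
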
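# Methods

## Scope and design intent

`cervixadapt` is a simulation study, not a treatment-planning system. It
compares three adaptive strategies for cervix EBRT — a plan-of-the-day
library (LOP) and online replanning with 3 mm / 5 mm PTV margins — under
intrafraction anatomical change, on a synthetic cohort. Everything that in
the clinic comes from imaging, contouring, deformable registration or a
commercial optimizer is replaced by a parametric model whose ground truth
is known exactly. Absolute dose numbers are therefore model quantities;
the meaningful outputs are *between-strategy* comparisons and the
structural/statistical patterns of the report bundle.

## The deformable anatomy model

All geometry lives on a fixed patient frame: axis 0 = left-right, axis 1 =
anterior-posterior (+ anterior), axis 2 = inferior-superior (+ superior),
millimetres, with the cervix near the origin. The default grid is 2.5 mm
isotropic over a 40 cm cube (160³ voxels), matching typical planning-CT
resolution while staying desk-scale.

**Cervix-uterus (CTV_T_LR).** A bent elliptical capsule along a quadratic
Bezier centreline from the cervix base to the uterine fundus, continued
20 mm inferiorly as the upper vagina. Cross-section semi-axes grow from
the cervix radius to a wider corpus; over the cervix segment the AP
semi-axis carries an extra 5 mm, the delineation margin of the high-risk
CTV folded into the low-risk CTV analytically (the carve-out against
bladder and rectum is realized by subtracting the capsule from those
organs instead). The capsule is sampled as dense cross-section rows (caps
included as rows of shrinking radius); the voxel rasterizer (union of row
ellipsoids with a 2.5 mm tangential blend) and the surface mesh (one
vertex ring per row) describe the same continuous shape, so the mesh *is*
the structure's surface to sub-voxel accuracy.

**Bladder-driven motion.** The fundus position is
`fundus0 + anteversion_response * fill/100 * (0, sin45°, cos45°)`: filling
pushes the fundus anterior-superiorly along a fixed direction, the cervix
base and vagina stay put, and the Bezier bend distributes the displacement
smoothly (cervix-region motion is ≤ ~10% of fundus motion). This is the
simplest geometry reproducing the clinically observed bladder-driven
uterine tilt with a motion magnitude that decays from fundus to cervix.

**Other organs.** Bladder: a superellipsoid (exponent 2.5) whose semi-axes
are solved so the voxelized volume matches the prescribed fill in ml
(two fixed-point corrections after subtracting the uterus; the rendered
volume is within a few % of the target, contract: ±10%). Rectum: a gently
curved posterior tube. CTV_LN_Pelvic: two lateral vertical tubes fixed to
the bony frame. Bowel bag: a large pelvic superellipsoid (truncated at the
cranial grid face) minus bladder, rectum and CTV_T_LR; its caudal extent
varies per patient and is the main driver of bowel-dose heterogeneity.

**Ground-truth deformation field.** Because the capsule is parametric,
equal surface parameters at two bladder fills are corresponding material
points. `ground_truth_dvf` returns the full-bladder surface mesh with
per-vertex displacements onto the empty-bladder mesh — the role a
contour-based biomechanical registration plays on real scans, with zero
correspondence error by construction. Scaling the displacements by
α ∈ [0, 1] yields the interpolated structures of the library.

A note on the "half a voxel" reproduction contract: it holds exactly on
the continuous surfaces (vertex correspondence error ~1e-15) and is tested
there. Two independent *rasterizations* of the same continuous surface can
legitimately differ by one voxel; mask-level agreement is asserted at that
level.

## Population distributions and motion calibration

Per-patient parameters are drawn once per seed:

| parameter | distribution | default rationale |
|---|---|---|
| uterus length | N(75, 10) mm, clipped 55–95 | adult uterus + cervix extent |
| cervix radius | N(16, 2) mm, clipped 12–21 | ~3 cm cervix diameter + tumour |
| anteversion response | LogNormal(median 13.09 mm/100 ml, σ=0.621) | motion calibration (below) |
| bladder base volume | N(60, 20) ml, clipped 15–120 | post-void residual + early refill |
| fill rate (patient mean) | N(2.5, 0.8) ml/min, clipped 0.8–5 | typical drinking-protocol inflow |
| fill rate (per-fraction SD) | 0.5 ml/min | day-to-day hydration variation |
| setup rotation SD | 1.5° (sagittal, about the top of the uterus) | residual setup rotation |
| bowel caudal shift | N(0, 10) mm, clipped ±22 | patient-to-patient bowel descent |
| tumour regression rate | 0 (off by default) | regression is a separate question |

The 10-minute fundus displacement is `anteversion_response × rate × 0.1`.
The two free constants of the anteversion-response lognormal were solved
(once, before any acceptance run, by direct numerical inversion against
the fill-rate law) so that the *population* displacement distribution has
median 3.1 mm and 90th percentile 7.8 mm — the cervix-uterus motion
statistics reported for a comparable ~9–10 minute interval. A 200-patient
× 4-fraction cohort reproduces both percentiles within the stated ±20%
band; single-cohort scatter is roughly ±10% on the 90th percentile.

Per-fraction sampling: the pre-delivery fill t0 = base volume + a
truncated-normal excess, clipped to 40–290 ml so the daily anatomy stays
bracketed by the planning-scan states (30/350 ml) as the drinking protocol
intends; t1 = t0 + rate × Δt (Δt default 10.0 min, the cohort-average
sagittal-to-transversal interval). Intrafraction *translations* are not
modelled, mirroring the registration choice the simulation reproduces;
the per-fraction setup rotation displaces only the bony frame (nodal CTV)
relative to the soft tissue and is shared by t0 and t1.

What the generator does **not** emulate: delineation variability, bowel
peristalsis and gas, rectum filling changes, MRI geometric distortion,
inter-observer contouring differences, and any correlation between bladder
filling and bowel-bag shape. A green cohort test therefore establishes the
internal consistency of the strategy comparison under bladder-driven
motion — not clinical dose accuracy.

## Geometry

* **Margins** follow the standard RT reading of direction-dependent
  expansions: the structuring element is the union of the 8 octants of
  axis-aligned ellipsoids whose semi-axes come from the margins of the
  matching sign combination. When the two margins of every axis pair agree
  the element is a single ellipsoid and the dilation is computed exactly
  as a scaled Euclidean distance transform; the general case uses an
  explicit footprint with FFT convolution. Both paths are oracle-tested
  against a brute-force shift-union Minkowski dilation.
* The **"0 mm below the vagina"** ITV rule is realized as "voxels inferior
  to the vaginal SI plane seed no dilation (but are kept)", which is
  unambiguous at the boundary.
* **Interpolation count**: the least k such that k equally spaced
  interpolations keep consecutive corresponding vertices within 1 cm;
  under linear scaling this is ⌈maxdisp/gap⌉ − 1, and it is oracle-tested
  against exhaustive search. The gap metric is vertex correspondence
  (the scaling construction provides it); a symmetric Hausdorff mode is
  available as the alternative reading.
* **Voxelization of moved surfaces**: point-in-surface test on voxel
  centres (sign against the nearest moved vertex's outward normal, ties
  toward inclusion) followed by hole filling.

## The idealized dose engine

`dose(x) = Rx · h · Φ((s − d(x))/σ)` with d(x) the signed Euclidean
distance to the PTV surface (negative inside), Φ the normal CDF,
h = 1.04 the hotspot cap, σ = 6 mm the penumbra scale and s the
"shoulder". The normalization pins the 95% isodose *exactly* s mm outside
the PTV surface. Consequences used throughout:

* the planning goals (PTV D98% ≥ 95%, V95% > 98%) hold by construction
  for s ≥ 0 (checked on every plan, violation raises a planning error);
* PTV_A ⊆ PTV_B ⇒ dose_A ≤ dose_B pointwise (signed distances are
  monotone in the mask), which makes the nested-margin dominance between
  the online strategies exact rather than approximate — a deliberate
  idealization of what a per-plan optimizer would only approximately give;
* the conformity index depends on s alone (CI cannot grow when σ shrinks),
  so `calibrate_penumbra` can invert the mean CI over representative PTVs
  for s deterministically (it reads CI(s) off the cumulative distribution
  of outside distances; the result is quantized by the voxel grid and the
  closest achievable value to the mid-range target 1.175 is chosen).

One global penumbra parameter set is used per experiment (calibrated on
the first patient's PTVs), preserving pointwise monotonicity across all
plans. OAR sparing is *not* modelled explicitly: between-strategy OAR
differences arise solely from target-volume differences, which is the
comparison axis of the study. The engine's planned PTV D98% (~100–101%)
is consequently higher than a real optimizer's (~95%); D0.1% (~104%) and
CI (1.2–1.3 after calibration) land in the clinically reported range.
Dose is stored for the full course; fraction dose × 25 recovers it
exactly.

## Evaluation conventions

* Cumulative DVHs at 0.05 Gy bins; D_p% by linear interpolation on the
  cumulative curve (sub-bin accuracy for D0.1% without keeping voxel
  doses); metrics agree with direct voxel sorting within one bin
  (oracle-tested).
* Percent-of-prescription metrics use the 45 Gy course prescription.
* Bowel constraints use the strict "<" convention: a patient mean exactly
  at 350/500 cm³ counts as a violation.
* The LOP reference-dose volume per patient is the selection-count
  weighted mean over library members (algebraically the per-fraction
  mean); online strategies use the plain mean of their per-fraction plans.
* Empty structures on an evaluation anatomy are flagged and excluded from
  coverage counts rather than propagated as zeros.

## Strategies

* **Library construction**: per interpolation (endpoints included), ITV =
  anisotropic expansion → encompassing CTV = ITV ∪ nodal CTV → PTV =
  isotropic 5 mm → dose. Members are labelled by interpolation percentage
  (0 = empty-bladder, 100 = full-bladder). Members also store the
  interpolated bladder and the bowel-bag-minus-organs masks the clinical
  optimizer would consume (bookkeeping only here).
* **Plan-of-the-day selection** ("best fitting plan" is not further
  specified clinically): the smallest-ITV member fully containing the
  daily low-risk CTV; if none contains it, the greatest covered fraction;
  ties toward the smaller ITV, then the lower label. This is standard
  plan-of-the-day practice and deterministic; selection by ITV (not PTV)
  coverage is the stricter of the two open readings.
* **Online replanning**: PTV = CTV_T_LR ⊕ 3 or 5 mm ∪ nodal CTV ⊕ 3 mm on
  the t0 anatomy.
* A per-patient `rebuild_week` flag regenerates the library mid-course
  (the repeat-CT events of clinical practice); off by default, and inert
  unless tumour regression is enabled (the anatomy model is otherwise
  week-independent).

## Statistics

Paired Wilcoxon signed-rank (zeros dropped; exact null for n ≤ 25 when
untied, else normal approximation with continuity correction),
tie-corrected Kruskal-Wallis, and OLS with a two-sided t-test on the
slope — all delegated to scipy behind the module surface, with
independent oracles (sign enumeration, hand rank formula, normal
equations) and type-I calibration checks (nominal 5% ± 2% at 2000 null
replicates) in the test suite. Paired differences are pooled per fraction
across patients (the reading consistent with per-fraction differencing);
no multiple-testing correction is applied, matching the original
analysis; α = 0.05. The V40 regression is reported with the orientation
"difference = V40(online) − V40(LOP)" recorded in the result, under which
a *negative* slope means the online benefit grows with the
library-strategy bowel dose.

## Numerical choices

* Distance transforms and dose are computed on padded bounding boxes
  (pad = shoulder + 6σ ≈ 40 mm); beyond it the dose is < 1e-8 Gy and is
  set to zero.
* Signed distance = EDT(outside) − EDT(inside); boundary voxels are never
  exactly zero.
* Rigid mask rotation uses nearest-neighbour resampling; the nodal-CTV
  setup rotation is instead applied analytically to the tube centreline
  (exact, no resampling loss).
* Sub-voxel margins are quantized away with a warning.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit integers; cohort members get seeds from `SeedSequence([seed, i])`
  reduced below 2³¹. Identical configurations produce byte-identical CSVs.

## Known limitations

* One anatomical archetype (anteverted uterus, fixed organ topology);
  no retroverted uteri, no hysterectomy variants.
* Motion is one-dimensional in parameter space (bladder fill); rectum and
  bowel are static between t0 and t1.
* The dose engine has no OAR-driven shaping, so absolute OAR doses are
  only comparable *between strategies*, and cohort-level absolute numbers
  (reference-volume reductions, violation counts) are smaller than the
  clinically reported ones, which depend on the unavailable patient
  anatomies.
* LOP libraries here span 2–8 members for plausible displacement ranges
  (clinically reported: 2–7); the upper end occurs for the largest
  simulated anteversion responses.
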
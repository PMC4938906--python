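# Methods

## The kinematic model

The foot (excluding sesamoids) is modelled as a rigid-body tree of 26 bone
segments rooted at the tibia: talus, calcaneus, navicular, cuboid, three
cuneiforms, five metatarsals and fourteen phalanges (the hallux has no
central phalanx). Each non-root segment connects to its parent by an
idealized joint:

| joint | type | DoF | angles |
|---|---|---|---|
| ankle (tibia–talus) | revolute | 1 | plantarflexion |
| subtalar (talus–calcaneus) | revolute | 1 | inversion |
| talonavicular, calcaneocuboid | spherical | 3 | plantarflexion, inversion, adduction |
| cuneonavicular 1–3 | universal | 2 | plantarflexion, adduction |
| tarsometatarsal 1–5 | universal | 2 | plantarflexion, adduction |
| metatarsophalangeal 1–5 | universal | 2 | plantarflexion, adduction |
| interphalangeal (9) | revolute | 1 | plantarflexion |

Total joint DoF: 1+1+3+3+6+10+10+9 = **43**. The distal joints deliberately
omit frontal-plane rotation: there is no room on the forefoot to place
enough markers to observe it, and sagittal/transverse motion dominates
there.

Frames and conventions: lab X anterior, Y medial (right foot), Z up; meters
and radians internally, degrees in all reports. At the neutral (all-zero)
configuration every segment frame is axis-aligned and each segment's origin
sits at its joint center. A joint rotates about 1–3 ordered unit axes fixed
in the parent frame, composed first-axis-first (intrinsic), with a per-DoF
sign making plantarflexion, inversion and adduction positive. The ankle
axis is mediolateral; the subtalar axis is inclined 42° in the sagittal
plane and 23° medially in the transverse plane (classical cadaver-derived
orientation). Both, like all geometry, live in the editable JSON template
and can be replaced.

### Template geometry

No CT-derived geometry ships with the package. `default_template()` builds
a synthetic nominal adult right foot (~28 cm heel to hallux tip) with
hand-set joint centers, a 43-marker protocol (6 shank markers, 3 heel, 12
midfoot/tarsal, 12 metatarsal, 14 toe markers), the 16 scan landmarks used
for scaling, and hand-placed inter-tarsal contact ellipsoids with 1–4 mm
clearance at neutral. Geometry is a model *parameter*: every algorithm in
the package is geometry-agnostic and validated on both this template and
toy chains.

## Rhythms (DoF coupling)

Ligamentous structures crossing several joints couple their motion into
functional units; the model expresses each such rhythm as a linear slaving
of one DoF to one or more masters, collected into the affine map

    q_full = C q_reduced + offset,  C ∈ R^(43×r)

where every row of `C` is either a unit selector (independent DoF) or a
coupling row (slaved DoF). Six rhythm groups ship by default (all
coefficients configurable; chained masters are resolved by substitution
when `C` is built, and cycles are rejected):

1. **IP flexion**: distal IP flexion of toes 2–5 = c·(proximal IP flexion), c = 1.
2. **MTP flexion**: MTP 2–5 flexion = c_k·(MTP 1 flexion), c_k = 1.
3. **Metatarsal transverse arch**: TMT k flexion (k = 2,3,4) interpolates the
   bounding rays, w_k·TMT1 + (1−w_k)·TMT5 with w_k = (5−k)/4 — a linear
   "arch height" model of the metatarsal heads.
4. **Tarsal transverse arch**: central / lateral cuneonavicular flexion
   interpolates medial cuneonavicular and calcaneocuboid flexion (weights
   2/3 and 1/3).
5. **Medial longitudinal arch**: medial cuneonavicular and TMT1
   flexion/adduction slaved to talonavicular flexion/adduction (c = 1).
6. **Lateral longitudinal arch**: TMT5 flexion = c·calcaneocuboid flexion, c = 1.

With all six active the tracked dimension is 25. The linear form with unit
default coefficients is a declared modelling choice: it satisfies the
qualitative anatomical couplings, keeps the inverse-kinematics problem
small and always-feasible (rhythms are *hard* constraints by construction,
not penalties), and exposes every coefficient as an explicit parameter for
pathology-specific variants. Nonlinear or data-learned rhythm forms are out
of scope.

## Inter-tarsal contact

Cuboid–navicular, cuneocuboid and the two intercuneiform articulations have
no idealized joint; to stop the solver from driving these bones through
each other, each tarsal bone owns one ellipsoid surface and four
articulating pairs carry a non-penetration rule.

**Signed separation** between two ellipsoids is defined as the minimum over
both surfaces of the signed distance from one surface's points to the other
surface: the gap when disjoint, minus the deepest surface penetration when
overlapping (for spheres, `|c1−c2| − r1 − r2`). It is symmetric and
rigid-motion invariant. Computation: point-to-ellipsoid distance is solved
exactly by bracketed root-finding on the standard characteristic function;
the surface minimization runs a deterministic multi-start (quasi-uniform
direction scan, BFGS descent from the best candidates plus the center-line
direction; warm-started across consecutive frames). Overlapping pairs get a
denser scan and a derivative-free polish because the interior distance
field is non-smooth along the medial axis. A fast exact disjointness test —
the algebraic separation condition that `det(λA + B) = 0` has two distinct
positive roots — screens pairs before any distance computation.

The rule enters the IK objective as a smooth one-sided quadratic penalty
`w·min(0, separation)²` (default weight 1e6), *lazily*: each frame is first
solved without it, the four pairs are screened, and only a frame whose
solution leaves a pair penetrating is re-solved with penalty residuals. The
penalty gradient uses the envelope theorem (contact points fixed in their
body frames), verified against finite differences. A post-solve check
reports all pairwise separations. Contact is kinematic only — no forces.

## Subject scaling (thin-plate spline)

A subject-specific model is obtained by warping the template with the
radial-basis interpolant fitted to 16 named surface landmarks (heel,
malleoli, navicular, metatarsal and toe-tip points) annotated on the
template and on the subject's foot scan. The kernel is the 3-D biharmonic
spline U(r) = r with a full affine term, solved from the standard bordered
linear system; the warp interpolates the landmarks exactly and reproduces
any affine map of them exactly (so pure scaling is recovered without
distortion). The 2-D kernel r² log r is available as a configuration
alternative.

Applying the warp: all points (joint centers, marker and landmark
attachments, ellipsoid centers) are carried through the warp in the
neutral-pose lab space and re-expressed in the warped frames; joint axes
rotate by the polar factor of the local warp Jacobian (computed
analytically), and ellipsoid shapes transform by the full local linear
action with SVD re-orthonormalization. A non-invertible Jacobian at any
joint center aborts scaling. Whether a non-affine warp should rotate joint
axes at all is genuinely open; transporting them by the polar factor
preserves unit-norm and orthogonality invariants and degrades gracefully to
the identity for uniform scaling, which is the declared choice here.
Landmarks are supplied as a JSON sidecar; no automatic landmarking of scan
meshes is attempted.

## Inverse kinematics

Per frame, the solver minimizes the weighted marker objective over the root
pose (6 DoF) and the reduced coordinates:

    min_{root, q_r}  Σ_i w_i ‖m̂_i(root, C q_r + offset) − m_i‖²  (+ contact penalty)

by Levenberg–Marquardt with analytic geometric Jacobians: each rotational
column is `axis × (marker − joint center)`, chained through `C`. Marker
weights default to 1 and are configurable per marker. Occluded (NaN)
markers are dropped from the sum for that frame — never interpolated inside
the solver — with an optional pre-filter that linearly fills occlusion gaps
of at most 5 frames. A frame needs at least ⌈(r+6)/3⌉ visible markers.
Convergence: step tolerance 1e-10, at most 100 iterations; a frame is
flagged converged when the projected gradient norm falls below 1e-8, and a
diverged frame is carried as NaN, never silently filled. Trials are solved
in time order, warm-started from the previous frame; the first frame starts
from the neutral pose, adequate near foot-flat. Global (all-frames)
trajectory optimization and soft-tissue-artifact modelling are explicitly
out of scope.

## Synthetic gait generator

The generator stands in for motion-capture recordings. Each independent DoF
follows a sum of up to three raised-cosine bumps over 0–100% stance
(amplitude in degrees, timing and width in % stance), anchored so the
heel-strike sample equals its specified value exactly; the root (tibia)
pose follows the same family (forward progression plus a shank roll of
~15° over stance). Default amplitudes are placed near mean stance-phase
ranges of healthy adult walking — ankle ~17°, subtalar ~12°, Chopart joints
6–15°, cuneonavicular arches 1–3°, first MTP ~40° flexion with the
characteristic late-stance dorsiflexion/push-off shape, toe IP joints
15–25° — with phases matching the usual qualitative pattern (midstance
eversion, late-stance inversion and push-off flexion). These are magnitude-
and-shape stand-ins, not digitized recordings.

Markers come from forward kinematics of the (subject-scaled) template plus
isotropic Gaussian noise (default SD 1 mm — the upper end of optical
tracking error for small foot markers) and contiguous random occlusion gaps
of 1–5 frames (default 2% of samples), both seeded. A cohort draws, per
subject: a uniform anatomical scale in [0.92, 1.08] with 2% per-axis
anisotropy (applied through the TPS scaling path via synthetic target
landmarks), a multiplicative amplitude factor (SD 10%) and a timing shift
(SD 2% stance) per DoF; each subject gets three trials with independent
noise. Defaults: 101 frames over a 0.7 s stance.

What the generator does **not** emulate: soft-tissue artifact (correlated,
motion-dependent marker displacement), marker placement error between
sessions, camera-visibility-driven (systematic) occlusion, and any
deviation of true foot kinematics from the rhythm model — generated motion
satisfies the rhythms exactly. Passing round-trip tests therefore certifies
the solver and pipeline, not the anatomical fidelity of the rhythms
themselves.

## Curve analysis

Angle curves are referenced to heel strike (the heel-strike sample is
subtracted, so every curve starts at 0°), resampled by linear interpolation
onto the canonical 201-point grid (0–100% stance in 0.5% steps), and
aggregated per DoF: trials are averaged within participant first; each
participant-mean curve yields a range of motion (max − min); the summary
reports mean/max/min RoM across participants and the extreme joint angles
over the participant-mean curves. Grid points whose native bracketing
samples are missing stay missing — gaps are explicit, never imputed.

**COV25** quantifies inter-participant variability for curves that
oscillate around zero (where the ordinary coefficient of variation
explodes): at each grid step where *all* participants have data, the sample
standard deviation (n−1) across participant-mean curves is divided by the
joint's full RoM (max − min over all participant-mean curves); COV25 is the
percentage of evaluated steps with ratio strictly below 0.25. 100 = low
variance, 0 = high variance. A zero-RoM joint makes the statistic undefined
and raises, rather than silently reporting 0. Computing the spread across
participant means (not pooled trials) matches the per-subject averaging of
the RoM summary; a per-trial alternative is available behind a flag
(`cov_threshold` is likewise configurable).

## The scaled-down study and what it shows

`footkin.pipeline.run_study` simulates a 6-subject × 3-trial cohort,
re-derives each subject's model from its landmarks through the TPS path,
solves every trial (contact penalty on, occlusion pre-filter at 5 frames)
and produces the summary table, alongside the identical statistics computed
from the generator's ground-truth curves. Problem sizes: 18 trials × 101
frames, 31 optimization variables per frame.

Recovery quality at the default noise level splits by observability, and
the split is itself informative. Sagittal ankle, subtalar, Chopart,
cuneonavicular, TMT and MTP angles are recovered with cohort-mean RoM
errors of a few percent. Two DoF classes are materially worse, for reasons
inherent to the marker protocol rather than the solver: (i) transverse
midfoot DoF with true RoM of 1–2° are smaller than the angle noise a 1 mm
marker error induces on 1–3 cm lever arms, so their recovered RoM is
dominated by noise; (ii) toe interphalangeal flexions are observed by a
single toe-tip marker ~2 cm from the joint (≈2.7° angle noise per frame at
1 mm marker noise), and the max − min RoM statistic is upward-biased by
noise extremes. Round-trip tests at zero noise recover all 43 DoF to
< 0.1°, isolating the effect as observability, not solver error. Users
interpreting transverse midfoot or toe-IP output on real data should expect
the same limitation.

## Numerical choices

- Rotation composition: Rodrigues per axis, first-axis-first; root rotation
  is Rz·Ry·Rx of the stored (rx, ry, rz).
- Ellipsoid fitting: algebraic least squares via the smallest singular
  vector of the centered/scaled design matrix; indefinite quadrics
  (hyperboloids) and rank-deficient point sets are rejected; needs ≥ 9
  points.
- Point-to-ellipsoid root finding: Brent on the characteristic function
  with a relative off-axis nudge (1e-9 of each semi-axis) so points on
  symmetry axes keep a valid bracket.
- TPS solve: dense bordered system; condition number above 1e12 (coplanar
  or duplicate landmarks) is rejected.
- LM tolerances: xtol 1e-10, ftol/gtol effectively off (1e-14), so the
  convergence flag is governed by the explicit projected-gradient check.
- Tie-breaks: the MTP coupling master is MTP1 (largest RoM of the
  candidates); arch interpolation weights follow ray position. Both are
  configuration, not hard-coded behavior.

## Known limitations

- Geometry, marker sites and rhythm coefficients are plausible stand-ins,
  not subject-derived values; all are editable in the template JSON.
- Rhythm forms are linear with default unit coefficients.
- Contact is non-penetration only; no contact forces, no mesh collision.
- C3D input is not supported; motion files are TRC (plain text) with a JSON
  event sidecar.
- No kinetics, no musculoskeletal layer, no statistical hypothesis testing
  on curves.
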
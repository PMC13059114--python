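# Methods

This note documents the model behind `phenotrack`, the parameter
choices, and the numerical and design decisions, in enough detail to
re-derive or challenge any of them.

## 1. Motion model and conventions

The assembloid is treated as a rigid body in the image plane: between
consecutive frames its content undergoes a translation `(dx, dy)` (px)
and a rotation `theta` (deg) about a pivot. Deformation, growth and
out-of-plane motion are *not* modeled; they appear as residual error.

A `RigidTransform` maps a point `p` (x, y; y points down) to
`R(theta) (p + d - c) + c` — translate, then rotate about center `c`.
Positive `theta` rotates +x toward +y. Composition `A.then(B)` means
"A first, then B" and composes the translation as
`d = d_A + R(theta_A)^T d_B`. For a stack, `pair[k]` is the residual
motion between the *corrected* frame k−1 and frame k, and
`cumulative[k] = pair[k].then(cumulative[k-1])` carries frame-0 content
onto frame k; applying `cumulative[k].inverse()` to frame k returns it
to the frame-0 pose. Before any estimation, the frame-0 assembloid
centroid is shifted (integer pixels, recorded as `recenter_shift`) to
the image center so the rotation pivot has maximal clearance.

## 2. Segmentation

The working grayscale image (by default the brightfield channel) is
smoothed (Gaussian, sigma 2 px), thresholded (Otsu by default), and the
largest connected component at least `min_area_px` = 1000 px² is kept.
Its convex hull defines the assembloid mask; the centroid of the filled
hull is the recentering target, and the hull radius sizes the polar
band used for rotation. The hull deliberately fills concavities: the
rigid estimate should follow the body, not surface indentations.

## 3. Translation: template matching

* `n_templates` = 6 square templates of `template_size_px` = 64 px are
  chosen inside the mask, eroded by half the template diagonal + 1 px so
  a template can never sample background, greedily maximizing local
  variance subject to pairwise center separation ≥ template size.
* Each template is matched against a `search_window_px` = 48 px
  neighborhood of the moving frame using zero-normalized
  cross-correlation (skimage `match_template`). Matches scoring below
  `score_floor` = 0.5 are discarded; if every template fails, the pair
  is abandoned (`RegistrationError`).
* The *median* of the per-template displacements is the estimate:
  robust to a minority of templates landing on ambiguous texture.
* Subpixel refinement fits a quadratic through the score at the peak
  and its two neighbors per axis. An exact-match gate skips the fit
  when the peak score is within 1e-9 of a perfect match, so a pure
  integer shift is returned exactly (the quadratic would otherwise add
  a spurious fraction from interpolation noise).

## 4. Rotation: polar region matching

Rotation about the center becomes a horizontal (angular) shift after
polar unwrapping. The annulus between 25% and 95% of the hull radius
(inner rows are angularly degenerate; the rim mixes with background) is
unwrapped at `bin_deg` = 0.25°/column with bilinear sampling. The band
is tiled into `n_regions` = 40 regions (4 radial rings × angular
tiles). For each region the normalized squared difference

    NSD(k) = sum((T - I_k)^2) / sqrt(sum(T^2) * sum(I_k^2))

is scored over integer column offsets k up to `max_search_deg` = 10°;
regions whose best score exceeds `score_ceiling` = 0.3 are dropped
(lower NSD is better). Ties resolve toward the smallest |offset|. The
*circular median* of the surviving per-region angles, times `bin_deg`,
is the rotation estimate. NSD is written out by hand because its exact
form (including the geometric-mean normalization) is the primitive
being implemented; translation ZNCC, by contrast, reuses skimage.

## 5. Iterative refinement

Per pair, a damped fixed-point loop alternates: (1) translation,
(2) rotation about the updated center, (3) translation again — each
update scaled by `damping` = 0.5 before being composed into the
accumulated transform. The trailing translation step matters because a
rotation update changes where template content lands; ending an
iteration on a stale translation would slow convergence. The loop stops
when one full iteration's updates fall below `conv_tol_px` = 0.5 px and
`conv_tol_deg` = 0.1°, or at `max_iterations` = 15. Damping trades a
few extra iterations for stability: undamped alternation can oscillate
when translation and rotation errors alias into each other.

Across a stack, each pair estimate is *seeded* with the previous
cumulative transform, so the matcher only resolves the small
frame-to-frame residual rather than the full accumulated motion — this
keeps the search windows small and prevents error accumulation from
re-estimating large motions. A failed pair logs a warning and carries
the identity residual (i.e. the previous cumulative pose) rather than
aborting the stack. An optional 3-point median filter over the pair
rotation series (`smooth_theta`, off by default) suppresses isolated
outliers at the cost of genuine single-frame jerks.

## 6. FUCCI detection, phase calling, linking

* Nuclei are detected on the sum of the red and green channels with a
  Laplacian-of-Gaussian blob detector (sigma 2–5 px, threshold 0.02),
  then each center is refined by a 3×3 intensity-weighted centroid.
  Per-nucleus red/green intensities are mean values over a disc of
  radius `max(1, sqrt(2)·sigma)`.
* The hue maps the red:green balance to a 0–60° scale: pure red → 0,
  balanced → 30, pure green → 60 (half-angle form of the usual RGB hue,
  restricted to the red–green sector). Phase thresholds: hue < 25 → G1,
  25–45 → S, > 45 → G2M. Detections whose total intensity falls below
  `intensity_floor_frac` = 5% of the stack's dynamic range are called
  UNKNOWN rather than given an unreliable hue.
* Linking is greedy nearest-pair per frame with gap closing: a track
  may skip up to `max_gap` = 2 frames, with the distance budget scaled
  by the gap length (base `max_link_dist_px` = 30). Tracks shorter than
  2 detections are dropped. Greedy matching is transparent and, at the
  nucleus densities the hard-core generator produces, empirically
  lossless (link accuracy 1.0 on the default scene); a global assignment
  solver was judged not worth the opacity.

## 7. Migration metrics and cohort statistics

Per trajectory (positions converted to µm by `pixel_size_um`,
default 1.3): path length (sum of step lengths), net displacement
(first to last point), convex-hull area CHA (shapely; 0 for < 3 or
collinear points), and dominant phase (modal call ignoring UNKNOWN,
ties resolved toward the later-occurring phase). Cohort ranking sorts
by descending CHA (ties by cell id for determinism) and reports the
G2M:G1 count ratio in the top-N and bottom-N cells; the ratio is `None`
(undefined), not infinity, when the set contains no G1 cell, and the
summary flags when N exceeds half the cohort so the sets overlap.
Infiltration % is the fraction of a region mask covered by
above-threshold tumor signal. Group comparison is the classic pooled-
variance two-sample Student t-test (scipy `ttest_ind`, equal_var);
identical zero-variance groups return t = 0, p = 1 instead of NaN.

## 8. Synthetic ground truth

The generator scripts everything the pipeline later estimates:

* **Texture:** band-pass filtered Gaussian noise (feature band 8–32 px)
  on a disc (radius 150 px in a 512² frame by default), soft 2 px rim.
  Band-pass texture gives the matchers realistic mid-scale features —
  white noise would make template matching trivially sharp, flat discs
  impossible.
* **Motion:** a bounded reflected random walk for the disc center
  (per-pair |dx|,|dy| ≤ `t_max_px` = 6) and rotation increments
  |dtheta| ≤ `r_max_deg` = 4 (5 in the accuracy benchmark).
* **Cells:** 40 nuclei with a 10 px hard core (nuclei cannot overlap)
  and ≥ 16 px initial spacing, random walks (step sigma 2 px) confined
  to 85% of the disc radius, rendered as Gaussian spots (sigma 2.5 px,
  peak 60% of dynamic range) colored by scripted phase: G1 = red,
  S = red+green, G2M = green. Phases either cycle through scripted
  G1/S/G2M sojourn ranges or stay static. In `phase_coupled` motion
  mode, G2M cells step `g2m_speed_factor` = 2× farther than G1 cells
  (S intermediate) — the condition used to verify the ranking contrast.
* **Rendering:** uint16 at a dynamic range of 60000 with 2% additive
  Gaussian noise. Scene randomness and render noise use separate
  seeded streams so the same scene can be re-rendered identically.
* Truth is exported in the registration module's own conventions
  (`truth_pairs`, `truth_cumulative`, registered cell positions), so
  estimator output is compared transform-to-transform without any
  re-derivation in the tests.

What the generator does *not* emulate: deformation or growth during the
movie (a `growth_rate_px` stress knob exists but defaults to 0),
photobleaching, uneven illumination, cell division/apoptosis, or
out-of-focus motion. Conclusions about robustness to those effects
cannot be drawn from the synthetic assay.

## 9. Butterfly state projection

Each cell carries four signature scores (OPC, NPC, AC, MES) plus two
cycle scores (G1/S, G2/M). With `D = max(OPC,NPC) − max(AC,MES)`:

    X = log2((OPC − NPC) + 1)  if D > 0      (progenitor branch)
        log2((AC − MES) + 1)   if D < 0      (differentiated branch)
    Y = sign(D) · log2(|D| + 1)
    CCS = G1/S + G2/M

The plain form `Y = log2(D + 1)` is undefined for D ≤ −1; the signed
form above agrees with it for D ≥ 0, mirrors it for D < 0, and keeps
`sign(Y) = sign(D)` everywhere. `D = 0` maps to the origin. A
non-positive X log argument is reported as an input error naming the
offending score pair. Signature scoring itself (gene-set enrichment) is
out of scope; the module consumes a score table.

## 10. Acceptance criteria

`tests/test_acceptance.py` contains one test per criterion; the
headline figure is independently recomputed by
`scripts/acceptance.py --seed <int> --out <path>`.

1. **Pairwise rotation accuracy:** median |theta error| < 0.5° over
   ≥ 30 independent synthetic pairs (rotations ≤ 5°, translations
   ≤ 6 px/axis, 2% noise, 150 px disc). Measured: 0.074° (seed 1).
2. **Convergence:** mean refinement iterations ≤ 12 per pair on the
   default 30-frame scene. Measured: ≈ 4.4, all pairs converged.
3. **Translation:** integer shifts recovered exactly; subpixel shifts
   within 0.5 px.
4. **No drift:** cumulative rotation error at frame 30 < 1.5°;
   registered centroid drift < 3 px on every frame.
5. **Metric oracles:** CHA matches an independent monotone-chain +
   shoelace implementation to 1e-9 on 100 random point sets; the t
   statistic matches its closed form to 1e-9.
6. **Tracking fidelity:** recall, link accuracy and phase accuracy all
   ≥ 0.95 on the default scene. Measured: 1.0 / 1.0 / 1.0.
7. **Ranking contrast:** in a phase-coupled scene the top-N G2M:G1
   ratio exceeds the bottom-N ratio (N = half the cohort).
8. **Butterfly reference points:** hand-computed coordinates reproduced
   on all three D branches.

## 11. Limitations

* The rigid model ignores deformation; soft or growing assembloids will
  show residual motion that pollutes per-cell tracks.
* Rotation relies on internal texture: a featureless or radially
  symmetric body yields no usable regions (reported, not guessed).
* The greedy linker can swap identities when nuclei pass within the
  match distance of each other in consecutive frames.
* Phase calling assumes two-channel FUCCI with a monotone red→green
  progression; sensor variants with different kinetics need re-tuned
  hue thresholds (`phase.t_g1s`, `phase.t_sg2m`).
* All validation is synthetic; real-microscope effects (illumination
  drift, debris, z-motion) are untested by construction.
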
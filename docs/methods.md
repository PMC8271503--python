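# Methods

## Problem and model

A fixed monocular camera watches a region of interest (ROI) of ground-plane
area A0 (m²). Downstream of any pedestrian detector, each frame yields a set
of labeled, scored bounding boxes. The pipeline answers three questions per
frame: how many pedestrians n are in the ROI, which pairs are closer than
the minimum distance d_c (default 2 m), and whether the scene is so dense
that violations are to be expected.

**Ground-point extraction.** A pedestrian's position is the midpoint of the
bottom edge of their bounding box — the feet, which lie on the ground plane
z = 0. The box centroid is available as a comparison variant
(`pose_mode="center"`); it sits roughly a half body-height above the ground
and back-projects with a systematic depth bias, which is why the bottom
anchor is the default.

**Bird's-eye-view mapping.** Image pixels and ground-plane meters are
related by a 3×3 projective matrix M (world→image). Positions are recovered
by the inverse map, p_bev = M⁻¹ p_im in homogeneous coordinates. M is
calibrated from ≥4 surveyed key points by the normalized direct linear
transform: both point sets are Hartley-normalized (centroid 0, mean radius
√2), the 2n×9 linear system is solved by the smallest right singular
vector, and the result is denormalized and scaled so m₃₃ = 1 (unit
Frobenius norm with a positive leading sign when m₃₃ ≈ 0). No robust
fitting is used: key points are operator-selected, not detector output.
Degenerate configurations (collinear/coincident points) are detected via
the gap in the singular spectrum and reported as calibration failures. A
point whose homogeneous image has |w| < 10⁻¹²·‖M‖ lies on the horizon of
the map and is reported unmappable rather than silently returned; during
frame analysis such a detection is dropped with a warning.

**Per-frame statistics.** After ROI filtering (boundary-inclusive
point-in-polygon, so a pedestrian standing exactly on the border does not
flicker in and out), the frame is summarized by

- n and the social density ρ = n / A0 (1/m²); A0 defaults to the polygon's
  shoelace area, with a user override since the area may be surveyed
  independently;
- all n(n−1)/2 pairwise Euclidean distances, in lexicographic pair order;
- the violation count v: unordered pairs with d < d_c. The literal double
  sum over ordered pairs counts every violating pair twice; that convention
  is available (`pair_counting="ordered"`) but the unordered count is the
  interpretable default. The comparison is strict by default, inclusive as
  an option;
- the violation ratio r_v = v/n (NaN when n = 0) and d_avg, the mean over
  pedestrians of each one's nearest-neighbour distance (NaN when n < 2).
  NaNs propagate to evaluation, where such frames are skipped, never
  imputed as zeros.

**Control signals.** Two instantaneous binary outputs per frame: c1 = 1
when any pairwise distance is ≤ d_c (inclusive — a pair at exactly the
minimum distance earns a cue even though the strict count does not register
a violation; the asymmetry between the two printed conventions is kept
deliberately and both are configurable), and c2 = 1 when ρ > ρ_c strictly.
No latching or hysteresis: signals are pure functions of the frame.

**Critical social density.** ρ_c = 0 trivially guarantees no violations but
is useless; the useful quantity is the largest density still statistically
consistent with a violation-free frame. Per-frame pairs (v_k, ρ_k) are
pooled — all frames with a defined density, including v = 0 frames, at
native frame rate — and fitted by OLS with ρ as the response:

    ρ = β₀ + β₁ v + ε,  ε ~ N(0, σ²).

ρ_c is the lower bound of the two-sided 95% prediction interval for a new
observation at v = 0,

    ρ_c = max(0, β₀ − t_{n−2,0.975} · s · √(1 + 1/n + v̄²/S_vv)),

with s² = RSS/(n−2). The t-based single-observation interval is the
standard choice under the normal-error assumption; the fit and interval are
implemented in closed form and cross-checked in the test suite against
statsmodels' OLS prediction machinery as an independent oracle. The clamp
at zero matters: when the per-frame scatter of ρ at v = 0 is wide relative
to β₀ (as it is for the default synthetic scene), the lower band edge is
negative and the estimator honestly reports ρ_c = 0 — no nonzero density
can be certified violation-free at that level. The adjusted Fisher–Pearson
skewness of the ρ series is attached as a normality diagnostic (values near
zero support the error model). The interval level defaults to 0.95 and is
linked to the violation-probability budget U0 = 1 − PCI² by default, but
both are independently configurable.

A known tension in the derivation: a two-sided 95% interval puts 2.5% of
probability below the lower bound, not 5%; the implementation follows the
two-sided interval and records the level explicitly in every report.

## Evaluation protocol

Predicted and ground-truth per-frame tables are aligned by frame id.
Reported metrics: MAE of d_avg (meters), MAE of both r_v and v (the ratio
and the raw count are separate, deliberately — reporting both removes any
ambiguity about which is meant), and frame-level violation *detection*
(a frame is positive iff v > 0) as a confusion matrix with precision,
recall and accuracy in percent, rounded to two decimals.

## Synthetic scenes

The generator emulates the statistical structure of crowded public spaces
(a town square, a mall concourse) without rendering anything:

| parameter | default | why |
|---|---|---|
| ROI | 20 m × 20 m (A0 = 400 m²) | scale of a monitored plaza |
| λ(t) | sinusoid, 8 ± 6 peds, 60 s period | ebb and flow of foot traffic; densities 0–0.035 /m² bracket intercepts seen in real crowd footage |
| group fraction | 0.5 | companion groups are roughly half of public-space pedestrians |
| group size / spread | mean 3, σ = 0.7 m | pairs-to-small-groups at conversational distance; induces violations at moderate density |
| d_c | 2 m | the common distancing rule |
| pixel noise | 2 px on box corners | sub-pixel to few-pixel detector jitter |
| miss prob / FP rate | 0.05 / 0.2 per frame | occlusion-like misses, occasional spurious boxes |
| camera | 20 m square → 1920×1080 trapezoid, 29–60 px/m | oblique surveillance view; box height affine in image row |

Counts are Poisson(λ(t)); singletons are uniform in the ROI, grouped
pedestrians are Gaussian around uniform cluster centers with out-of-ROI
members rejection-resampled (so A0 semantics stay exact). Frames are
independent — every downstream statistic is per-frame, so temporal dynamics
would add cost without adding coverage. Randomness flows from one seed,
split into a *scene* stream and a *detector* stream, so the same seed gives
identical ground truth under different detector-noise settings (the
noise-sweep comparisons are paired).

What the generator does **not** emulate: occlusion geometry (misses are
independent coin flips, not density-dependent), detector score calibration,
tracking identity, non-planar ground, lens distortion, and temporal
correlation of crowding. Passing tests therefore demonstrate correctness of
the geometry, counting and inference machinery under a faithful error
model — not detector robustness on real video, which requires annotated
footage and a trained detector.

## Numerical choices and problem sizes

- Homography equality is tested after normalization (m₃₃ = 1), making
  recovery-up-to-scale a plain matrix comparison; noise-free DLT recovery
  is exact to ~10⁻¹⁵ relative error, round trips to ~10⁻¹⁴ m.
- An exactly linear (v, ρ) relation leaves only rounding noise in the OLS
  residuals; RSS below 10⁻²⁴ of the total sum of squares is snapped to
  zero so the zero-noise limit collapses the prediction interval cleanly.
- Simulation-based tests use 500 frames (statistics stabilize well before
  that: a Poisson mean over 500 frames has relative SE < 2%) and 500
  replicates for interval-coverage experiments (binomial SE ≈ 1%, against
  an acceptance band of ±2%). Fixed seeds throughout; the acceptance
  script derives all stream seeds from its `--seed` argument.
- Score threshold default 0.5 with an inclusive ≥ comparison; pedestrian
  label default `"person"` — both configurable for other detector
  vocabularies.

## Known limitations

- The bottom-edge anchor assumes visible feet; heavy occlusion biases the
  mapped position downward in the image, i.e. toward the camera.
- OLS ignores serial correlation of consecutive frames; for high-FPS
  streams the prediction interval is approximately right but the nominal
  level is not exact. Subsampling frames is a reasonable mitigation and is
  left to the caller (native rate is the default).
- ρ_c = 0 is a legitimate output, not an error: it signals that the scene's
  density–violation scatter is too wide to certify any safe density at the
  requested level.
- The violation count is quadratic in n per frame; fine for surveillance
  crowd sizes (n ≲ 10³), not for stadium-scale scenes.
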
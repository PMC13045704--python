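# Methods

## The measurement model

`spinecobb` treats the spine on a coronal radiograph as a single smooth
curve rather than a stack of vertebrae. The input is a binary mask of
the whole spine; the model is the per-row centroid curve x(t) of that
mask, smoothed by one least-squares polynomial x = f(t). All quantities
of clinical interest are functionals of f:

* **tilt** at a point is the slope f′(t) (the tangent of the angle the
  spine makes with the vertical image axis);
* a **scoliotic curve boundary** is an inflection, f″(t) = 0 with a sign
  change — where a left-bending arc hands over to a right-bending one;
* a **vertebral direction** is θ = arctan(mean of f′ over a tolerance
  window), in degrees, confined to (−90°, 90°);
* a **Cobb angle** is the absolute difference of two adjacent vertebral
  directions, and the largest one in an image is the *main* angle that
  grades severity.

Assumptions this rests on:

* the mask covers one connected spine, oriented roughly top-to-bottom in
  the raster (each image row crosses the spine once); masks that are
  fragmented are rejected, masks with missing rows are bridged by the
  polynomial fit and flagged ("gappy") when more than 5% of the rows in
  the spine's span are empty;
* pixels are square when geometry is computed. Masks carrying anisotropic
  spacing metadata are resampled (nearest-neighbour, to the finer
  spacing) before the centerline is extracted, because slopes — hence
  every angle — are meaningless in an anisotropic frame. Without
  spacing metadata, pixels are assumed square and a warning is logged;
* a polynomial of degree ≤ 10 can follow the centerline. Clinically a
  spine shows at most three or four alternating curves, well within the
  four sign changes a degree-10 polynomial's second derivative affords.

## Parameters, defaults, and why

| parameter | default | meaning |
|---|---|---|
| `tolerance` (L_t) | 0.15 | window length as a fraction of the containing interval; the direction is the slope averaged over this window rather than a single tangent, mimicking how readers align to endplates rather than the geometrically steepest point. Calibratable against a reader panel. |
| `degree` | 10 | polynomial degree of the centerline fit; fixed, no model selection, so the pipeline is deterministic. |
| `normalized_length` | 572 samples | every centerline is resampled onto this grid before fitting so one smoothing configuration serves all image resolutions. The lateral coordinate is scaled by the same affine factor, which preserves dx/dt exactly; angles are therefore invariant to the normalization (verified to < 1° under 2× rasterization). |
| `max_interval_frac` | 0.5 | an inflection-free interval longer than this fraction of the domain is split at its midpoint, recursively: a long gentle drift still deserves a measured direction. |
| `grid_step` | 0.25 samples | density of the deterministic search grids (inflection scan, tilt argmax). Inflection roots are refined by bisection to `grid_step`/100. |
| severity thresholds | 10/25/45/60° | half-open bins [0,10), [10,25), [25,45), [45,60), [60,∞) for levels 0–4; exactly 10° grades level 1, consistent with ≥ 10° defining scoliosis. |
| ICC variant | ICC(2,1) | two-way random effects, absolute agreement, single rater: raters are a sample of possible readers and systematic offsets should count against agreement. ICC(2,k) and ICC(3,1) are selectable. |
| kappa weighting | unweighted | linear/quadratic weights available for the ordinal severity scale. |

## Numerical choices

* The degree-10 Vandermonde system on t ∈ [0, 571] is numerically
  singular, so the fit is conditioned on [-1, 1] internally; derivatives
  are evaluated analytically from the conditioned coefficients.
* Tilt maximization uses |f′|, not f′: a leftward tilt is as tilted as a
  rightward one. Ties on the search grid break toward smaller t (more
  superior), and the main-angle tie breaks toward the most superior pair.
* Tolerance windows keep their exact length L_t × interval at interval
  edges: an overflowing window is translated inside, never shrunk.
  Because the averaged derivative telescopes, the direction reduces to a
  difference quotient (f(t_hi) − f(t_lo))/(t_hi − t_lo) — no quadrature.
* Inflections closer than max(`grid_step`, 1% of the domain) to each
  other or to the domain ends are discarded. A degree-10 fit can wiggle
  at the domain boundaries and emit a spurious near-boundary inflection;
  the resulting sliver interval would be far shorter than a vertebra
  (~34 of 572 samples for a typical 17-vertebra span) and merely
  duplicates the boundary peak, so a minimum anatomical interval of ~6
  samples is enforced.
* Tolerance calibration compares candidate objectives with a 1e-9
  absolute tolerance; objectives closer than that are ties and the
  smallest L_t wins (float equality would make the tie rule dead code).
* Cobb values are reported unsigned in [0, 180) with no minimum-angle
  filter: small secondary angles are retained deliberately.
* Report JSON rounds all floats to 9 decimals, which makes repeated runs
  byte-identical across platforms.
* The measurement engine contains no randomness at all; seeds exist only
  in the synthetic-data generator and the bootstrap.

## The phantom generator and what it does (not) show

`phantoms.py` renders bands of foreground around an analytic centerline
(constant, linear, single half-sine arch, sinusoidal S-curve, or cubic
spline) with optional half-width jitter and interior holes. Because the
centerline family is closed-form, ground truth is too: for an S-curve of
amplitude A and period T the peak slope is 2πA/T, so the Cobb angle
between adjacent opposite crests is 2·arctan(2πA/T), and the suite
builder inverts this to place phantoms in chosen severity bins.
`analytic_cobb` mirrors the partition-and-argmax semantics (including
the midpoint split of inflection-free intervals, without which an arch
phantom would yield no angle at all) entirely on the analytic curve — it
shares no code path with the pipeline and serves as the independent
oracle in the tests and the acceptance script.

Noise enters only through the half-width (boundary jitter) and interior
holes, never through the centerline itself, so the analytic truth stays
exact in expectation. The simulated reader panel models rater j's value
for case k as truth_k + b_j + e_jk with b_j ~ N(0, bias_sd²) and
e_jk ~ N(0, noise_sd²), clipped at 0°; the defaults (7 readers,
noise_sd 3°, bias_sd 1°) reflect a panel of experienced readers whose
pairwise differences sit in the few-degree range reported for manual
Cobb measurement.

What phantoms deliberately do not emulate: ribs, pelvis and shoulder
superposition, vertebral texture, rotation/projection effects, exposure
variation, or segmentation failure modes of a real detector. Passing the
phantom suite shows the *geometry engine* is correct and stable; it says
nothing about how a particular segmentation backend behaves on clinical
radiographs, which is exactly why the backend is pluggable and scored
separately (Dice).

## Problem sizes used

The test suite and acceptance script run entirely on generated data:
20 straight bands and 30 curved phantoms (640×320 px, severity levels
0–4, six per level), 50 random polynomial curves for the brute-force
tilt check, 200-case simulated panels for the stochastic agreement
statistics, and a 6-case calibration set. These sizes keep the whole
battery in the seconds range while leaving the stochastic checks with
comfortable margins (e.g. the pairwise-difference closed form is tested
at ±15% where the simulation sits within ~2%).

## Known limitations

* The t-axis is the image row, not arc length; for extreme curvatures
  (|θ| approaching 90°) a row may cross the spine twice and the per-row
  centroid model degrades. Severities up to level 4 (~80°) are covered
  by the test suite; beyond that the single-valued-function assumption
  weakens.
* Degree-10 smoothing bounds the number of representable curve
  reversals; a grossly fragmented or wildly oscillating mask will be
  over-smoothed rather than rejected (the validation report flags such
  masks instead).
* The tolerance window biases directions slightly toward zero relative
  to the pointwise tangent (by construction — that is its purpose); with
  L_t = 0.15 the resulting main-angle bias on sinusoidal phantoms is
  about 1–2° at high severity, shrinking to < 0.05° as L_t → 0.
* End vertebrae are not named anatomically (no T1…L5 labelling), and
  3-D effects (vertebral rotation, sagittal balance) are out of scope:
  the measurement is purely coronal-plane 2-D, as in routine practice.
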
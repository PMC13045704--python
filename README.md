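# spinecobb

Fully automated Cobb angle measurement for scoliosis assessment on PA/AP
spine radiographs, starting from a binary spine segmentation mask — plus
the multi-reader agreement statistics used to validate such a tool and a
synthetic phantom generator with analytic ground truth.

## Who this is for

The Cobb angle — the angle between lines parallel to the endplates of the
two most tilted vertebrae of a spinal curve — is the standard quantifier
of scoliosis; ≥ 10° defines the condition, and the thresholds 25°/45°/60°
drive management decisions. Manual measurement is slow and shows large
inter-reader variability. `spinecobb` measures every Cobb angle in an
image from the *global geometry of the spine* rather than per-vertebra
landmarks, and renders an auditable overlay. It is aimed at researchers
building or validating automated scoliosis measurement: the segmentation
step is a pluggable backend (any detector honoring a small contract), and
everything downstream of the mask is deterministic, inspectable code.

## Method

Given a binary spine mask:

1. **Centerline** — for every mask row, the centroid of the foreground
   columns gives samples x(t) (t = row index, superior → inferior).
2. **Normalization** — the centerline is resampled to a fixed 572 samples,
   with the lateral coordinate scaled by the same affine factor so slopes
   dx/dt (hence all angles) are preserved across resolutions.
3. **Smoothing** — a single least-squares polynomial fit x = f(t) of
   degree ≤ 10 (default 10), conditioned internally on [-1, 1].
4. **Breakpoints** — the domain is partitioned at geometric inflections
   (sign changes of f″, refined by bisection) and, recursively, at the
   midpoints of intervals longer than half the domain.
5. **Tilted points and directions** — in each interval [x_i, x_{i+1}] the
   most tilted point maximizes |f′(t)|. A tolerance window of length
   L_t · (x_{i+1} − x_i) (default L_t = 0.15) is centred on the peak and
   the vertebral direction is the window-averaged slope,

       θ = arctan( (1 / (t_hi − t_lo)) ∫ f′(t) dt )
         = arctan( (f(t_hi) − f(t_lo)) / (t_hi − t_lo) ) ∈ (−90°, 90°).

6. **Cobb angles and severity** — each adjacent pair of directions yields
   D_k = |θ₁ − θ₂|; the largest D_k is the *main* angle and grades
   severity into levels 0–4 by the bins [0,10), [10,25), [25,45),
   [45,60), [60,∞).

The tolerance L_t can be calibrated against a reader panel by minimizing
Σ_k |D_k − R̄_k| over a candidate grid (`calibrate_tolerance`). The
agreement suite implements the deviation statistics D̄_mean / D̄_median,
the pairwise reader difference, the reader-vs-algorithm difference, MAD
matrices, Pearson correlation, ICC (two-way random effects; ICC(2,1)
absolute-agreement by default), Cohen's kappa, and the severity-grading
classification metrics.

## Worked example

Generate a synthetic S-shaped spine whose true main Cobb angle is 40.0°
by construction, then measure it:

```python
import spinecobb as sc
from PIL import Image

spec = sc.spec_for_angle(40.0, family="s_curve", seed=4)
image, mask = sc.rasterize(spec)
sc.save_mask(mask, "spine_mask.png")
Image.fromarray(image.pixels, mode="L").save("spine.png")
print(sc.analytic_cobb(spec).main)    # 40.0  (closed-form ground truth)
```

```bash
spinecobb measure --mask spine_mask.png --image spine.png \
                  --out report.json --overlay overlay.png
```

The run logs `measure: 3 angles, main 39.34 deg, severity 2` and the JSON
report contains:

```
main_angle_deg   39.338580336
severity_level   2
angles           38.7   0.0   39.3 (main)
thetas           -19.34  19.35  19.34  -20.00
```

Reading this: the pipeline found four tilted points with alternating
directions of about ±19–20°, so the two scoliotic curves measure ≈ 39°
each (the tiny 0.0° angle joins two tilted points on the same crest of
the S). The main angle 39.34° sits 0.66° from the analytic truth —
within the pixel-level accuracy expected of a rasterized 640×320 phantom
— and grades severity level 2 (moderate, 25–45°). `overlay.png` shows
the fitted centerline, a direction segment through each tilted point,
and every angle labelled, the main one in orange with a star.

The same battery is available from Python (`sc.measure`,
`sc.analytic_cobb`, `sc.icc`, ...) and via the `synth`, `agree` and
`calibrate` subcommands; `spinecobb --help` lists them.

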
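# Methods

## Measurement model

A trans-illuminated whole mount is an absorbance image: carmine-bound
epithelium attenuates light, the cleared fat pad transmits it. Two measures
are derived per specimen, inside an operator-traced AOI polygon:

- **Area method.** A binary dense mask (epithelium) and its complement within
  the AOI (interductal fat pad) are built by gray-level thresholding after
  illumination correction. Area = set-pixel count × `cm_per_pixel²`. Because
  the two masks partition the AOI, `A_epi + A_fat = A_total` holds exactly.
- **Volumetric method.** Per-pixel optical density
  `OD(g) = min(od_max, log₁₀(255 / max(g, 1)))` summed over a mask gives ΣOD,
  proportional (under Beer–Lambert assumptions) to the amount of stained
  tissue in the light path. `od_max = 2.4 ≈ log₁₀(255)` is the dynamic range
  an 8-bit sensor can express; gray 0 is routed through `max(g, 1)` and the
  clamp so that `OD(0) = OD(1) = od_max` rather than diverging. A linear ramp
  `OD(g) = od_max·(255−g)/255` is selectable for instruments whose OD
  calibration was a straight lookup table; the logarithmic form is the default
  because it is standard transmittance densitometry and explains the 0–2.4
  range. ΣOD is always measured on the lymph-node-excised grayscale image
  *before* flattening and contrast enhancement — both rescale gray levels and
  would destroy the photometric interpretation; this is also the only choice
  under which the fat pad retains the non-zero ΣOD it empirically has.

Density percentages are `100·part/total` per specimen; a zero denominator
(empty AOI) reports 0 with an explicit `density_undefined` flag so batch runs
complete. Group densities default to mean-of-ratios (average the per-specimen
percentages); ratio-of-means is available via `density_convention`.

## Pipeline stages and the choices behind them

**Grayscale.** ITU-R 601 luminance, rounded half up. Idempotent on grayscale
input.

**Lymph-node excision.** A 4-connected flood fill from an operator seed with
absolute gray tolerance (default 32) selects each node; selected pixels are
set to white so they contribute zero dense area and zero ΣOD. Excision
happens before any filtering so the node's darkness cannot leak into the
background estimate.

**Flattening.** Background = grayscale closing with a disc of radius `r`
followed by a mean filter of size `2r+1`; output = `255·img/background`,
clipped. Closing of a bright-background image removes dark structures
narrower than the disc, so `r` must exceed the widest duct; the default
`r = min(height, width)/8` satisfies that by a wide margin while still
tracking illumination-scale shading. Division (rather than subtraction) is
used because uneven trans-illumination is multiplicative in transmitted
intensity. The closing uses a decomposed disc footprint, keeping the filter
near-linear in pixel count. The exact algorithm of the commercial "flatten"
filters is proprietary; this construction is this package's own documented
choice and is validated behaviourally (a 60-gray-level synthetic gradient
changes measured density by well under 3 percentage points).

**Contrast enhancement.** Linear stretch mapping the `f` and `1−f` gray-level
quantiles to 0 and 255. The *operation* default is `f = 0.01`; the *pipeline*
default is `f = 0` (pure min–max). Rationale: a fixed saturated fraction
assumes the stained tree occupies more than that fraction of the frame. A
rudimentary gland can occupy a fraction of one percent, in which case the
lower 1 % quantile falls inside the fat-pad distribution and the stretch
maps a large share of the fat below any sensible threshold. Anchoring at the
observed extremes never inverts, and saturation of the background is instead
delegated to the threshold's guard band (next paragraph).

**Thresholding.** Dense = AOI pixels with enhanced gray ≤ `upper`; non-dense
= the rest of the AOI. Stained epithelium is dark, so dense is the lower
gray range; `upper = 255` is rejected because it would make the non-dense
mask empty by construction. The operation default is `upper = 254`
("anything not saturated white"), which presumes an enhancement that drives
the fat pad to full saturation. The pipeline default is `upper = 200`: after
min–max stretching the fat pad sits within a few gray levels of white but
retains residual texture and sensor noise, and a ~55-level guard band keeps
it in the non-dense mask while epithelium (enhanced to the bottom quarter of
the range) remains far below the cut. Both defaults are configurable.

**AOI rasterization.** Pixel-center even-odd (crossing-number) rule with
half-open boundary handling: a pixel belongs to the AOI when its center is
inside the polygon; centers on the low-coordinate boundary are included, on
the high side excluded, so abutting polygons tile without double counting.
Either winding order is accepted; polygons may extend beyond the frame and
are clipped by rasterization.

## Synthetic phantoms

`PhantomSpec` → (`render_phantom`) → carmine-toned RGB image + exact ground
truth. The generator emulates the features the pipeline must cope with, with
defaults chosen to be realistic for a low-magnification whole-mount capture:

| parameter | default | meaning |
|---|---|---|
| `stage` | 1.0 | developmental parameter in [0, 1]: 0 ≈ weanling rudiment, 1 ≈ mature tree |
| `height × width` | 384 × 512 px | frame size (a scaled-down composite; ~1.9 × 2.6 cm at the default 50 µm/px pitch) |
| `branch_prob` | 0.09 | per-step tip split probability, multiplied by `stage` |
| `branch_angle_sd` | 0.35 rad | heading jitter / branch divergence scale |
| `segment_length_px` | 6 | growth step |
| `width_decay` | 0.9 | geometric duct-width decay per branching generation |
| `trunk_width_px` | 7 | primary duct width |
| `end_bud_radius_px` | 5 | terminal end-bud radius |
| `n_lymph_nodes` | 1 | dark ellipses placed in the fat pad, clear of the tree |
| `illumination_gradient_amplitude` | 20 gray | smooth diagonal shading (60 used in the robustness check) |
| `noise_sd` | 3 gray | Gaussian pixel noise |
| `fat_texture_sd` | 2.5 gray | low-frequency fat-pad texture |

Growth runs `12 + 48·stage` steps of a correlated random walk with binary
branching (tip count capped at 40); tips stopping at the frame margin or
surviving to the end become end buds. The AOI is the convex hull of the tree
dilated by `end_bud_radius + 8` px — mirroring the operator's trace around
the most distal end buds — and the walk margin is sized so this AOI always
lies strictly inside the frame. Foreground/background grays (epithelium
58–88, fat ≈ 242, lymph ≈ 72) leave over 100 gray levels of separation
before degradation, so default thresholds are exercised non-trivially rather
than at a knife edge. Ground-truth masks are frozen before gradient and
noise are applied.

What the phantoms do *not* emulate: staining gradients within the
epithelium, folds, bubbles, wrinkles, residual muscle, partial clearing,
focus variation across a composited capture, and anatomically realistic
side-branching/alveolar budding. Passing the phantom suite therefore shows
the pipeline's geometry, calibration and illumination handling are correct;
it does not certify performance on degraded real-world mounts, where the
operator-chosen threshold and AOI remain the main controls.

## Study conditions used by tests and the acceptance script

The default developmental series is 7 stages evenly spaced in [0, 1] with 9
phantoms per stage (63 specimens), matching a 7-time-point, n = 9 growth
study design; per-phantom seeds are `base_seed + index`. On this series the
pipeline's log–log regression of epithelial ΣOD on epithelial area attains
r² ≈ 0.997, the measured epithelial area matches ground truth within 10 %
for every phantom, dense-mask Jaccard overlap exceeds 0.8, and mean
epithelial area increases strictly with stage. Monte-Carlo trend checks on
ground truth use 50 seeds per stage. Frame size and replicate counts were
chosen once as the package's default study conditions.

## Numerical conventions

- Pixel coordinates are 0-based `(row, col)`, origin top-left; pixels are
  square (anisotropic pitch unsupported).
- All gray-level arithmetic rounds half up and clips to [0, 255].
- Sample SD uses the n−1 denominator; SEM = SD/√n; a single observation
  reports SD = SE = 0. Both SD and SEM are always reported because published
  "±" values are frequently ambiguous.
- Welch's t test is the two-group default (small unequal-variance groups);
  the pooled-variance variant is selectable. Identical samples short-circuit
  to (t, p) = (0, 1).
- `percent_reduction` permits negative values (increases); it requires a
  positive control mean.
- Report rounding convention: areas to 2 decimals, ΣOD to 1, percentages
  to 1.

## Known limitations

- The dense/fat split is a single global threshold after flattening; mounts
  with strong local staining variation may need per-image threshold tuning.
- Lymph-node excision needs operator seeds; nodes touching the epithelial
  tree at similar gray levels can make the wand leak (reduce the tolerance).
- ΣOD assumes the 8-bit capture is not saturated at the dark end; an opaque
  specimen clamps at `od_max` per pixel.
- The phantom growth model is morphological, not biological: stages are
  ordinal conditions, not ages, and its variance across seeds is larger than
  between-animal variance in a real cohort.
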
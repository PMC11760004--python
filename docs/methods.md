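# Methods

## Segmentation

Marbling is segmented by per-image Otsu thresholding of the luminance
channel. Choices the input format forces but the method itself leaves open:

- **Color collapse.** ITU-R BT.601 weights
  (`0.299 R + 0.587 G + 0.114 B`, rounded). Fat/lean contrast in sirloin
  photographs is overwhelmingly a brightness contrast, so the particular
  luminance convention is immaterial; BT.601 is the common default for
  8-bit imagery. 16-bit inputs are rescaled to 8 bits first.
- **Histogram domain.** The 256-bin histogram is built from ROI pixels
  only. Background (removed, typically black) would otherwise form a large
  spurious mode and drag the threshold down.
- **Tie-break.** The between-class variance
  `w0 w1 (mu0 − mu1)^2` is maximized over integer thresholds
  `t ∈ [0, 254]`; ties go to the smallest `t`, fixed for reproducibility.
  A single-intensity ROI raises `DegenerateHistogram` rather than
  returning an arbitrary value.
- Alternative thresholding algorithms are exposed only as a config enum
  (`threshold_method`); Otsu is the single implementation.

The implementation is vectorized; tests check it against an independent
plain-loop exhaustive search over all 255 candidate thresholds.

## Particle morphometry

- **Connectivity** defaults to 8 so diagonal fat streaks remain one
  fleck; 4 is available.
- **Perimeter** is the count of unit pixel edges adjacent to a non-fat or
  out-of-image pixel: deterministic, integer-valued, and exactly 4 for a
  single pixel. Sub-pixel estimators (e.g. Crofton) would change absolute
  values but not group contrasts, and are out of scope.
- **Cumulative rule.** With integer areas the cumulative fraction
  generically never *equals* 0.5, so `A50` is the area of the particle at
  the smallest rank whose ascending cumulative fraction **reaches** 0.5
  (and `P50` the analogue on the perimeter-sorted sequence). `F4` is the
  count of smallest particles whose cumulative area fraction stays
  strictly below 0.5, i.e. the rank of the `A50` particle minus one.
- Sorting ties are broken by the row-major first-encounter label id.
- No minimum particle size is imposed by default (`min_area = 1`); the
  filter exists for noisy inputs.

## The tile grid and F7

The ROI **bounding box** is split into `step × step` tiles with half-open
integer boundaries `floor(k · extent / step)`; `step` therefore measures
tiles relative to the muscle extent, making images of different sizes
comparable. Two conventions the tiling leaves open were fixed as:

- A tile is **included** when its ROI coverage (ROI pixels / tile pixels)
  is at least `min_coverage` (default 0.5) — "tiles located in the meat
  region".
- The ratio denominator for an included tile is its **ROI pixel count**,
  not the full tile area, so partially covered border tiles are normalized
  by the meat they actually contain instead of being biased low.

F7 is the sample (n−1) standard deviation of the included ratios; it
requires at least two included tiles. For ratios confined to [0, 1],
`F7 ≤ 0.5 · sqrt(n/(n−1))`, and `F7 = 0` iff all ratios are equal — both
are tested properties. `F8 = F2b / F7` is undefined (error, or NaN in the
batch pipeline) when `F7 = 0`.

The **Kuchida index** needs a physical scale; `pixels_per_cm` has no
default because image resolution is a property of the acquisition, not of
the method. The synthetic panels use 20 px/cm, which puts single fine
blobs (~13 px ≈ 0.03 cm²) inside the 0.01–0.5 cm² counting window and
single coarse blobs (~450 px ≈ 1.1 cm²) outside it.

## Group statistics

- Fine vs. coarse uses the **Welch** unequal-variance two-sided t test —
  group variances differ visibly between fineness groups, and Welch costs
  nothing when they do not. Zero-variance samples are handled explicitly
  (equal means → p = 1; distinct means → flagged degenerate, p → 0 limit).
- Three groups use one-way fixed-effects ANOVA, `F = MSB/MSW` with
  df (k−1, N−k).
- The **bootstrap** is a nonparametric percentile 95% CI of the group
  mean, B = 1000 by default, seeded; the point estimate is the plain mean
  and is never altered by resampling.
- The **step sweep** evaluates F7 at 5, 10, …, 95 tiles per axis
  (increment 5) and selects the step minimizing the fine-vs-coarse Welch
  p value, ties to the smaller (cheaper) step.
- No multiple-testing correction is applied across grades or steps; the
  sweep's p values are a selection heuristic, not simultaneous inferences.

## Synthetic marbling panels

The generator is a Boolean blob model: disks with truncated-normal radii,
mildly elongated by a random factor `1 + shape_irregularity·|N(0,1)|` and
randomly rotated, are dropped uniformly inside an elliptical ROI until the
fat fraction first reaches the target; the final blob is trimmed
pixel-by-pixel so every image realizes the target fraction exactly (well
inside the ±0.02 documented tolerance). Fat and lean render at mean
intensities 200 and 80 with Gaussian noise (σ = 8 by default), so Otsu
segmentation is exercised end-to-end; at this contrast recovery of the
generating mask is essentially perfect (≥ 99% ROI-pixel agreement is the
tested bound).

Default study conditions: 560 × 560 px images, a centered 480 × 400
elliptical ROI (bounding box large enough for every step in the 5–95
sweep), fat fraction 0.35, and radius presets **fine = 2 px,
medium = 6 px, coarse = 12 px** with SD = 25% of the mean. All groups
share the fat fraction by construction, isolating the spatial-distribution
signal from the fat-amount signal. One integer seed determines a panel;
per-image seeds are `base_seed + index`.

What the generator does **not** emulate: streak-like anisotropy of real
coarse marbling, illumination gradients, camera noise structure, muscle
boundary texture, or the correlation between fat fraction and grade.
Passing panel tests therefore demonstrates that the indices respond to
particle-size structure at matched fat content under clean imaging — not
that the pipeline is robust to uneven lighting, which remains the known
weak point of histogram thresholding.

On these blob panels the fine/coarse separation of F7 keeps improving
with finer grids, so the sweep's argmin typically lands at the top of the
scanned range rather than at any interior optimum; the interior optimum
reported for real carcass imagery reflects texture properties (streak
scale, segmentation noise) the blob model deliberately omits. The sweep
here validates the *mechanics* (19 steps, unique argmin, bit-exact
reruns), not a particular optimal step.

## Scaled-down problem sizes

Test and validation workloads use: 20 images per group for the
three-group panel; 200 replicates of 10-vs-10 images at 160 × 160 px for
the null calibration of the fine-vs-coarse test (rejection rate checked
against 5% ± 3%); 6 images at each of five blob radii (2, 4, 6, 9, 12 px)
for the F7–Kuchida correlation. These sizes give stable statistics while
keeping the suite quick to run on one CPU.

## Numerical and degenerate-input policy

Every operation raises a typed error on inputs where its statistic is
undefined (empty marbling, single-intensity histogram, sub-pixel tiles,
fewer than two tiles or samples, missing scale) instead of returning
sentinel values; the batch pipeline logs and skips such images. All
artifact files are plain CSV/TSV/PNG/JSON and byte-reproducible given
identical inputs, configuration, and seed.
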
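# Methods

`nucseg` implements a training-free pipeline for detecting, instance-
segmenting and counting fluorescent-labeled cell nuclei in single-channel
microscopy frames, together with the evaluation statistics used to validate
such pipelines and a synthetic scene generator that provides exact ground
truth. This note documents the model, the parameters that matter, the
numerical conventions, and what the synthetic tests do and do not show.

## Pipeline model

The segmentation is a fixed composition of classical operators; there is no
fitting stage and every behavior is controlled by a small set of
interpretable parameters.

**1. Edge-preserving smoothing.** Each frame `I` is filtered bilaterally:

    O(p) = Σ_q I(q) c(p,q) s(p,q) / Σ_q c(p,q) s(p,q)

over a square window of radius `window_radius`, with a Gaussian spatial
closeness kernel `c(p,q) = exp(-||p-q||² / 2σ_s²)` and a Gaussian intensity
similarity kernel `s(p,q) = exp(-(I(p)-I(q))² / 2σ_c²)`. Defaults:
`σ_c = 1` intensity unit and `σ_s = σ_global`, the standard deviation of
the input frame's intensities (`"auto"`). Note the unusual assignment —
the *spatial* bandwidth tracks the image's *intensity* spread; both sigmas
are exposed in the configuration so users can swap to the conventional
small-spatial / wide-range setting if their data calls for it. The window
radius defaults to `ceil(3 σ_s)` (≥ 99% of the Gaussian mass), capped at
half the smaller frame dimension and floored at 1.

Two mathematically identical evaluation paths exist. The direct path
accumulates shifted windows and works for any input. For large frames with
a discrete intensity alphabet (8-/12-/16-bit integers), the filter is
evaluated exactly by decomposing the sums over the distinct intensity
values and computing each spatial sum as a zero-padded FFT convolution;
zero padding *is* the border rule (see below), since the numerator and
denominator lose identical out-of-frame mass. This is not an approximate
fast-bilateral variant: both paths agree with a brute-force double loop to
float precision, and the test suite checks both.

**2. Background correction.** White top-hat `T = I − (I ∘ b)` with a flat
(binary) disk `b` of radius 21 px: the gray-scale opening removes every
bright structure narrower than the disk, so subtracting it keeps nuclei
(diameters well under 42 px at the targeted magnification) and flattens
slowly varying illumination. Output is ≥ 0 and ≤ input everywhere.

**3. Foreground refinement.** On the top-hat image, in this fixed order:
Otsu global threshold (mask = pixels strictly above the threshold) → hole
filling → binary opening (disk radius 1) to sever loosely connected
components → removal of components with strictly fewer than 40 px →
binary closing (disk radius 2) to smooth boundaries. The 40-px cut is
strict: a 40-px component survives, a 39-px one does not.

**4. Seed selection.** The refined mask's chamfer Euclidean distance
transform (5×5 mask by default) is stretched linearly to [0, 255]; its
regional maxima — connected plateaus strictly above their external
boundary, with plateau adjacency and boundary both defined by a 5×5 square
window — are dilated by a disk of radius 3 and connected-component
labeled. The dilation merges the few near-coincident peaks a single
nucleus can produce into one seed.

**5. Watershed.** The edge landscape is the discrete Laplacian of the
pre-processed image (4-neighbor stencil, reflective borders). Flooding
starts from all seeds simultaneously through a priority queue keyed on
(edge value, insertion order): pixels are dequeued in increasing edge
value, ties broken first-in-first-out, so plateaus are scanned
breadth-first and a contested pixel goes to the marker front that reached
it first. Each flooded pixel adopts the label of the neighbor that
enqueued it; markers are never relabeled. Flooding is confined to the
refined foreground mask and the final labels are clipped to it, so
background stays 0 and basins cannot leak. The cell count is the number of
distinct positive labels.

## Parameters (defaults)

| parameter | default | units | role |
| --- | --- | --- | --- |
| `bilateral.sigma_c` | 1 | intensity | range (similarity) bandwidth |
| `bilateral.sigma_s` | auto (= σ_global) | px | spatial bandwidth |
| `bilateral.window_radius` | auto (= ⌈3σ_s⌉) | px | window truncation |
| `tophat.radius` | 21 | px | background structuring disk |
| `seeds.open_radius` | 1 | px | opening disk |
| `seeds.min_area` | 40 | px | strict minimum component size |
| `seeds.close_radius` | 2 | px | closing disk |
| `seeds.maxima_window` | 5 | px | regional-maxima square side |
| `seeds.dilate_radius` | 3 | px | seed-merging dilation disk |
| `seeds.edt_mask` | 5 | – | chamfer mask size (3 or 5) |

All are overridable via TOML config or `--set key=value` on the CLI. The
`bilateral.enabled=false` configuration runs the identical downstream
program on the plain top-hat image (the no-smoothing ablation arm).

## Numerical conventions

* **Coordinates** are row-major `(row, col)`, 0-based. Foreground
  components and plateaus use 8-connectivity; hole filling floods the
  background 4-connectedly; watershed flooding uses 4-connectivity.
* **Borders**: the bilateral window renormalizes over in-image pixels;
  morphological erosion/dilation ignore out-of-image samples (identity
  elements outside); the Laplacian reflects. A constant frame is therefore
  a bilateral fixed point and maps to all zeros under the top-hat.
* **Otsu on float data** is defined over a 256-bin equal-width histogram
  spanning [min, max]; the threshold is the center of the last background
  bin, ties resolved toward the lowest threshold.
* **Chamfer weights** are the optimal real-valued sets: 3×3
  (0.95509, 1.36930), maximum relative deviation from exact Euclidean
  ≤ 4.5%; 5×5 (0.9866, 1.4142, 2.2062), ≤ 1.4%. Distances are rounded to
  9 decimals so that geometrically symmetric pixels, whose minimal paths
  accumulate the same weights in different orders, compare exactly equal
  during plateau analysis.
* **Degenerate inputs**: a constant frame yields an empty label map; an
  all-foreground mask has unbounded distances and raises unless
  `seeds.border_is_background` makes the frame edge a virtual distance
  source; an empty maxima set yields zero cells.
* **Watershed dams**: every flooded pixel receives a label (counts and
  overlap scores use filled regions); `watershed.boundary_lines=true`
  additionally clears one pixel per adjacent-label interface for display.

## Evaluation statistics

Dice and IoU are computed on binarized (foreground vs background) masks,
reported in percent; they satisfy `IoU = DSC / (2 − DSC)` on the unit
scale, and empty-vs-empty is defined as 100%. Count agreement uses the
sample Pearson correlation (two-sided p from the t transform with n − 2
df) and Bland-Altman analysis with differences signed automated − manual,
bias ± 1.96 × sample SD as the 95% limits of agreement, and the fraction
of pairs outside the limits as the outlier rate. Dataset evaluation
reports per-image rows plus mean ± SD summaries.

## Synthetic scenes

The generator emulates wide-field fluorescence screening frames:
pseudo-circular nuclei (flat core, logistic rim of 1 px scale, so apparent
radius = geometric radius at half peak) on a dark background
(6% of dynamic range) with an optional low-frequency illumination ramp and
additive Gaussian noise; overlapping nuclei compose by intensity maximum.
Ground truth assigns each covered pixel to the nearest generating center
and is exact by construction.

The standard suite is 20 frames of 512×512 at 8 bit, counts ramping
geometrically from 5 to 150 (sparse members sit at ~1% coverage, the
densest near 18%), radii 8–12 px, edge-to-edge separation ≥ 4 px, nucleus
peaks 65–85% of dynamic range and noise σ = 4 — a high signal-to-noise
regime in which Otsu separability holds by construction. Passing the
count-recovery and Dice checks on this suite therefore demonstrates the
pipeline logic (seeding, splitting, counting), **not** robustness to low
contrast, clutter, debris, focus drift or heavy overlap found in real
data; the `SceneSpec` fields (`noise_sigma`, `intensity_range`,
`overlap_fraction`) produce harder regimes for robustness experiments.
The 8-bit alphabet also keeps the bilateral level decomposition at ≤ 256
exact FFT convolutions per frame.

Problem sizes used by the shipped checks: the full suite for count
recovery and segmentation fidelity (one shared run), 6 frames at 256×256
for the parallel byte-identity check, ≤ 15×15 random instances (100+ per
operator) for the brute-force oracle comparisons, and 10⁴ simulated
differences for Bland-Altman calibration.

## Known limitations

* σ_s = σ_global makes the bilateral window scale with image contrast; on
  high-contrast 16-bit frames the 3σ window hits its cap (half the frame)
  and the filter becomes global — the conventional swap (small σ_s, wide
  σ_c) is available through the config.
* One seed per refined-mask maximum: heavily overlapped clusters whose
  distance map has a single plateau are counted as one nucleus.
* The 40-px size filter is applied once, before seeding; small watershed
  fragments are not re-filtered afterwards.
* Genuinely multi-channel color input is rejected rather than converted;
  channels must be split upstream.
* The parent-workers executor parallelizes across images only; a single
  very large frame does not benefit.
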
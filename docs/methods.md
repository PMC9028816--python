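# Methods

## The measurement model

The package measures neighborhood streetscape quality in three layers.

**Per-image detection.** Each of the eight streetscape features gets its
own binary classifier that maps an image to a probability of feature
presence. One classifier per feature — rather than one multi-label model —
keeps each feature improvable in isolation and avoids the failure mode
where a rare class (zebra crosswalks) is starved by a prevalent one (curb
cuts). Per-feature class imbalance is instead handled inside each model
with per-class sample weights in the loss.

**Coordinate aggregation.** An audit coordinate is either an intersection
(street-graph node of degree ≥ 3) or a segment midpoint, and carries four
directional images (headings 0°/90°/180°/270°). Per-image probabilities
become one presence call per (coordinate, feature):

- threshold ≥ 0.50, boundary inclusive;
- sidewalks: the four probabilities are averaged before thresholding, so a
  sidewalk visible on one side of the block (some headings only) is not
  vetoed by the other views;
- every other feature: present if any direction clears the threshold.
  Applying the threshold per direction and OR-ing is the natural
  coordinate-level reading of a per-image rule; a `rule_map` argument can
  switch any feature to the mean rule instead;
- sidewalk buffers are conditional: where no sidewalk was detected the
  buffer is absent and the buffer classifier is not consulted;
- crossing furniture (zebra/line crosswalks, walk signals, curb cuts) is
  only audited at intersections; sidewalks, buffers, streetlights, and
  bike symbols at all coordinates (configurable eligibility map);
- a missing directional image is dropped from the aggregation (the
  sidewalk mean runs over available directions, at least one required); a
  coordinate with no usable image is skipped and logged, never imputed.

**Neighborhood scoring.** For each participant, calls inside the 500 m
street-network buffer around the home node are reduced to per-feature
fractions: positives divided by the feature's *eligible* coordinates
(intersection features ÷ intersections, others ÷ all coordinates).
Because denominators differ by feature, fractions are z-scored across the
participant sample — (x − mean)/SD with the n−1 sample SD — to express
each neighborhood relative to the sample. Zebra and line fractions are
summed into "all crosswalks" *before* z-scoring (the composite is a sum of
the measured quantities, so it can exceed 1; the alternative — summing the
two z-scores — is available behind a flag). The total microscale score is
the sum of exactly seven z-terms: sidewalks, sidewalk buffers, curb cuts,
all crosswalks, walk signals, bike symbols, streetlights. Totals are sums
of centered terms, so the sample mean is 0 to numerical precision.

The sidewalk-buffer denominator is all sidewalk-eligible coordinates, not
only sidewalk-positive ones: with the conditional call rule this keeps the
buffer fraction monotone in streetscape quality (a neighborhood without
sidewalks scores 0 rather than undefined). The conditional-denominator
reading is available via `buffer_denominator="sidewalk-present"`.

## Macroscale walkability

Four components per unit (participant buffer or block group): net
residential density (housing units / residential parcel area), land-use
mix, intersection density (count of ≥ 3-leg intersections in the buffer),
and transit access (stop count). Land-use mix is normalized Shannon
entropy −Σ pᵢ ln pᵢ / ln 7 over the fixed seven-category list
(residential, retail, recreational, office, civic, food, entertainment);
the normalization anchors 1 at evenness across those seven uses, so absent
categories lower the score rather than shrinking the base. The walkability
index is the sum of the four components' sample z-scores, which makes it
invariant to affine rescaling of any raw component; intersection and
transit counts are therefore carried per buffer rather than per km²
(equal-area buffers make the distinction vanish under z-scoring; a
per-area option exists for unequal buffers).

Stratification ranks units into deciles (average ranks for ties, then
ceiling binning): SES deciles 1–5 = lower, 7–10 = higher, 6th omitted;
walkability deciles 1–4 = lower, 7–10 = higher, 5–6 excluded. The
exclusions reduce mis-categorization at the category boundaries.
Cross-classification yields the four recruitment strata.

## The training loop

An epoch is one pass through the training set; the model is checkpointed
after every epoch. "Error" in traces is mean binary cross-entropy (the
loop only needs a monotone goodness measure; any proper loss would do).
Training stops on the first of:

- **overfit**: the first epoch e after which validation error strictly
  rises for `patience` (default 3) consecutive epochs while training error
  does not rise. Both conditions matter — a joint rise is instability,
  not overfitting. A transient rise shorter than `patience` is ignored;
- **plateau**: no new validation minimum for `patience` epochs;
- the epoch budget.

The deployed checkpoint is the validation-error argmin restricted to
epochs strictly before any overfit point, ties broken toward the earlier
epoch (smaller effective capacity). A train–correct cycle harvests the
top-k most confident false positives and false negatives (|p − 0.5|
descending) from a labeled pool, folds them into the training set, and
retrains from scratch.

Augmentation is whitelisted to horizontal flip, brightness, and contrast.
Crop, zoom, warp, cutout, and rotation can remove a feature sitting at the
image edge, silently corrupting the label; requesting them is an error,
not a warning.

**Default backbone.** The `tiny-cnn` backbone is a fixed (untrained)
random convolutional feature layer — 16 random 5×5×3 filters at stride 4
over a 4×-downsampled image, ReLU, 3×3 average pooling — concatenated with
an 8×8 grid of per-cell RGB means and a 16×16 grid of color-opponent
(G−R, B−G, R−B) means, feeding a logistic head trained by seeded minibatch
gradient descent. Random convolutional features are a standard cheap
featurizer; only the head is trained, which keeps an eight-classifier
bench under ten seconds of CPU time and makes every epoch bit-reproducible
(single-threaded, seeded shuffling). The fine opponent grid exists because
thin glyphs (the painted bike symbol) vanish when averaged into 32-px RGB
cells but survive as hue-dominance signals. Backbones are pluggable; a
large pretrained network can be adapted behind the same interface, and
nothing downstream depends on the backbone choice.

## What the simulators emulate — and what they do not

**Scenes** (`scenes`). 256×256 RGB streetscapes built from horizontal
bands (sky, ground, optional sidewalk strip, optional vegetated buffer
strip, road) and one geometric glyph archetype per feature, each with
bounded position/scale/hue jitter, mild photometric variation
(brightness/contrast 0.92–1.08), and sensor noise. Distractors are
deliberate confusers that never change labels: dark shadow stripes
mimicking zebra markings, a "real" parked bike off the road versus the
painted road symbol, and a bare pole without a luminaire. A
pixel-statistic oracle (glyph-colored pixel counts in each feature's
canonical region, via hue-dominance predicates) classifies clean scenes
with 100% accuracy, certifying that the learning task is well-posed — so a
classifier failure is a training defect, not an unlearnable bench.

Two RNG details matter. Each scene's draws come from its own stream
derived from (dataset seed, scene index), so generation is reproducible
independent of order or parallelism. The spec-draw stream and the
render-jitter stream are separated by a stream-id component: if rendering
re-consumed the same stream that drew the labels, layout jitter would be a
deterministic function of the labels and a classifier could "read" labels
from the background — an information leak that survives train/validation
splits because the mapping is identical for every (seed, index).

Passing on this bench shows the pipeline machinery and the loop logic are
correct; it does not show that any backbone reaches real-world GSV
accuracy. Real imagery has occlusion, weather, perspective, and feature
designs this renderer does not attempt (no photorealism, camera pose, or
fisheye projection).

**Regions** (`geosim`). The street network is a perturbed rectangular
grid (Phoenix-like morphology; intersection degrees controllable by
construction), edges 100 m by default, one segment coordinate per edge
midpoint, block groups tiling the grid. A latent walkability factor per
block group is drawn from a spatially smooth Gaussian process
(exponential kernel, range two block-group widths) — adjacent
neighborhoods resemble each other, as in real urban form; without this
smoothness a 500 m buffer spanning several block groups would decorrelate
from its home block group. SES is an independent draw from the same
process, so the SES × walkability stratification has all four cells.

Feature presence at a coordinate is Bernoulli with
logit⁻¹(logit(baseline) + loading · latent). Baseline rates default to
the model-detected prevalences reported for the Phoenix study region
(sidewalks 0.898 down to zebra crosswalks 0.003); loadings default to
moderate positive values (0.7–1.0 per SD of latent). Sidewalk-buffer
truth is forced absent where sidewalk truth is absent. A present feature
is visible in ≥ 1 of the four directional scenes — ≥ 2 for sidewalks, so
the mean rule is exercised — and a visible buffer only in headings where
the sidewalk is visible, so every directional image is a renderable scene.
Block-group attributes (housing, land-use shares interpolating single-use
→ uniform, Poisson transit stops) are monotone in the latent factor plus
noise. Perceived subscales are standardized drivers plus Gaussian noise;
traffic-safety and crime-safety are pure noise, deliberately independent
of the latent factor, so the pipeline's null correlations are testable.

Not emulated: real geocoding, census ingestion, parcel geometry,
address-offset buffers, travel-time buffers, and any spatial sampling
bias in where imagery exists.

## Numerical choices

- Threshold comparisons are `>=`, making 0.50 itself "present".
- z-scores use the n−1 sample SD; zero spread raises an error naming the
  degenerate feature rather than silently emitting zeros (rare features
  in small regions genuinely hit this; study-scale runs do not).
- Spearman ρ is the Pearson correlation of average ranks (ties averaged),
  p from the two-sided t approximation, pairwise-complete observations;
  cells with < 3 complete pairs are missing. Stars follow the
  †/*/**/*** convention at 0.10/0.05/0.01/0.001 with no multiple-testing
  correction by default (per-cell stars); Benjamini–Hochberg is available.
- Performance ratios with zero denominators are undefined (NaN), never 0.
- Deciles: average ranks, then ceil(10·r/n), clipped to 1–10.
- Checkpoint ties break to the earlier epoch; harvest ordering is stable
  sort by |p − 0.5|.
- All stage seeds derive from one global seed via SHA-1, kept below 2³¹.

## Problem sizes

The test bench and the reproduction script use: 800 training + 400
validation scenes (≈ 400 per class) for the classifier bench; a 25×25-node
region (50 block groups, ≈ 1,800 audit coordinates) with 200 participants
for end-to-end recovery; 400 simulated matrices at n = 200 for the null
calibration of the validity matrix. These sizes give tight Monte-Carlo
bands (prevalence recovery within ±0.03; null p < 0.05 rate within
0.05 ± 0.02) while a full suite run stays under two minutes.

## Known limitations

- Coordinate-level agreement in trained mode is bounded by rule
  interactions, not classifier quality: a sidewalk visible in exactly 2 of
  4 directions puts a calibrated classifier's mean at the 0.50 boundary,
  and the any-direction rule multiplies per-image false-positive rates by
  up to four. Oracle mode isolates the aggregation from this effect.
- The simulators plant monotone, logistic associations; the pipeline is
  not exercised against confounded or non-monotone structure.
- Perceived subscales are generated at block-group resolution, so
  within-block-group perception variance is noise only.
- The tiny backbone reads color-geometry regularities; it is a bench
  default, not a claim about real-imagery performance.
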
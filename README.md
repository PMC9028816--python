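# walkaudit

Automated **microscale walkability audits** from street-level imagery, with
a fully synthetic test bench.

Microscale streetscape features — sidewalks, sidewalk buffers, curb cuts,
zebra and line crosswalks, walk signals, painted bike symbols, and
streetlights — shape pedestrian physical activity but are rarely measured,
because in-person or virtual audits by trained human raters do not scale.
`walkaudit` implements the full computational pipeline for replacing those
raters with per-feature binary image classifiers:

1. **Per-feature classifiers** (one independent binary model per feature,
   never one multi-label model) trained with a *train–correct loop*:
   epoch-wise checkpointing, overfit detection (validation error rising
   while training error falls), best-checkpoint selection restricted to
   pre-overfit epochs, and hard-example harvesting for retraining.
   Augmentation is restricted to horizontal flip, brightness, and contrast
   — the only transforms that cannot push a feature out of frame.
2. **Coordinate-level presence calls** from the four directional images at
   each audit coordinate: probability threshold fixed at **≥ 0.50**;
   sidewalks use *mean-then-threshold* over the four headings (a sidewalk
   on one side of the block shows in only some views); all other features
   use the any-direction rule; sidewalk buffers are assessed only where a
   sidewalk was detected.
3. **Neighborhood summaries** inside 500 m street-network buffers around
   participant homes: per-feature positive-coordinate fractions (with
   intersection-only features divided by intersections), z-scored across
   the sample, zebra + line combined into *all crosswalks*, and the
   **total microscale score** = Σ of the 7 z-terms
   (sidewalks, buffers, curb cuts, all crosswalks, walk signals, bike
   symbols, streetlights).
4. **Macroscale walkability**:
   *walkability index* = z(net residential density) + z(land-use mix) +
   z(intersection density) + z(transit access), with land-use mix the
   normalized entropy −Σ pᵢ ln pᵢ / ln 7 over seven parcel land uses, plus
   the SES × walkability decile stratification (SES deciles 1–5/7–10 with
   the 6th omitted; walkability deciles 1–4/7–10 with 5–6 excluded).
5. **Evaluation**: precision, recall, negative predictive value,
   specificity, and accuracy against labeled validation images, and
   convergent validity as a 10 × 12 Spearman matrix (microscale z-scores ×
   macroscale components + perceived-walkability subscales).

Because real audit imagery and participant data are proprietary, the
package ships two first-class simulators: `scenes` renders labeled
synthetic streetscapes (with confuser distractors such as zebra-like
shadows), and `geosim` simulates street-network regions with a planted
latent walkability factor driving feature prevalence, macroscale
attributes, and perceived-walkability responses — so every stage is
testable against known ground truth.

## Worked example

```python
from walkaudit.pipeline import PipelineConfig, run_pipeline, read_output_csv

cfg = PipelineConfig(seed=7)             # 25x25 grid, 200 participants, oracle classifiers
out = run_pipeline(cfg, "demo_run")

perf = read_output_csv(out / "call_metrics.csv")
print(perf[["feature", "precision", "recall", "accuracy"]])

m = read_output_csv(out / "validity_matrix.csv")
print(m[(m.row == "total_microscale") & (m.column == "walkability_index")])
```

With oracle (ground-truth-reading) classifiers every call metric is 1.0 by
construction, and the validity matrix recovers the planted association
structure:

```
             row            column      rho            p stars
total_microscale walkability_index 0.668169 3.148039e-27   ***
```

while the deliberately independent crime-safety subscale stays null
(ρ = 0.022, p = 0.76).  Per-participant summaries look like:

```
participant_id  frac_sidewalk  frac_all_crosswalks  total_microscale
        p_0000       0.925466             0.065574          3.656610
        p_0001       0.926316             0.027778         -0.795144
```

`frac_sidewalk` is the share of buffer coordinates with a detected
sidewalk; `total_microscale` ranks the neighborhood's overall streetscape
quality relative to the sample (mean 0 by construction).

Swap `classifier_mode="trained"` to run the full stack: tiny CPU-trainable
classifiers are trained on rendered scenes, every coordinate's four
directional images are rendered and classified, and the same scoring runs
on model output instead of ground truth.

A `walkaudit` CLI wraps the stages (`synth-scenes`, `synth-region`,
`audit`, `summarize`, `macro`, `validate`, `report`, `run-all`); every run
directory carries its config hash, per-stage JSON-lines log, and seeds, and
identical configs reproduce outputs byte-identically.

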
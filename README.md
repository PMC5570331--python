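# scenegaze

Analysis toolkit for scene-viewing eye-tracking studies, plus a synthetic
data generator so the whole pipeline is testable without any recordings.

The pipeline covers:

- **`scenegaze.scene_saliency`** — graph-based saliency maps in [0, 1]:
  feature channels (intensity, color opponency, oriented energy) on a
  coarse working grid, activation as the stationary distribution of a
  Markov chain whose edges combine feature dissimilarity with spatial
  falloff, a concentration pass, channel fusion and min–max normalization.
  A center–surround fallback sits behind the same interface.
- **`scenegaze.gaze_preprocess`** — saccade/fixation segmentation from
  1000 Hz samples (velocity 30°/s OR acceleration 8000°/s² thresholds),
  recursive baseline outlier removal, baseline replacement, drift
  correction, and trial/participant exclusion rules (blink fraction,
  missing responses, bad baselines).
- **`scenegaze.roi_partition`** — the four-way scene partition (head, body,
  low-/high-saliency by percentile cutoff), within-social saliency splits,
  component counts and ROI-relative saliency.
- **`scenegaze.fixation_density`** — duration-weighted, Gaussian-smoothed,
  max-normalized fixation density maps per trial and response window.
- **`scenegaze.attention_metrics`** — raw and area-normalized ROI density
  and fixation-count scores, first-three-fixation frequencies, reaction
  times.
- **`scenegaze.stats_inference`** — balanced fully-within-subjects ANOVA
  with Huynh–Feldt ε and generalized η², Cohen's d, and noncentral-F power
  for the one-way within design (with a Monte-Carlo cross-check).
- **`scenegaze.synthetic_data`** — seeded synthetic scenes with planted
  head/body regions and distractors, plus simulated gaze (gamma fixation
  durations, raised-cosine saccade profiles, blinks, per-trial drift)
  with full ground truth.
- **`scenegaze.io_core` / `scenegaze.pipeline` / `scenegaze.cli`** —
  formats (CSV gaze tables, PNG scenes, indexed-PNG masks with a JSON
  color table), screen-geometry conversions, config, and orchestration.

## CLI

All stages are exposed as subcommands with global
`--config/--seed/--log-level/--out-dir` flags:

```sh
scenegaze --seed 1 --out-dir session simulate --subjects 2 --social 4 --nonsocial 4
scenegaze --out-dir out saliency session/scenes/stim000.png
scenegaze --out-dir out preprocess --gaze session/gaze.csv --trials session/trials.csv
scenegaze --out-dir out rois --saliency-map out/stim000_saliency.png \
    --mask session/scenes/stim000_mask.png
scenegaze --out-dir out density --events out/events.csv --trials session/trials.csv \
    --width 300 --height 225
scenegaze --out-dir out metrics --gaze session/gaze.csv --trials session/trials.csv \
    --scenes-dir session/scenes
scenegaze --out-dir out stats --metrics-csv out/metrics.csv \
    --dv density_norm --within roi,task
```

All thresholds (detection, baselines, exclusions, ROI percentile,
smoothing SD, ...) are config keys; see `scenegaze.io_core.DEFAULT_CONFIG`
and override via `--config my.yaml`.

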
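# romval

Validation pipeline for joint range-of-motion (ROM) measured from monocular
3D human-pose-estimation landmarks against optical motion-capture ground
truth, for musculoskeletal telerehabilitation exercises.

Given two 3D landmark-trajectory streams per acquisition — a 6-marker mocap
stream (default 100 FPS) and a 33-landmark predicted skeleton stream
(default 30 FPS) — the pipeline:

1. **Anatomical frame** (`romval.anatomical_frame`) — builds a camera-invariant
   virtual coordinate system from the four torso keypoints of the first
   complete frame: the frontal-plane normal (Z) from a deterministic
   consensus (RANSAC-style) plane fit, the transverse-plane normal (Y) as
   the shoulders→hips midpoint vector, and the sagittal-plane normal (X)
   by the right-hand rule. Mocap streams whose lab axes are already
   anatomical use a configurable axis mapping instead.
2. **ROM amplitude** (`romval.rom_amplitude`) — per frame, projects the
   moving body-segment vector onto the exercise's plane of movement and
   measures the unsigned angle to the reference direction (vertically
   downward, or the dynamic foot→knee vector for the squat). Eight
   built-in exercise configurations: SF, SA, EF, SP, HA, SQ, MCH, SKF.
3. **Temporal alignment** (`romval.temporal_alignment`) — converts frames to
   seconds, detects repetition peaks, coarsely aligns by the first peak
   pair, downsamples the mocap stream onto the camera clock by
   nearest-sample matching (default tolerance 5 ms), fine-tunes the offset
   by maximizing the Pearson correlation over candidate peak pairings, and
   segments repetitions between flanking minima.
4. **Agreement metrics** (`romval.agreement_metrics`) — MAE, MAPE (with a
   near-zero ground-truth exclusion threshold, default 1°), Pearson r,
   raw cosine similarity, and OLS regression (x = predicted, y = ground
   truth), reported separately for peak amplitudes (per-repetition maxima)
   and motion amplitudes (all within-repetition samples).
5. **Synthetic motion** (`romval.synthetic_motion`) — a seeded generator
   (raised-cosine repetition pulses, forward-kinematic body template,
   camera yaw, start offset, angle-space linear distortion, landmark
   noise) so every stage is testable without laboratory data.

## CLI

```bash
# built-in exercise registry
rom-validate exercises

# render a synthetic acquisition pair (trajectory CSVs + truth manifest)
rom-validate simulate --exercise SA --seed 7 --yaw 35 --noise-mm 5 \
    --slope 0.89 --intercept 1.72 --out-dir sim/

# amplitude series for one trajectory file
rom-validate rom --exercise SA --input sim/pred.csv --skeleton mediapipe33 --fps 30

# align two streams; emit matched samples
rom-validate align --gt sim/gt.csv --pred sim/pred.csv --exercise SA \
    --tolerance-ms 5 --out aligned.csv

# segment repetitions and compute the agreement report
rom-validate evaluate --aligned aligned.csv --exercise SA --threshold-deg 1

# full study from a YAML config
rom-validate run --config study.yaml
```

Example `study.yaml`:

```yaml
mode: synthetic          # or "files" with a files: {CODE: {gt: ..., pred: ...}} block
seed: 7
exercises: [SF, SA, EF, SP, HA, SQ, MCH, SKF]
out_dir: study_out
protocol: {n_sets: 2, reps_per_set: 7, rest_s: 10.0, per_rep_jitter_deg: 4.0}
camera: {noise_sigma_m: 0.002, start_offset_s: 1.5}
yaw: {frontal: 0.0, sagittal: 35.0}
pipeline:
  ransac: {residual_threshold_m: 0.01, seed: 0}
  ground_truth: {down_axis: "+y", anterior_axis: "+z"}
  peaks: {min_prominence_frac: 0.2, min_separation_s: 1.0}
  match_tolerance_s: 0.005
  mape_threshold_deg: 1.0
  min_peak_frac: 0.5
```

`run_study` writes per-exercise report JSONs, aligned-sample CSVs, a
combined `summary.csv` (one row per exercise), and a parameter log; output
is byte-identical for identical config + seed.

## Trajectory file format

Wide CSV/TSV, one row per frame, three columns per landmark named
`<landmark>_x`, `<landmark>_y`, `<landmark>_z`; positions in meters;
missing landmark-frame pairs are empty cells. Skeleton definitions
(landmark order + canonical joint mapping) are in `romval.landmark_io`
(`MEDIAPIPE_33`, `MOCAP_6`).

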
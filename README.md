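# fapa

Automated inference of facial paralysis in head-fixed mice from face and
whisker videography, with the supporting facial-expression and
spike-train analyses.

The pipeline:

1. **`fapa.video_io`** — read videos or frame directories, convert to
   grayscale, align sessions via four anatomical landmarks (least-squares
   similarity transform), and crop the anterior / middle / posterior face
   zones.
2. **`fapa.whisker`** — segment a paint-marked whisker by color, clean the
   mask, reduce it to an angle about the whiskerpad insertion, rebase the
   session minimum to 0°, detect the movement-onset changepoint, split
   the signal into minimum-to-minimum movement cycles, and compute
   amplitude classes, cycle AUC, and a movement spectrogram.
3. **`fapa.hog`** — per-frame HOG descriptors (8 orientations, 32-px
   cells, 1 cell/block, square-root gamma compression) and the scalar
   `Diff` series: distance of every frame's HOG from frame 1.
4. **`fapa.decision`** — movement thresholds (group mean+sd, individual
   mean, two-session midpoint), the ten binary decision models over zone
   low-movement flags (the recommended default is model 2: normalized
   anterior AND middle), the per-frame movement rule, the >90%-stillness
   session verdict, and scoring (decision percentage, d′).
5. **`fapa.prototypes`** — basal prototype (mean HOG of 250 resting
   frames), emotional prototypes (mean of the 10 least-basal-correlated
   stimulation frames), and per-frame Pearson similarity traces.
6. **`fapa.ephys`** — PSTHs in 100-ms bins, 10-s-baseline z-scores, and
   normalized cross-covariance between firing and behavioral traces.
7. **`fapa.synthetic`** — seeded generators for everything above: face
   videos with zone-wise programmable motion over the standard 23-session
   timeline (transection / crush / sham schedules), whisker traces,
   marker videos, and motion-coupled Poisson spike trains.

## CLI

All commands are under a single `fapa` entry point; each writes its
outputs plus a `run_log.jsonl` with the resolved parameters.

```sh
# synthesize a crush-injury timeline and infer paralysis with model 2
fapa simulate --model crush --seed 7 --out runs/crush
fapa infer --summaries runs/crush/diff_summaries.csv --model 2 \
    --threshold-mode two_session --baseline 0 --paralyzed 3 \
    --out runs/crush/verdicts.json
fapa score --verdicts runs/crush/verdicts.json \
    --truth runs/crush/labels.csv --out runs/crush/score.json

# real data: frames -> whisker trace / HOG diffs / prototypes / PSTHs
fapa extract video.mp4 --out runs/frames
fapa track-whiskers frames_dir/ --config whisker.yaml --out runs/whisk
fapa hog frames_dir/ --zones zones.yaml --out runs/hog
fapa prototype --hogs hogs.csv --event-frame 250 --stimulus sucrose --out runs/proto
fapa ephys --spikes spikes.csv --events events.csv --out runs/ephys
```

Config files are YAML; e.g. `whisker.yaml`:

```yaml
color_ref: [1.0, 0.1, 0.1]
tolerance: 0.15
insertion: [480, 120]
fps: 120
```

and `zones.yaml`:

```yaml
zones:
  A: [0, 960, 0, 640]     # row_start, row_end, col_start, col_end (half-open)
  M: [0, 960, 640, 1280]
  P: [0, 960, 1280, 1920]
```

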
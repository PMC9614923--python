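# antmark

Annotation, quality control and motion analysis for ant-colony trajectory
datasets in the MOT text format.

Studying the clustering behaviour of social insects requires per-individual
motion trajectories: every ant in every video frame labelled with a bounding
box and a persistent identity. Such ground truth is produced by a
click-to-mark workflow — an annotator marks one ant's centre point frame by
frame, one ant per pass, and the per-ant files are merged into a single
ground-truth file — and is stored in the MOTChallenge text dialect (one
7-field comma-separated line per ant instance: frame, id, box left/top/width/
height, confidence). `antmark` re-implements that workflow headlessly and
packages the analysis and validation machinery around it:

- **`antmark.mot_io`** — bit-exact reading/writing of `det.txt` / `gt.txt`
  files, the `det/gt/img` sequence folder layout, the `SeqXObjectYImageZ`
  image-set name grammar, and YAML filming-metadata manifests (a ten-sequence
  manifest of the indoor/outdoor ant video collection is bundled).
- **`antmark.session`** — the annotation state machine: click-to-mark with a
  previous-frame reference point, next/previous navigation, check-and-modify,
  crash-safe resume, and the merge step that sorts all objects' records by
  frame and then ID.
- **`antmark.qc`** — automated review: duplicate/box/confidence integrity
  errors, track-gap and teleport warnings, sequence summaries, and segment
  reports that localise the frames needing remarking.
- **`antmark.kinematics`** — per-frame speeds from box centres. The pixel
  displacement between adjacent frames, Δps_t = √((px_t−px_{t−1})² +
  (py_t−py_{t−1})²), is calibrated to metres by an ant's body length in the
  world (L) over its length in the image (n), and to a speed by the frame
  rate f_c: v_t = Δps_t · (L/n) · f_c, with v_0 = 0 at each track start.
- **`antmark.geometry`** — the ground footprint of a tilted camera,
  BD = Height · (tan(α+β) − tan(α−β)), giving each filmed scene's width,
  depth and area from camera height, tilt α and angle of view β.
- **`antmark.motmetrics`** — CLEAR-MOT evaluation (MOTA, MOTP, FP, FN, IDSW)
  of tracker output against ground truth, with IoU matching, the
  correspondence-continuity rule and optimal assignment.
- **`antmark.synthetic`** — a seeded correlated-random-walk colony simulator
  (indoor fixed-roster and outdoor nest-entrance regimes) that emits complete
  `img/det/gt` sequence directories with a configurable speed distribution.
- **`antmark.viz` / `antmark` CLI** — trajectory overlays, speed heatmaps and
  histograms, plus subcommands `validate`, `merge`, `summarize`, `speeds`,
  `area`, `evaluate`, `simulate`, `render`.

## Worked example

Simulate an indoor colony (10 ants, 351 frames — the structure of an indoor
laboratory sequence), then summarise, analyse and evaluate it:

```text
$ antmark simulate --mode indoor --ants 10 --frames 351 --seed 1 --out .
3510 gt records -> Seq0001Object10Image94

$ antmark summarize Seq0001Object10Image94/gt/gt.txt
frames annotated: 351
tracks: 10
records: 3510

$ antmark speeds Seq0001Object10Image94/gt/gt.txt \
    --fps 25 --body-length-m 0.0106 --body-length-px 120
mean speed: 2.13 ± 1.31 cm/s over 3510 entries

$ antmark area --height-cm 30 --tilt-deg 45
17 cm × 16 cm, 272 cm²
```

The 3,510 records are 10 ants × 351 frames (every ant present in every
frame, the indoor regime). The pooled speed is the mean ± population SD over
every per-frame speed of every track, in cm/s, using the body-length
calibration L = 10.6 mm over n = 120 px at 25 fps — close to the simulator's
configured 2.16 cm/s target. The `area` line is the ground footprint of a
camera 30 cm above the ground tilted 45°, with the default 16°/7.5° angles of
view.

Evaluating a tracker's output against the ground truth (here the ground
truth against itself — a perfect tracker):

```text
$ antmark evaluate Seq0001Object10Image94/gt/gt.txt Seq0001Object10Image94/gt/gt.txt
{
  "MOTA": 1.0,
  "MOTP": 1.0,
  "FP": 0,
  "FN": 0,
  "IDSW": 0,
  "GT": 3510,
  "matches": 3510,
  "MOTP_distance_px": 0.0
}
```

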
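# Methods

## Annotation model and file dialect

A trajectory dataset is a set of sequences, each a folder triple `img/`
(JPEG frames named `000001.jpg` onward), `gt/gt.txt` and `det/det.txt`.
Annotation lines carry seven comma-separated numeric fields — frame, id, box
left, box top, box width, box height, confidence — with the box given by its
top-left corner in 0-based pixel coordinates (origin top-left, y down).
Frame indices are 1-based to match the image file names. Ground-truth lines
have id ≥ 1 and a 0/1 confidence flag ("consider this entry"); detection
lines have id −1 and a detector score. On write, records are sorted by
(frame, id), integers are printed without a decimal point and reals with the
shortest round-trip representation, so write→read is the identity on the
record set. Whether pixel coordinates are 0- or 1-based is not fixed by the
format; we fix 0-based and document it here. The reader rejects malformed
lines, role-invariant violations and duplicate (frame, id) pairs, but box
positivity and the confidence flag are deliberately checked by `qc` rather
than the loader, so damaged files can be loaded for inspection
(`SequenceAnnotations(..., validate=False)`).

The bundled manifest (`antmark/data/table1.yaml`) records the filming
parameters of the ten-sequence ant video collection the toolkit targets:
five indoor laboratory sequences (25 fps, 1920×1080, 10 ants each) and five
outdoor sequences (30 fps, 1280×720, 73–193 ants, four of them at a nest
entrance), totalling 5,354 frames and 712 ants. Its `body_length_px` values
are *estimates* reconstructed from the printed scene widths (1920 px / 17 cm
indoor, 1280 px / 17 cm outdoor) and the species' published body-length
ranges (midpoints: 10.6 mm indoor, 9 mm outdoor); the true per-sequence
pixel calibration was never published, which bounds how exactly any speed
statistic computed from the deposit can be reproduced.

## The marking state machine

One session marks one object across a whole sequence. A click on the
object's centre stores the centre and a square box of side Z (the Z of the
image-set name `Seq{X}Object{Y}Image{Z}`), corner = round(centre − Z/2) with
half-away-from-zero rounding so corners are integer pixels. Advancing
exposes the previous frame's mark as a reference point; the most recent mark
is carried forward across unmarked frames (the behaviour across unmarked
frames was a free choice; carrying forward keeps the reference useful when
an ant was absent). A start frame of 0 is the "begin at the first frame"
sentinel. The session writes the object's 7-field file after every mutating
event, which is what makes resume-from-interruption work; the cost is that a
resumed session sees centres quantised to the stored integer corners
(≤ 0.5 px). Marking an object absent from a frame is this implementation's
extension — the original workflow does not state how absence is encoded —
and simply removes the frame's record. Merge concatenates per-object files,
enforces ID uniqueness across objects (IDs are user-chosen, so uniqueness
cannot be assumed) and sorts by (frame, id).

## Quality control

`check_sequence` reports issues as data, never exceptions. Errors are
violated structural invariants: duplicate (frame, id), non-positive box,
confidence flag outside {0, 1}. Warnings are suspicious-but-legal patterns:
track gaps (outdoor ants legitimately exit), box centres outside the image
(corner overhang from edge clicks is silent), and single-frame jumps above a
threshold of 5 body lengths per frame. The teleport threshold is a
heuristic for what a human reviewer would catch visually — no numeric rule
exists in the workflow being reproduced — and is configurable.
`segment_report` clusters error frames whose spacing is at most the window
parameter into inclusive (first, last) segments for targeted remarking.

## Speed kinematics

Speeds come from box centres (the natural reading, since marks are centre
clicks): pixel displacement between adjacent frames, times L/n metres per
pixel, times f_c frames per second. Each track's first speed is 0 (ants
assumed stationary at the initial moment). Displacement is defined only
between adjacent frames: across a gap the speed is undefined, the missing
frames are recorded, and the track restarts at 0 — averaging across the gap
would fabricate a straight-line speed. The headline statistic pools every
(track, frame) speed from all tracks, including the forced zeros, and uses
the population SD (divisor N: the frames are a census, not a sample);
per-track means are available as an alternative pooling. The histogram uses
0.25 cm/s bins by default; the heatmap grid defaults to 36×64 cells for 16:9
frames, each cell holding the mean of the speeds whose position falls in it.

## Camera footprint geometry

A camera at height H, tilted α from the vertical plane's horizontal
direction, with angular half-extent β about its axis, images the ground
segment BD = H·(tan(α+β) − tan(α−β)). The printed angles of view (16°
horizontal, 7.5° vertical) are used directly as β: the derivation's
construction treats them as half-angles, and with H = 30 cm this is the only
convention that reproduces the published 17/8/16/11 cm scene dimensions, so
we follow it and flag the ambiguity. The width always uses α = 0 (the tilt
is purely vertical — consistent with every scene printing a 17 cm width).
Dimensions are rounded to whole centimetres and the area is the product of
the rounded dimensions (136 = 17 × 8). |α| + β ≥ 90° means the view cone
reaches the horizon; the footprint is unbounded and the function raises.

## CLEAR-MOT evaluation

Matching is per frame by IoU of axis-aligned boxes with threshold 0.5 by
default (the convention of the format's ecosystem; the workflow itself names
neither measure nor threshold). Correspondences from the previous frame are
kept first when still above threshold (the continuity rule), then the
remaining boxes are assigned by the Hungarian method on a cost matrix with
below-threshold pairs masked infeasible — which maximises the number of
valid matches and, among those, total IoU, and provably equals brute-force
enumeration (property-tested against a permutation oracle for ≤ 4 boxes per
side). Identity switches compare a ground-truth track's matched prediction
ID with its *last* matched ID, so a switch across an occlusion gap is
counted. MOTA = 1 − (FN+FP+IDSW)/GT; MOTP is reported as mean IoU over
matches (higher is better) with a mean centre-distance variant alongside.
Ground-truth confidence-0 records are excluded; prediction confidences are
ignored.

## Synthetic colony generator

The generator exists so that the full pipeline — marking, merging, QC,
kinematics, evaluation, rendering — is exercisable without the video
deposit. Motion is a correlated random walk: heading increments are normal
with SD σ = √(−2 ln ρ) so that ρ = E[cos Δθ] is the configured persistence
(default 0.9); step lengths are Gamma with shape 4 (moderate, right-skewed
variability); a pause (step 0) occurs with probability 0.1 per frame. The
Gamma mean is set to v̄·n/(L·f_c·(1−p_pause)) pixels so the expected
per-frame speed *as measured by the kinematics module* equals the configured
mean speed. Indoor walls deflect by re-drawing the heading until the step
stays inside — turning rather than shortening, so wall interactions do not
bias the speed distribution; outdoor boundaries absorb (the ant exits and
its track ends, IDs never reused). Defaults mirror the filmed regimes:
indoor 10 ants × 351 frames at 25 fps in 1920×1080 with 94 px boxes and a
2.16 cm/s mean; the outdoor preset 73 ants × 600 frames at 30 fps in
1280×720 at a central nest entrance with a 1.98 cm/s mean, 30 % of ants
present at frame 1 and the rest entering at uniformly random frames.

What the generator does *not* emulate: interaction between ants (following,
antennation, clustering), heteroscedastic annotator error, perspective
foreshortening in tilted scenes, and appearance realism beyond a dark
oriented elliptical blob per ant. Tests passing on synthetic data therefore
demonstrate the correctness of the bookkeeping and the statistics under the
stated motion model, not behavioural fidelity to real colonies.

`degrade_to_detections` derives detection-role files from ground truth: IDs
−1, confidence 1, optional integer Gaussian position jitter, independent
record drops at a false-negative rate, and at most one spurious box per
frame at a false-positive rate.

## Problem sizes and numerical choices

The test suite runs on small sequences (3–10 ants, 20–500 frames, images
down to 160×120), chosen so the full pipeline — including rendering and
property-based tests — completes in seconds while leaving every statistical
check enough samples (parameter recovery uses 10 ants × 500 frames ≈ 5,000
speed entries, asserted within 3·SEM of the configured mean). All
randomness flows through a single seeded NumPy generator per simulation;
renders, replays and serialisations are deterministic given identical
inputs. Known limitations: resumed sessions see quantised click centres
(≤ 0.5 px); speed statistics from real deposits inherit the unpublished
pixel-calibration uncertainty described above; and the CLEAR-MOT module
implements the CLEAR core only (no IDF1/HOTA identity-association family).
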
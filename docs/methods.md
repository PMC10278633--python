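# Methods

## The estimation problem

The withdrawal time of a colonoscopy — the time spent actively inspecting
the colonic mucosa while the endoscope is withdrawn — is a recognised
quality indicator (a minimum of 6 minutes is widely recommended).  Naively
it is measured from cecal intubation to scope removal, but that interval
also contains cleaning (washing, suction) and therapeutic work (injection,
position optimisation, polypectomy, resection inspection, forcep use),
which should not be credited as inspection.  `colowt` implements the
estimation pipeline around two pluggable per-frame predictors:

1. **Cecum trigger.**  A segmentation backend emits a three-channel
   probability map per frame (appendiceal orifice AO, ileocecal valve ICV,
   background).  Pixels are assigned to their argmax channel; 4-connected
   components with area ≥ `min_area_fraction` of the frame (default 0.001)
   become detection boxes with the mean in-component class probability as
   confidence.  The first frame with any AO or ICV box triggers the start
   of withdrawal; detection then stops and classification begins.

2. **Phase classification.**  Three binary classifiers (cleaning,
   therapeutic, forcep) emit per-frame positive-class probabilities.  The
   forcep label is positive for *both* the therapeutic and the forcep
   model: therapeutic blocks last minutes and tolerate a long smoothing
   window, whereas forcep biopsies last seconds and would be erased by it,
   so they get their own short-window classifier.  Each stream passes
   through, in order:

   * binarisation at `cut_point` (default 0.5, the two-class argmax);
   * a **majority-vote filter** over a centred window of `n` frames
     (defaults: 20 for cleaning and forcep, 200 for therapeutic).  The
     window for frame *i* spans `[i − ⌈(n−1)/2⌉, i + ⌊(n−1)/2⌋]`
     intersected with the stream (it shrinks at the boundaries; for even
     `n` the extra frame sits on the left).  Exact ties vote negative,
     favouring specificity;
   * a **confidence threshold** θ (default 0.15) that demotes surviving
     positives whose *raw* score is `< θ` and never promotes negatives.

   The three binary streams are merged with a logical OR: a frame is
   discarded if any model claims it, because phases can overlap.

3. **Withdrawal time.**  With `n_total` frames, `n_insertion` frames
   strictly before the trigger, `n_excluded` OR-merged positives at/after
   the trigger and frame rate `f`:

   `t_final = (n_total − n_insertion − n_excluded) / f`

   Subtracting the merged union rather than per-class counts means a frame
   labelled both cleaning and therapeutic is discarded once, not twice;
   per-class counts are reported alongside for bookkeeping.  The trigger
   frame itself is the first withdrawal frame.  If the cecum is never
   detected the estimate is flagged invalid and no time is reported.

## Evaluation

Per-frame sensitivity `TP/(TP+FN)` and specificity `TN/(TN+FP)` are
computed on frames at/after the ground-truth cecum frame only, since the
pipeline never classifies insertion.  Detection is scored per frame with
an IoU ≥ `iou_min` (default 0.25) box match per class, and for the
combined "both" row by presence alone (detecting the cecum matters more
than which landmark was recognised); per procedure by whether the
structure was ever matched; and temporally by the time to detection
`t_detection = t_model − t_groundtruth`, the lag in frames from a
landmark's first appearance to its first matched detection.  Low-quality
landmark frames are excluded from detection evaluation by default.
Procedure-level timing error is reported in seconds per minute of true
withdrawal, `|pred − gt| / (gt/60)`, averaged over procedures (a pooled
variant, total error over total minutes, is also computed).  A six-minute
audit compares prediction and ground truth against the ≥ 360 s criterion.

## Dataset splitting

Procedures are described by 11 per-class frame counts (AO, ICV, washing,
suction, injection, position optimisation, polypectomy, resection
inspection, forcep, NBI, NBI-NF), z-scored (counts span orders of
magnitude) and clustered with k-means (default k = 5, deterministic per
seed).  Each cluster is shuffled and allocated 70/20/10 to
train/test/val by largest-remainder rounding, so global proportions are
within one procedure per cluster of the targets; the no-patient-overlap
invariant is enforced.  Training pools are balanced by subsampling every
positive subclass to the size of its smallest sibling and adding
negatives at 2× the positive count (the detection task uses 0.5×); when
negatives run short, all are taken and a warning recorded.

## The synthetic procedure simulator

Real full-procedure videos are private clinical data, so the package
ships a simulator that emulates their structure: an unlabeled insertion
prefix; a cecum event (AO with probability 0.9, ICV 0.8, at least one
forced; boxes fixed over a 2 s visible span, AO in the left half of the
frame and ICV in the right so synthetic maps never overlap); and a
withdrawal region of exploration frames into which excluded phases are
spliced.  Therapeutic blocks (Poisson count, mean 1.25) contain the four
sub-phases in their canonical order; forcep events (Poisson mean 1,
~8 s) may fall inside a block; cleaning bursts arrive at 2.7 per
withdrawal minute (~6.6 s each) and either splice in as new frames or,
with probability 0.2, overlay therapeutic frames to produce dual-labelled
frames.  All durations are log-normal, truncated at one frame.  Defaults
target the per-procedure budget of roughly 5 min insertion, 7:35 of
exploration, 2:59 of cleaning and 3:21 of therapeutic work at 30 fps.
Because excluded phases are never overlaid on exploration frames, the
ground-truth withdrawal time equals the sampled exploration duration
exactly.

Score emission is calibrated to an operating point: a frame's score lands
on the correct side of 0.5 with probability equal to the model's
sensitivity (positives) or specificity (negatives), with Beta(2,2)
magnitudes within each half; defaults are the three classifiers'
unfiltered operating points (cleaning 0.80/0.89, therapeutic 0.92/0.85,
forcep 0.88/0.99).  A two-state Markov process can additionally mirror
short bursts of frames (geometric mean length, default 3) across 0.5,
emulating the short runs of wrong predictions the vote filter removes.
Synthetic segmentation maps fill each ground-truth box with class
probability 0.9 over background; channels sum to one per pixel.

What the simulator does *not* model: appearance (no pixels beyond the
probability maps), camera motion, gradual phase transitions, correlated
classifier errors near phase boundaries, bubbles or debris, and
low-quality landmark views.  Passing tests therefore demonstrate the
correctness of the post-processing, timing, evaluation and splitting
machinery under calibrated noise — not the accuracy of any real
classifier.

## Numerical and design notes

* **Vote-filter boundary bias.**  With an even window the onset frame of
  a long positive segment sees an exact tie and votes negative, so even
  error-free input loses one frame per segment onset at the default
  windows, and excluded segments shorter than about half the window are
  voted out entirely.  The exact-recovery (oracle) tests therefore run
  the pipeline with the identity filter (`n = 1`, which the filter
  contract defines as a no-op); the default-window runs quantify the
  residual bias instead of hiding it.
* Ties vote negative; thresholding compares `score ≥ θ` so θ = 0 is the
  identity; binarisation is strict (`score > cut_point`).
* The threshold is applied to the positive-class softmax probability.
* NBI/NBI-NF frames are negative for all three classifiers and count
  toward withdrawal time; they enter only as split features.  Whether
  narrow-band inspection should count as exploration is a clinical
  judgement call — the package includes it and flags the choice here.
* Box coordinates are 0-based half-open `(x = column, y = row)`;
  detection frames where predicted and ground-truth boxes exist but do
  not match count one FP *and* one FN for that class.
* Probability maps are stored as three 16-bit grayscale PNGs per frame
  (suffixes `.ao`/`.icv`/`.bg`, scaled to [0, 65535]); quantisation error
  is below 1e-4 per pixel.
* `k` for the split clustering is a free parameter; the default 5 is
  small relative to a ~100-procedure cohort yet separates
  therapeutic-heavy from clean procedures.
* Problem sizes: the simulated study runs 20 full-length procedures
  (~20–35 k frames each); the split contract is exercised on 96 shortened
  procedures (the contract depends only on counts, not durations);
  calibration checks use a single ~140 k-frame procedure.

## Limitations

The pipeline's accuracy on real video is bounded by the plugged-in
classifiers; all quantities reported by the test-suite and the acceptance
script are properties of the pipeline under calibrated synthetic noise.
The cecum trigger is irrevocable — a false detection during insertion
starts the timer early, and only specificity of the detector guards
against it.
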
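# colowt — automated withdrawal-time estimation for colonoscopy

The withdrawal time — the time an endoscopist spends actively inspecting
the colon while withdrawing the scope — is a key colonoscopy quality
indicator (guidelines recommend ≥ 6 minutes).  Measuring it properly
requires subtracting the cleaning (washing/suction) and therapeutic
(polyp-removal) phases that interrupt inspection, which is rarely done by
hand.  `colowt` implements the full estimation pipeline around pluggable
per-frame neural predictors, for researchers building or evaluating
colonoscopy quality-metric systems:

* **cecum trigger** — post-processes segmentation probability maps of the
  appendiceal orifice (AO) and ileocecal valve (ICV) into detection boxes;
  the first detection of either landmark starts the withdrawal phase;
* **phase classification post-processing** — per-model binarisation,
  centred majority-vote temporal filtering (window 20 frames for cleaning
  and forcep, 200 for therapeutic), confidence thresholding (θ = 0.15) and
  a logical-OR merge of the three binary streams;
* **withdrawal-time formula** —
  `t_final = (n_total − n_insertion − n_excluded) / f`,
  with `n_insertion` the frames before the first AO/ICV frame and
  `n_excluded` the merged positives after it;
* **evaluation** — per-frame sensitivity/specificity, false-negative
  breakdown per subclass, time to detection
  `t_detection = t_model − t_groundtruth`, per-procedure
  seconds-per-minute time error and the six-minute audit;
* **cluster-stratified 70/20/10 splitting** and class-balanced training
  subsampling;
* a **synthetic procedure simulator** (timelines, calibrated noisy score
  streams, segmentation maps) standing in for private clinical video, so
  the whole pipeline is testable end to end.

## Worked example

Simulate a procedure, emit noisy classifier scores, run the pipeline and
compare with ground truth:

```python
import colowt
import colowt.io as cio

cfg = colowt.SimulationConfig(seed=7)          # ~30 fps, ~17 min procedure
t = colowt.generate_timeline(cfg)
gt = colowt.ground_truth_withdrawal(t)

scores = {m: colowt.emit_scores(t, cfg, m) for m in colowt.MODEL_NAMES}
est = cio.run_pipeline(scores, cio.PipelineConfig(),
                       cecum_frame=t.first_cecum_frame())

print(t.ntotal, est.cecum_frame)               # 31471 8624
print(gt.t_final_s, gt.t_final_mmss)           # 475.4 7:55
print(est.t_final_s, est.t_final_mmss)         # 484.96666666666664 8:05
```

The simulated procedure has 31,471 frames at 30 fps; the cecum appears at
frame 8,624.  The true withdrawal time (exploration only) is 475.4 s
(7:55); with classifier noise at the default operating points the pipeline
estimates 485.0 s (8:05) — a 9.6 s error on a ~7.9-minute withdrawal,
about 1.2 s per minute.  With noiseless scores the estimate equals the
ground truth exactly.

The same is available from the shell (the `simulate` command derives one
seed per procedure, here `7000`; its procedure has 31,225 frames with the
cecum at frame 7,407, and the estimate prints `"t_final_s": 497.03…`,
`"t_final_mmss": "8:17"` along with all frame counts and a per-stage log):

```sh
colowt simulate --seed 7 --n-procedures 1 --out-dir sim/
colowt estimate --cecum-frame 7407 \
    --cleaning-scores sim/sim-0000007000.cleaning.scores.csv \
    --therapeutic-scores sim/sim-0000007000.therapeutic.scores.csv \
    --forcep-scores sim/sim-0000007000.forcep.scores.csv
colowt split --features features.csv --k 5 --seed 0 --out split.csv
```

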
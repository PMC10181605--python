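"""Evaluate a trained model by decision time and by sHOT bin.

Slides a (quickly trained) 10 s model over every test period, pools the
26 decisions per period, and prints specificity for asystole stratified
by the hands-off-time bins — the analysis at the heart of the sliding
strategy: accuracy is worst during uninterrupted compressions
(sHOT = 0) and climbs as clean seconds accumulate in the window. The
`aha_pass` column flags the per-class AED performance goals.
"""

import pandas as pd

from cprshock import (TrainConfig, make_dataset, materialize_windows,
                      performance_vs_shot, performance_vs_time,
                      predict_sliding, select_operating_point, train)

# Enriched-VF demonstration mix: the real-life OHCA mix (6% VF) needs a
# far larger cohort before the rare class is learnable (docs/methods.md).
DEMO_MIX = {"VF": 0.30, "NSR": 0.05, "ONR": 0.25, "ASYS": 0.40}
ds = make_dataset(n_patients=100, class_mix=DEMO_MIX, seed=11)
pids = ds.manifest.set_index("poi_id")["patient_id"]
learn = ds.split("learning")
windows = materialize_windows(learn, 10, [pids[p.poi_id] for p in learn])
res = train(windows, TrainConfig(max_epochs=70, patience=69, runs=1, seed=3))
op = select_operating_point(res.val_scores, res.val_labels)

advice = pd.concat(
    (predict_sliding(res.classifier, poi, 10, op.threshold)
     for poi in ds.split("test")),
    ignore_index=True,
)
print(f"{len(advice)} advices (26 per period, theta = {op.threshold:.3f})\n")

by_shot = performance_vs_shot(advice, 10)
print("specificity for asystole vs. sHOT (n = pooled windows per bin):")
print(by_shot.query("label == 'ASYS' and n > 0")
      .loc[:, ["shot_bin", "n", "metric", "ci_lo", "ci_hi", "aha_pass"]]
      .round(3).to_string(index=False))

by_time = performance_vs_time(advice, 10)
late = by_time.query("label == 'ASYS' and decision_time in (-5, 0, 5, 10)")
print("\nspecificity for asystole vs. decision time (CC stop at 0 s):")
print(late.loc[:, ["decision_time", "n", "metric"]].round(3).to_string(index=False))
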
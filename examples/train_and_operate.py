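"""Train the 10 s shock-advisory CNN on a synthetic cohort.

Materialises the 26x sliding-window expansion of the learning split,
trains the 27,681-parameter fully convolutional network with the
class-weighted loss, and selects the decision threshold on the
validation ROC by maximising Se + Sp. Runs in a few minutes on one CPU
core; enlarge the cohort and epoch budget for real experiments.
"""

from cprshock import (TrainConfig, make_dataset, materialize_windows,
                      roc_curve, select_operating_point, train)

# Enriched-VF demonstration mix: the real-life OHCA mix (6% VF) needs a
# far larger cohort before the rare class is learnable (docs/methods.md).
DEMO_MIX = {"VF": 0.30, "NSR": 0.05, "ONR": 0.25, "ASYS": 0.40}
ds = make_dataset(n_patients=100, class_mix=DEMO_MIX, seed=11)
pids = ds.manifest.set_index("poi_id")["patient_id"]
learn = ds.split("learning")
windows = materialize_windows(learn, duration=10,
                              patient_ids=[pids[p.poi_id] for p in learn])
print(f"learning windows: {windows.X.shape[0]} "
      f"({int(windows.y.sum())} shockable) of {windows.X.shape[1]} samples")

res = train(windows, TrainConfig(max_epochs=70, patience=69, runs=1, seed=3))
hist = res.histories[res.best_run]
print(f"stopped after {len(hist)} epochs; "
      f"best validation loss {res.best_val_loss:.4f}")

_, auc = roc_curve(res.val_scores, res.val_labels)
op = select_operating_point(res.val_scores, res.val_labels)
print(f"validation ROC-AUC: {auc:.3f}")
print(f"operating point: theta = {op.threshold:.3f} "
      f"(Se = {op.se:.3f}, Sp = {op.sp:.3f}, Se+Sp = {op.criterion:.3f})")
print("Advise shock whenever the network's pSh is >= theta.")
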
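"""Supervised per-sample labeling with a depth-10 decision tree.

Trains on the rater-union labels of one recording (features: smoothed
angular speed and head angle), reports contiguous-block 5-fold CV
accuracy, and turns the per-sample predictions into pruned events.
"""

import numpy as np

from headmov import (
    SimConfig,
    TreeConfig,
    compute_kinematics,
    labels_to_events,
    merge_raters,
    prune_short_intervals,
    simulate_trace,
    tree_classify,
    tree_cv_accuracy,
    tree_features,
    tree_train,
)

sim = simulate_trace(SimConfig(seed=9, n_trials=20))
kin = compute_kinematics(sim.trace)
union = merge_raters(sim.rater_labels)

cfg = TreeConfig()
features = tree_features(kin, cfg)
acc = tree_cv_accuracy(features, union, cfg)
model = tree_train(features, union, cfg)
pred = tree_classify(model, features, kin.timestamps)

rater_events = labels_to_events(union)
mean_dur = float(np.mean([e.duration for e in rater_events]))
events = prune_short_intervals(labels_to_events(pred), mean_dur,
                               cfg.min_interval_fraction)

print(f"5-fold CV accuracy: {acc:.3f} (majority class rate "
      f"{max(np.mean(union.moving), 1 - np.mean(union.moving)):.3f})")
print(f"tree depth {model.get_depth()} (limit {cfg.max_depth})")
print(f"{len(rater_events)} rater-coded movements -> {len(events)} tree events "
      f"after dropping intervals shorter than half the rater mean "
      f"({0.5 * mean_dur * 1000:.0f} ms)")
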
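"""Consolidate noisy per-beat decisions into AF episodes.

Flips a handful of isolated beats in otherwise perfect labels, then
shows how the (window, threshold) grid search removes them.
"""

import numpy as np

from afdetect import beats_to_episodes, evaluate, grid_optimize, smooth_labels

rng = np.random.default_rng(3)
reference = np.array(([-1] * 300 + [1] * 300) * 2)   # two long AF episodes
predicted = reference.copy()
flips = rng.choice(len(predicted), size=20, replace=False)
predicted[flips] = -predicted[flips]

print(f"before smoothing: {len(beats_to_episodes(predicted))} detected episodes "
      f"(reference has {len(beats_to_episodes(reference))}), "
      f"FS = {evaluate(predicted, reference).fs:.2f}%")

best, surface = grid_optimize(predicted, reference)
smoothed = smooth_labels(predicted, best)
print(f"grid search over {len(surface)} (w, p) cells -> "
      f"optimum w={best.w} beats, p={best.p}%")
print(f"after smoothing: {len(beats_to_episodes(smoothed))} episodes, "
      f"FS = {evaluate(smoothed, reference).fs:.2f}%")
print("isolated single-beat flips vanish; the detected episodes now match "
      "the reference runs.")
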
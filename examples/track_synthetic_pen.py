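"""Track a small synthetic pen and inspect tracker behavior.

Generates a one-minute scenario with the default corruption (5% missed
detections, 2 px box jitter, noisy embeddings, one visually confusable
pair), runs the appearance+motion tracker on every third frame, and
reports how well tracks recover the true identities.
"""

import numpy as np

from feedtrack import ScenarioConfig, evaluate_against_truth, run_synthetic

cfg = ScenarioConfig(duration_s=60.0, seed=1)
gt, rendered_by_frame, result = run_synthetic(cfg)

print(f"{cfg.n_individuals} individuals, {result.counts['sampled_frames']} sampled "
      f"frames, {result.counts['detections']} detections")
print(f"tracks spawned: {result.counts['tracks_spawned']} "
      "(a handful above the herd size: occasional gate rejections respawn)")

m = evaluate_against_truth(gt, rendered_by_frame, result)
print(f"track identity accuracy: {m['identity_accuracy']:.4f}")
print(f"mAP@0.5 = {m['map50']:.3f}, mAP@0.5:0.95 = {m['map50_95']:.3f}")
print("identity confusion (rows true, cols predicted):")
print(np.array2string(m["identity_confusion"]))
# With vote-pooled track identities, per-detection score confusions of
# the confusable pair are almost entirely absorbed.
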
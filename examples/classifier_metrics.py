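"""Per-class evaluation metrics for a frame-level image classifier.

Builds a small truth/prediction label set, computes the confusion
matrix and the per-class metric table, and shows the reconstruction of
derived metrics from published summary rates alone.
"""

import numpy as np

import preyfield as pf

rng = np.random.default_rng(0)
classes = ["krill", "open_water", "surface"]
truth = rng.choice(classes, 500, p=[0.3, 0.4, 0.3])
# a classifier that is right 75% of the time, else confuses with open water
predicted = np.where(rng.uniform(size=500) < 0.75, truth, "open_water")

m = pf.confusion(truth, predicted)
print("confusion matrix (rows = truth):")
print(m.counts.to_string())
print(f"\noverall accuracy: {pf.overall_accuracy(m):.3f}")
print()
print(pf.metrics_table(m).round(3).to_string(index=False))
print()
print("accuracy_threat_score is TP/(TP+FP+FN): unlike standard accuracy it")
print("ignores the true negatives that dominate one-vs-rest evaluations.")

# When only summary rates are published, derived metrics are recoverable:
cm = pf.metrics_from_rates(recall=0.63, precision=0.83, prevalence=0.26, n_total=1000)
print(f"\nfrom rates (recall 0.63, precision 0.83, prevalence 0.26, n=1000):")
print(f"  F1 {cm.f1:.2f}, NPV {cm.npv:.2f}, balanced accuracy "
      f"{cm.balanced_accuracy:.2f}, threat score {cm.accuracy_threat_score:.2f}")
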
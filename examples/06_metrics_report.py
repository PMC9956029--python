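"""Evaluation metrics: confusion-matrix reduction and one-vs-rest ROC/AUC."""

import numpy as np

from echopat.evaluate import multiclass_metrics, roc_ovr

# a 3-class confusion matrix (rows = truth, cols = prediction)
cm = np.array([[48, 1, 1], [2, 45, 3], [0, 2, 48]])
report = multiclass_metrics(cm, classes=("normal", "fluid", "deposits"))

print("overall accuracy:", round(report.overall_accuracy, 4))
for cls, m in report.per_class.items():
    print(f"{cls:9s} sens {m.sensitivity:.3f}  spec {m.specificity:.3f}  "
          f"prec {m.precision:.3f}  F1 {m.f1:.3f}")
print("macro:", {k: round(v, 4) for k, v in report.macro.items()})

rng = np.random.default_rng(0)
labels = rng.integers(0, 3, 300)
scores = rng.normal(size=(300, 3)) + 1.5 * (labels[:, None] == np.arange(3))
roc = roc_ovr(scores, labels)
print("\none-vs-rest AUCs:", {c: round(r["auc"], 3) for c, r in roc.items()})
print("\nEach AUC is the probability that a random positive outscores a")
print("random negative for that class; 0.5 is chance, 1.0 is perfect.")
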
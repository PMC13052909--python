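"""Evaluation metrics from predicted stroke probabilities.

Computes the confusion matrix, threshold scores and ROC/AUC for a toy
set of predictions, then shows AUC's rank interpretation.
"""

import numpy as np

import fedstroke as fs

labels = np.array([1, 1, 1, 0, 0, 0, 0, 1])
probs = np.array([0.92, 0.71, 0.45, 0.30, 0.62, 0.08, 0.19, 0.83])

report = fs.evaluate_predictions(labels, probs, threshold=0.5)
print(f"confusion: TP={report.tp} FP={report.fp} TN={report.tn} FN={report.fn}")
print(f"accuracy:  {report.accuracy:.3f}")
print(f"precision: {report.precision:.3f}")
print(f"recall:    {report.recall:.3f}")
print(f"F1:        {report.f1:.3f}")
print(f"AUC:       {report.auc:.3f}")

# AUC equals the probability that a randomly chosen stroke case gets a
# higher score than a randomly chosen normal case (Mann-Whitney):
pos, neg = probs[labels == 1], probs[labels == 0]
pairs = [(p > n) + 0.5 * (p == n) for p in pos for n in neg]
print(f"rank check (U / n1*n0): {np.mean(pairs):.3f}")
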
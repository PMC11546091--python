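"""Evaluation metrics from confusion-matrix counts.

Recomputes the six metrics for two relation-extraction benchmark
confusion matrices and for an end-to-end interaction-prediction run.
"""

from kgppi.metrics import ConfusionMatrix, mcc, report

for name, cm in [
    ("IEPA", ConfusionMatrix(tp=272, tn=272, fp=23, fn=23)),
    ("HPRD50", ConfusionMatrix(tp=141, tn=139, fp=13, fn=11)),
    ("end-to-end pipeline", ConfusionMatrix(tp=1571, tn=2092, fp=3, fn=524)),
]:
    rep = report(cm)
    print(f"{name}: tp={cm.tp} tn={cm.tn} fp={cm.fp} fn={cm.fn}")
    print(f"  sensitivity {rep.sensitivity:.2%}  specificity {rep.specificity:.2%}  "
          f"precision {rep.precision:.2%}")
    print(f"  accuracy {rep.accuracy:.2%}  F1 {rep.f1:.2%}  MCC {mcc(cm):.4f}")

print("\nMCC combines all four cells; values near 1 mean the classifier is "
      "strong on both classes, 0 is chance level.")
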
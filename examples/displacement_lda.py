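"""Predict propidium displacement from two docking-derived variables.

Generates the default 19-compound synthetic study, extracts each
compound's percent overlap with the docked propidium-analog pose and its
binding energy Eb = -ΔG, fits the two-feature linear discriminant, and
reports resubstitution and jackknifed (leave-one-out) accuracy with the
misclassified compounds.
"""

import dockoverlap as d

study = d.make_study()
X, y, ids = d.study_features(study)

model = d.lda_fit(X, y)
print("fitted discriminant:")
print(f"  weights (overlap %, Eb): {model.weights.round(4).tolist()}")
print(f"  threshold: {model.threshold:.4f}")

preds = [d.lda_predict(model, x)[0] for x in X]
print(f"\nresubstitution accuracy: {d.accuracy(preds, list(y)):.1f}%")

loo, table = d.loo_accuracy(X, y, ids)
print(f"leave-one-out accuracy:  {loo:.1f}%  (n = {len(ids)})")
wrong = table.loc[~table["correct"]]
if len(wrong):
    print("misclassified:", ", ".join(wrong["id"]))
else:
    print("no compound misclassified under the jackknife")

print("\nper-case discriminant scores (positive = predicted active):")
print(table[["id", "truth", "prediction", "score"]].round(3).to_string(index=False))
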
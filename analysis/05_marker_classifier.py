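"""Train and validate the two-marker AND-rule classifier.

Per-marker ROC analysis on the discovery cohort's absolute expression,
threshold selection at >= 90% sensitivity for OSC (miR-196b-5p low -> OSC;
miR-107 high -> OSC), then evaluation of the conjunctive classifier on the
independent validation cohort: predict OSC only when both rules agree.
"""

from pathlib import Path

import pandas as pd

from ocumir import io
from ocumir.classifier import (
    classify_cohort,
    evaluate,
    roc_curve,
    threshold_at_sensitivity,
)
from ocumir.pipeline import write_rules

DATA = Path("results/data")
OUT = Path("results/classifier")
OUT.mkdir(parents=True, exist_ok=True)

disc = io.read_marker_table(DATA / "markers_discovery.tsv")
disc_labels = io.read_annotation(
    DATA / "markers_discovery_annotation.tsv"
).set_index("sample_id").loc[disc.index, "group"]

rules = []
for marker, direction in (("miR-196b-5p", "low"), ("miR-107", "high")):
    roc = roc_curve(disc[marker], disc_labels, "OSC", direction)
    rule = threshold_at_sensitivity(roc, 0.9, marker=marker)
    rules.append(rule)
    side = "<=" if direction == "low" else ">="
    calls = classify_cohort([rule], disc[[marker]], "SCCC")
    rep = evaluate(calls, disc_labels, "OSC")
    print(f"{marker}: AUC {roc.auc:.3f}; rule '{marker} {side} "
          f"{rule.threshold:.3f} -> OSC' gives discovery sensitivity "
          f"{rep.sensitivity_pct}% / specificity {rep.specificity_pct}%")
write_rules(rules, OUT / "rules.yaml")

val = io.read_marker_table(DATA / "markers_validation.tsv")
val_labels = io.read_annotation(
    DATA / "markers_validation_annotation.tsv"
).set_index("sample_id").loc[val.index, "group"]
calls = classify_cohort(rules, val, "SCCC")
report = evaluate(calls, val_labels, "OSC")
report.calls.rename_axis("sample_id").to_csv(OUT / "validation_calls.tsv",
                                             sep="\t")
pd.DataFrame([{
    "tp": report.tp, "fn": report.fn, "tn": report.tn, "fp": report.fp,
    "n_indeterminate": report.n_indeterminate,
    "sensitivity_pct": report.sensitivity_pct,
    "specificity_pct": report.specificity_pct,
}]).to_csv(OUT / "validation_report.tsv", sep="\t", index=False)
print(f"combined AND-rule on validation cohort (n={len(val)}): "
      f"sensitivity {report.sensitivity_pct}% "
      f"({report.tp}/{report.tp + report.fn} OSC correct), "
      f"specificity {report.specificity_pct}% "
      f"({report.tn}/{report.tn + report.fp} SCCC correct)")
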
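"""Prognostic contrasts within each tumor type.

Compares metastatic vs non-metastatic SCCC and recurrent vs non-recurrent
OSC.  The simulated outcome flags are independent of expression, so this step
illustrates the negative result the analysis design must be able to report:
nominal hits at roughly the type-I rate and uninformative (high) FDR
q-values, leading to no validated prognostic marker.
"""

from pathlib import Path

import pandas as pd

from ocumir import io
from ocumir.diffexpr import differential_expression
from ocumir.normalization import detectability_filter, median_normalize

DATA = Path("results/data")
OUT = Path("results/prognostic")
OUT.mkdir(parents=True, exist_ok=True)

ct = io.read_ct_table(DATA / "ct_matrix.tsv")
annot = io.read_annotation(DATA / "annotation.tsv")
expr = median_normalize(detectability_filter(ct))

for tumor, flag in (("SCCC", "metastasis"), ("OSC", "recurrence")):
    sub_annot = annot[annot["group"] == tumor].copy()
    sub_annot["group"] = sub_annot[flag].map(
        {True: f"{flag}_yes", False: f"{flag}_no"})
    sub_expr = expr.loc[sub_annot["sample_id"]]
    de = differential_expression(sub_expr, sub_annot,
                                 (f"{flag}_no", f"{flag}_yes"))
    io.write_de_table(de, OUT / f"de_{tumor}_{flag}.tsv")
    tested = de[~de["skipped"]]
    hits = tested[tested["p_value"] < 0.05]
    q_range = (f"{hits['q_value'].min():.1%}-{hits['q_value'].max():.1%}"
               if len(hits) else "n/a")
    print(f"{tumor} {flag}: {len(hits)}/{len(tested)} nominal hits "
          f"(p<0.05), FDR among hits {q_range} -> "
          + ("no robust prognostic candidates" if
             (hits["q_value"] >= 0.25).all() else "candidates warrant follow-up"))
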
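"""Generate the study's input data: a discovery profiling run (377-assay CT
matrix over 14 OSC, 18 SCCC and 12 control samples, with planted tumor-vs-
control and OSC-vs-SCCC effects) plus discovery and validation absolute-
expression tables for the two candidate markers miR-196b-5p and miR-107.

Writes everything under results/data/ so the later analysis steps can load it
from disk exactly as they would a real export.
"""

import sys
from pathlib import Path

from ocumir import io
from ocumir.simulate import (
    MarkerSimConfig,
    SimulationConfig,
    simulate_ct_matrix,
    simulate_marker_expression,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 20220428
OUT = Path("results/data")
OUT.mkdir(parents=True, exist_ok=True)

profiling = SimulationConfig(
    seed=SEED,
    de_fraction=0.1,
    effect_size_ct=2.5,
    contrasts=(("control", "OSC"), ("control", "SCCC"), ("OSC", "SCCC")),
)
ct, annot, truth = simulate_ct_matrix(profiling)
io.write_ct_table(ct, OUT / "ct_matrix.tsv")
io.write_annotation(annot, OUT / "annotation.tsv")
truth.to_csv(OUT / "de_truth.tsv", sep="\t", index=False)
print(f"profiling run: {ct.shape[0]} samples x {ct.shape[1]} assays, "
      f"{ct.isna().to_numpy().mean():.1%} undetected, "
      f"{truth['assay_id'].nunique()} assays with planted effects")

disc, disc_annot = simulate_marker_expression(
    MarkerSimConfig(seed=SEED + 1, n_per_class={"OSC": 14, "SCCC": 18}))
val, val_annot = simulate_marker_expression(
    MarkerSimConfig(seed=SEED + 2, n_per_class={"OSC": 11, "SCCC": 12}))
io.write_marker_table(disc, OUT / "markers_discovery.tsv")
io.write_annotation(disc_annot, OUT / "markers_discovery_annotation.tsv")
io.write_marker_table(val, OUT / "markers_validation.tsv")
io.write_annotation(val_annot, OUT / "markers_validation_annotation.tsv")
print(f"marker tables: discovery n={len(disc)}, validation n={len(val)} "
      f"({', '.join(disc.columns)})")
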
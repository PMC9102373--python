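"""Configuration-driven orchestration of the full study design.

One run covers: simulating or loading a CT matrix plus annotation,
detectability filtering, global-median normalization, per-contrast
differential expression with candidate selection and supervised clustering
(CDT/GTR export), classifier training on a discovery marker table, and
evaluation on an independent validation cohort.  Every output is re-derivable
from the written manifest (config + seed) alone.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, io
from .classifier import classify_cohort, evaluate, roc_curve, threshold_at_sensitivity
from .clustering import supervised_cluster
from .diffexpr import differential_expression, select_candidates
from .normalization import DEFAULT_MAX_CT, detectability_filter, median_normalize
from .simulate import (
    MarkerSimConfig,
    SimulationConfig,
    config_to_dict,
    simulate_ct_matrix,
    simulate_marker_expression,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "write_rules",
           "read_rules"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "results/run"
    # Profiling inputs: either file paths or a simulation spec.
    ct_table: str | None = None
    annotation: str | None = None
    simulate: dict | None = None
    # Marker (validation-assay) inputs: paths or simulation specs.
    marker_discovery: str | dict | None = None
    marker_validation: str | dict | None = None
    marker_directions: dict[str, str] = field(
        default_factory=lambda: {"miR-196b-5p": "low", "miR-107": "high"}
    )
    positive_class: str = "OSC"
    negative_class: str = "SCCC"
    # Analysis thresholds.
    detectability_max_ct: float = DEFAULT_MAX_CT
    p_max: float = 0.05
    fdr_max: float | None = None
    top_k: int | None = None
    min_per_group: int = 3
    min_sensitivity: float = 0.9
    contrasts: list[tuple[str, str]] = field(
        default_factory=lambda: [("control", "SCCC"), ("control", "OSC"),
                                 ("OSC", "SCCC")]
    )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError("unknown config key(s): " + ", ".join(sorted(unknown)))
        cfg = cls(**d)
        cfg.contrasts = [tuple(c) for c in cfg.contrasts]
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def write_rules(rules, path) -> None:
    """Serialize marker rules as a small key-value (YAML) file."""
    payload = [
        {"marker": r.marker, "threshold": float(r.threshold),
         "direction": r.direction, "positive_class": r.positive_class}
        for r in rules
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"rules": payload}, fh, sort_keys=False)


def read_rules(path):
    from .classifier import MarkerRule

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return [MarkerRule(**r) for r in payload["rules"]]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
    return _Ctx()


def _load_profiling(config: PipelineConfig):
    if config.simulate is not None:
        sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
        ct, annot, truth = simulate_ct_matrix(sim)
        return ct, annot, truth, config_to_dict(sim)
    if config.ct_table is None or config.annotation is None:
        return None, None, None, None
    ct = io.read_ct_table(config.ct_table)
    annot = io.read_annotation(config.annotation)
    io.check_annotation_covers(ct, annot)
    return ct, annot, None, None


def _load_markers(spec, seed: int):
    if spec is None:
        return None, None
    if isinstance(spec, str):
        table = io.read_marker_table(spec)
        return table, None
    sim = MarkerSimConfig(**{**spec, "seed": seed})
    table, annot = simulate_marker_expression(sim)
    return table, annot


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
        "stages": [],
        "outputs": {},
    }
    manifest["config"]["contrasts"] = [list(c) for c in config.contrasts]

    with _stage("input"):
        ct, annot, truth, sim_used = _load_profiling(config)
        if ct is not None:
            io.write_ct_table(ct, out / "ct_matrix.tsv")
            io.write_annotation(annot, out / "annotation.tsv")
            if truth is not None:
                truth.to_csv(out / "de_truth.tsv", sep="\t", index=False)
            if sim_used is not None:
                manifest["config"]["simulate"] = sim_used
    manifest["stages"].append("input")

    if ct is not None:
        with _stage("normalize"):
            filtered = detectability_filter(ct, config.detectability_max_ct)
            expr = median_normalize(filtered)
            io.write_ct_table(expr, out / "expression_log2.tsv")
            manifest["outputs"]["expression"] = "expression_log2.tsv"
        manifest["stages"].append("normalize")

        groups = set(annot["group"])
        for contrast in config.contrasts:
            name = f"{contrast[0]}_vs_{contrast[1]}"
            unknown = [g for g in contrast if g not in groups]
            if unknown:
                raise PipelineError(
                    f"stage 'diffexp:{name}' failed: unknown group(s) "
                    + ", ".join(unknown)
                )
            with _stage(f"diffexp:{name}"):
                de = differential_expression(expr, annot, contrast,
                                             config.min_per_group)
                io.write_de_table(de, out / f"de_{name}.tsv")
                cand = select_candidates(de, p_max=config.p_max,
                                         fdr_max=config.fdr_max,
                                         top_k=config.top_k)
                io.write_de_table(cand, out / f"candidates_{name}.tsv")
            manifest["stages"].append(f"diffexp:{name}")

            if len(cand):
                with _stage(f"cluster:{name}"):
                    both = annot["group"].isin(contrast).to_numpy()
                    sub_annot = annot[both]
                    sub_expr = expr.loc[sub_annot["sample_id"]]
                    clust, purity = supervised_cluster(
                        sub_expr, sub_annot, cand["assay_id"].tolist()
                    )
                    io.write_cdt_gtr(clust, sub_expr, out / f"cluster_{name}")
                    purity.to_csv(out / f"purity_{name}.tsv", sep="\t",
                                  index=False)
                manifest["stages"].append(f"cluster:{name}")
            else:
                logger.info("no candidates for %s; clustering skipped", name)

    disc_table, disc_annot = _load_markers(config.marker_discovery,
                                           config.seed + 1)
    if disc_table is not None:
        if disc_annot is None:
            if annot is None:
                raise PipelineError("stage 'classifier' failed: marker table "
                                    "given without sample annotation")
            disc_annot = annot
        with _stage("classifier:train"):
            labels = disc_annot.set_index("sample_id").loc[
                disc_table.index, "group"]
            rules = []
            for marker, direction in config.marker_directions.items():
                roc = roc_curve(disc_table[marker], labels,
                                config.positive_class, direction)
                rules.append(threshold_at_sensitivity(
                    roc, config.min_sensitivity, marker=marker))
            write_rules(rules, out / "rules.yaml")
            manifest["outputs"]["rules"] = "rules.yaml"
        manifest["stages"].append("classifier:train")

        val_table, val_annot = _load_markers(config.marker_validation,
                                             config.seed + 2)
        if val_table is not None:
            with _stage("classifier:evaluate"):
                if val_annot is None:
                    val_annot = annot
                val_labels = val_annot.set_index("sample_id").loc[
                    val_table.index, "group"]
                calls = classify_cohort(rules, val_table,
                                        config.negative_class)
                report = evaluate(calls, val_labels, config.positive_class)
                report.calls.rename_axis("sample_id").to_csv(
                    out / "validation_calls.tsv", sep="\t")
                summary = pd.DataFrame([{
                    "tp": report.tp, "fn": report.fn, "tn": report.tn,
                    "fp": report.fp,
                    "n_indeterminate": report.n_indeterminate,
                    "sensitivity_pct": report.sensitivity_pct,
                    "specificity_pct": report.specificity_pct,
                }])
                summary.to_csv(out / "validation_report.tsv", sep="\t",
                               index=False)
                manifest["outputs"]["validation_report"] = "validation_report.tsv"
            manifest["stages"].append("classifier:evaluate")
        else:
            logger.info("no validation cohort configured; evaluation skipped")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
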
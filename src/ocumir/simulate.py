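"""Synthetic CT matrices and absolute-expression tables with known ground truth.

Real input to the pipeline is a TaqMan low-density-array (TLDA) profiling run:
a samples x assays table of threshold-cycle (CT) values with "Undetermined"
entries for undetected miRNAs, plus single-assay absolute-expression tables for
validation markers.  This module emulates both so every downstream stage —
normalization, differential expression, clustering, classifier training — can
be exercised and calibrated against planted truth without any external data.

The CT model is additive on the cycle scale (multiplicative on expression):

    CT(s, a) = baseline(a) + offset(s) + effect(a, group(s)) + noise(s, a)

with stochastic dropout whose probability rises with CT past a configurable
onset, and a hard instrument cap at 40 cycles above which a well is recorded
as undetected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "MarkerSimConfig",
    "CT_CAP",
    "simulate_ct_matrix",
    "simulate_marker_expression",
]

#: Instrument convention: wells that never cross threshold within 40 cycles
#: are reported as "Undetermined".
CT_CAP = 40.0


@dataclass
class SimulationConfig:
    """Parameters of a simulated TLDA profiling run.

    Defaults mirror a 377-assay human miRNA A-card profiled on a discovery
    cohort of 14 sebaceous carcinomas (OSC), 18 conjunctival squamous cell
    carcinomas (SCCC) and 12 controls.
    """

    n_assays: int = 377
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"OSC": 14, "SCCC": 18, "control": 12}
    )
    #: Fraction of assays planted as differentially expressed per contrast.
    de_fraction: float = 0.1
    #: CT shift (cycles) applied to planted assays in the affected group.
    effect_size_ct: float = 2.0
    #: SD of the per-sample global CT offset (loading / RT efficiency).
    sample_offset_sd: float = 0.5
    #: SD of per-well measurement noise (cycles).
    noise_sd: float = 0.5
    #: CT at which dropout probability starts to rise.
    dropout_base_ct: float = 33.0
    #: Logistic width (cycles) of the dropout ramp.
    dropout_scale: float = 1.5
    #: Range of assay baseline CTs (abundant to rare).
    baseline_ct_range: tuple[float, float] = (18.0, 35.0)
    #: Contrasts receiving planted effects, as (group_a, group_b) pairs.
    contrasts: tuple[tuple[str, str], ...] = (("control", "OSC"), ("control", "SCCC"))
    seed: int = 0

    def validate(self) -> None:
        if self.n_assays < 1:
            raise ValueError("n_assays must be >= 1")
        if not self.group_sizes:
            raise ValueError("group_sizes must name at least one group")
        for g, n in self.group_sizes.items():
            if n < 1:
                raise ValueError(f"group {g!r} must have >= 1 sample, got {n}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        for name in ("effect_size_ct", "sample_offset_sd", "noise_sd",
                     "dropout_base_ct", "dropout_scale"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        if self.sample_offset_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for pair in self.contrasts:
            for g in pair:
                if g not in self.group_sizes:
                    raise ValueError(f"contrast group {g!r} not in group_sizes")


@dataclass
class MarkerSimConfig:
    """Log-normal absolute-expression model for single validation assays.

    ``class_params`` maps marker id -> class label -> (location, scale) of the
    natural-log expression.  Default markers emulate the two discriminating
    miRNAs: miR-196b-5p higher in SCCC, miR-107 higher in OSC, with locations
    straddling the published decision thresholds (1172.258 and 365.4 absolute
    units) and a dispersion typical of FFPE qPCR replicates.
    """

    class_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "miR-196b-5p": {
                "OSC": (math.log(450.0), 0.9),
                "SCCC": (math.log(3200.0), 0.9),
            },
            "miR-107": {
                "OSC": (math.log(1100.0), 0.9),
                "SCCC": (math.log(130.0), 0.9),
            },
        }
    )
    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"OSC": 14, "SCCC": 18}
    )
    seed: int = 0

    def validate(self) -> None:
        if not self.class_params:
            raise ValueError("class_params must name at least one marker")
        for marker, per_class in self.class_params.items():
            for cls, (loc, scale) in per_class.items():
                if not (math.isfinite(loc) and math.isfinite(scale)):
                    raise ValueError(f"non-finite parameters for {marker}/{cls}")
                if scale <= 0:
                    raise ValueError(
                        f"scale must be > 0 for {marker}/{cls}, got {scale}"
                    )
        for cls, n in self.n_per_class.items():
            if n < 1:
                raise ValueError(f"class {cls!r} must have >= 1 sample, got {n}")


def _dropout_probability(ct: np.ndarray, onset: float, scale: float) -> np.ndarray:
    """Logistic detection-failure probability, monotone increasing in CT."""
    z = (ct - onset) / scale
    return 1.0 / (1.0 + np.exp(-z))


def simulate_ct_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a CT matrix, its sample annotation, and the planted-effect record.

    Returns
    -------
    ct : DataFrame, samples x assays
        CT values in cycles; NaN marks undetected wells.
    annotation : DataFrame
        Columns ``sample_id``, ``group``, and boolean outcome flags
        ``metastasis`` / ``recurrence`` (drawn independently per sample so
        prognostic contrasts can be exercised under the null).
    truth : DataFrame
        One row per planted (assay, contrast) effect: ``assay_id``,
        ``group_a``, ``group_b``, ``direction`` (up/down in B vs A),
        ``effect_ct`` in cycles.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    assay_ids = [f"miR-sim-{i:03d}" for i in range(config.n_assays)]
    samples: list[str] = []
    groups: list[str] = []
    for g, n in config.group_sizes.items():
        for i in range(n):
            samples.append(f"{g}-{i + 1:02d}")
            groups.append(g)

    lo, hi = config.baseline_ct_range
    baseline = rng.uniform(lo, hi, size=config.n_assays)
    offsets = rng.normal(0.0, config.sample_offset_sd, size=len(samples))

    # Plant effects: round(de_fraction * n_assays) assays per contrast, each
    # shifted by +/- effect_size_ct in group B relative to group A.
    n_planted = round(config.de_fraction * config.n_assays)
    effect = np.zeros((len(samples), config.n_assays))
    truth_rows = []
    group_arr = np.asarray(groups)
    for group_a, group_b in config.contrasts:
        planted = rng.choice(config.n_assays, size=n_planted, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_planted)
        in_b = group_arr == group_b
        for j, s in zip(planted, signs):
            effect[in_b, j] += s * config.effect_size_ct
            # Lower CT = higher expression, so a negative CT shift is "up".
            truth_rows.append(
                {
                    "assay_id": assay_ids[j],
                    "group_a": group_a,
                    "group_b": group_b,
                    "direction": "up" if s < 0 else "down",
                    "effect_ct": s * config.effect_size_ct,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["assay_id", "group_a", "group_b", "direction", "effect_ct"],
    )

    noise = rng.normal(0.0, config.noise_sd, size=(len(samples), config.n_assays))
    ct = baseline[None, :] + offsets[:, None] + effect + noise

    p_drop = _dropout_probability(ct, config.dropout_base_ct, config.dropout_scale)
    dropped = rng.random(size=ct.shape) < p_drop
    ct = np.where(dropped | (ct > CT_CAP), np.nan, ct)

    ct_df = pd.DataFrame(ct, index=pd.Index(samples, name="sample_id"),
                         columns=assay_ids)
    annotation = pd.DataFrame(
        {
            "sample_id": samples,
            "group": groups,
            "metastasis": rng.random(len(samples)) < 0.5,
            "recurrence": rng.random(len(samples)) < 0.5,
        }
    )
    return ct_df, annotation, truth


def simulate_marker_expression(
    config: MarkerSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample positive absolute-expression values per class.

    Returns a samples x markers table (values on the standard-dilution-series
    scale) and the matching sample annotation.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples: list[str] = []
    classes: list[str] = []
    for cls, n in config.n_per_class.items():
        for i in range(n):
            samples.append(f"{cls}-v{i + 1:02d}")
            classes.append(cls)

    markers = list(config.class_params)
    values = np.empty((len(samples), len(markers)))
    class_arr = np.asarray(classes)
    for k, marker in enumerate(markers):
        per_class = config.class_params[marker]
        for cls in config.n_per_class:
            if cls not in per_class:
                raise ValueError(f"marker {marker!r} lacks parameters for {cls!r}")
            loc, scale = per_class[cls]
            mask = class_arr == cls
            values[mask, k] = rng.lognormal(loc, scale, size=int(mask.sum()))

    table = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"),
                         columns=markers)
    annotation = pd.DataFrame({"sample_id": samples, "group": classes})
    return table, annotation


def config_to_dict(config: SimulationConfig | MarkerSimConfig) -> dict:
    """Serializable view of a simulation config (for run manifests)."""
    d = asdict(config)
    if "contrasts" in d:
        d["contrasts"] = [list(c) for c in d["contrasts"]]
    return d
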
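"""Detectability filtering, global-median delta-Ct normalization, and
standard-curve absolute quantification.

The profiling platform reports threshold cycles (CT); lower CT means more
abundant target.  Each miRNA in a sample is normalized to the median CT of all
detectable miRNAs in that sample, which removes per-sample loading and
reverse-transcription efficiency offsets:

    log2 relative expression(s, a) = median_CT(s) - CT(s, a)

so the per-sample median of the normalized values is 0 and larger values mean
higher abundance.  Single validation assays are quantified absolutely against
a standard dilution series fitted as CT = slope * log10(quantity) + intercept;
a perfectly efficient PCR doubles product every cycle, giving slope
-1/log10(2) = -3.3219 and efficiency (10^(-1/slope) - 1) * 100 = 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "detectability_filter",
    "median_normalize",
    "fit_standard_curve",
    "absolute_quantify",
    "predict_ct",
]

#: Instrument ceiling: CT at or above this is treated as undetected by default.
DEFAULT_MAX_CT = 40.0


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares dilution-series fit CT = slope * log10(quantity) + intercept."""

    slope: float  # cycles per log10 quantity; < 0 for a valid assay
    intercept: float  # cycles at quantity 1
    efficiency: float  # percent; 100 = perfect doubling per cycle
    r_squared: float

    @property
    def valid(self) -> bool:
        return self.slope < 0


def detectability_filter(ct: pd.DataFrame, max_ct: float = DEFAULT_MAX_CT) -> pd.DataFrame:
    """Mask entries with CT >= ``max_ct`` and drop assays undetected everywhere.

    Dropped assays are logged.  An entirely empty result is allowed (with a
    warning) so callers can decide how to proceed.
    """
    if not 0 < max_ct <= 40:
        raise ValueError(f"max_ct must be in (0, 40], got {max_ct}")
    out = ct.mask(ct >= max_ct)
    all_missing = out.columns[out.isna().all(axis=0)]
    if len(all_missing):
        logger.info(
            "dropping %d assay(s) undetected in every sample: %s",
            len(all_missing), ", ".join(map(str, all_missing[:10]))
            + ("..." if len(all_missing) > 10 else ""),
        )
        out = out.drop(columns=all_missing)
    if out.shape[1] == 0:
        logger.warning("no assay detectable in any sample at max_ct=%g", max_ct)
    return out


def median_normalize(ct: pd.DataFrame) -> pd.DataFrame:
    """Global-median delta-Ct normalization to log2 relative expression.

    Missing cells stay missing and are excluded from the per-sample median.
    A sample with zero detectable assays is an error (its median is undefined).
    """
    n_detect = ct.notna().sum(axis=1)
    empty = n_detect.index[n_detect == 0]
    if len(empty):
        raise ValueError("sample(s) with no detectable assay: "
                         + ", ".join(map(str, empty)))
    medians = ct.median(axis=1, skipna=True)
    return ct.rsub(medians, axis=0)


def fit_standard_curve(quantities, cts) -> StandardCurve:
    """Fit the dilution series by ordinary least squares of CT on log10 quantity.

    Replicate CTs at a dilution point enter individually.  A fit with
    non-negative slope is returned but flagged invalid (``curve.valid`` False).
    """
    q = np.asarray(quantities, dtype=float)
    c = np.asarray(cts, dtype=float)
    if q.shape != c.shape:
        raise ValueError("quantities and cts must have equal length")
    if q.size < 3:
        raise ValueError(f"need >= 3 dilution points, got {q.size}")
    if np.any(q <= 0):
        raise ValueError("quantities must be > 0")
    x = np.log10(q)
    if np.ptp(x) == 0:
        raise ValueError("dilution points must span distinct quantities")
    fit = stats.linregress(x, c)
    slope = float(fit.slope)
    efficiency = float((10.0 ** (-1.0 / slope) - 1.0) * 100.0) if slope != 0 else np.nan
    curve = StandardCurve(
        slope=slope,
        intercept=float(fit.intercept),
        efficiency=efficiency,
        r_squared=float(fit.rvalue) ** 2,
    )
    if not curve.valid:
        logger.warning("standard curve has non-negative slope %.4g; "
                       "quantification from it is invalid", slope)
    return curve


def absolute_quantify(cts, curve: StandardCurve):
    """Map CT values to absolute quantities through an inverted standard curve.

    quantity = 10 ** ((CT - intercept) / slope); missing CT yields missing
    quantity.  Accepts a scalar, array, or Series and returns the same shape.
    """
    if not curve.valid:
        raise ValueError("cannot quantify from an invalid standard curve "
                         f"(slope={curve.slope:.4g} >= 0)")
    ct_arr = np.asarray(cts, dtype=float)
    q = 10.0 ** ((ct_arr - curve.intercept) / curve.slope)
    if isinstance(cts, pd.Series):
        return pd.Series(q, index=cts.index, name=cts.name)
    if np.isscalar(cts):
        return float(q)
    return q


def predict_ct(quantities, curve: StandardCurve):
    """Forward standard-curve map: CT = slope * log10(quantity) + intercept."""
    q = np.asarray(quantities, dtype=float)
    ct = curve.slope * np.log10(q) + curve.intercept
    return float(ct) if np.isscalar(quantities) else ct
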
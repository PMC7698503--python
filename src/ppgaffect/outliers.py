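"""Median-absolute-deviation outlier removal over the feature matrix.

Per feature column, the scaled MAD is

    MAD = 1.4826 * median(|x_i - median(x)|)

(the 1.4826 factor calibrates MAD to the standard deviation under
normality) and the acceptance band is median +/- 3*MAD, inclusive.  A row
is removed when ANY of its features falls outside its column's band —
per-row removal keeps the matrix rectangular without imputation.  Bounds
are computed once over the whole matrix (a single pass, before any
train/test split; see the methods note for the leakage caveat).

When a column's MAD is zero the band collapses to the median, so only
values strictly different from the median are flagged — the inclusive
band makes this fall out of the same comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import OutlierFilterError, ValidationError
from .io_core import FeatureMatrix

logger = logging.getLogger(__name__)

MAD_SCALE = 1.4826
MAD_K = 3.0


@dataclass
class MADBounds:
    """Per-feature robust location, scale and acceptance band."""

    median: float
    mad: float
    lower: float
    upper: float


def mad_bounds(values: np.ndarray) -> MADBounds:
    """Median, scaled MAD and the +/- 3*MAD acceptance band of one series."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValidationError("cannot compute MAD bounds of an empty series")
    med = float(np.median(x))
    mad = MAD_SCALE * float(np.median(np.abs(x - med)))
    return MADBounds(med, mad, med - MAD_K * mad, med + MAD_K * mad)


def filter_outliers(fm: FeatureMatrix) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Drop every row with any feature outside its column's MAD band.

    Returns the filtered matrix and a removal report with one line per
    offending (row, feature) pair: row_id, offending_feature, value,
    lower, upper.
    """
    if fm.n_rows < 2:
        raise ValidationError("need >= 2 rows to filter outliers")
    records = []
    keep = np.ones(fm.n_rows, dtype=bool)
    for j, name in enumerate(fm.feature_names):
        b = mad_bounds(fm.values[:, j])
        col = fm.values[:, j]
        out = (col < b.lower) | (col > b.upper)
        for i in np.flatnonzero(out):
            records.append({"row_id": int(i), "offending_feature": name,
                            "value": col[i], "lower": b.lower, "upper": b.upper})
            keep[i] = False
    if not keep.any():
        raise OutlierFilterError(
            "MAD filter removed every row — inspect the feature matrix"
        )
    report = pd.DataFrame(records,
                          columns=["row_id", "offending_feature", "value",
                                   "lower", "upper"])
    report = report.sort_values(["row_id", "offending_feature"]).reset_index(drop=True)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("MAD filter removed %d of %d rows", n_removed, fm.n_rows)
    return fm.subset_rows(keep), report
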
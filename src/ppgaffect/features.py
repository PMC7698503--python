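"""The 26-feature HRV vector computed from one segment's beat series.

Four families, in registry ID order (see ``io_core.FEATURE_NAMES``):

1–5   beat-timing means: instantaneous heart rate, valley→peak and
      peak→valley times, NN and VV interval means;
6–15  interval statistics: RMSSD, SDNN, SDSD, NN range, NN50/NN20 counts
      and percentages, and the coefficients of variation CVSD, CVNNI;
16–21 spectral band powers of the NN tachogram via a Lomb–Scargle
      periodogram: LF (0.04–0.15 Hz), HF (0.15–0.4 Hz), their ratio,
      total power (0–0.4 Hz), and the normalised fractions of LF+HF;
17–26 Poincaré-plot geometry: SD1 (transverse), SD2 (longitudinal),
      their ratio (emitted twice, as SD12 and as the Cardiac Sympathetic
      Index), and the Cardiac Vagal Index log10(4·SD1 · 4·SD2).

Conventions (the source material is silent on all of these, so they are
fixed here and unit-tested):

* ``Mean_HR`` is the mean of instantaneous rates 60000/NN_i, not
  60000 / Mean_NNI.
* SDNN and SDSD use sample (n−1) normalisation, as HRV software usually
  does; RMSSD is the plain root mean square of successive differences.
* SD1 and SD2 use the algebraic ellipse-fitting convention
  SD1 = RMSSD/√2 and SD2² = 2·var_pop(NN) − SD1², so the textbook
  identities SD1² + SD2² = 2·var_pop(NN) and SD1 = RMSSD/√2 hold exactly.
* NN50/NN20 use strict inequality (differences *greater than* 50/20 ms).
* Undefined ratios (zero denominators) are emitted as NaN sentinels;
  rows containing sentinels are dropped, with a logged count, before
  classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .beats import BeatSeries, beat_series_from_segment
from .errors import BeatDetectionError, InsufficientBeatsError, StructuralError
from .io_core import DROPPED, FEATURE_NAMES, FeatureMatrix, Segment

logger = logging.getLogger(__name__)

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


def time_geometric(bs: BeatSeries) -> dict[str, float]:
    """Beat-timing means: Mean_HR, Mean_VP, Mean_PV, Mean_NNI, Mean_VVI."""
    if bs.nn_ms.size < 2:
        raise InsufficientBeatsError("need >= 2 NN intervals for timing means")
    return {
        "Mean_HR": float(np.mean(60000.0 / bs.nn_ms)),
        "Mean_VP": float(np.mean(bs.vp_ms)) if bs.vp_ms.size else np.nan,
        "Mean_PV": float(np.mean(bs.pv_ms)) if bs.pv_ms.size else np.nan,
        "Mean_NNI": float(np.mean(bs.nn_ms)),
        "Mean_VVI": float(np.mean(bs.vv_ms)) if bs.vv_ms.size else np.nan,
    }


def time_statistical(nn_ms: np.ndarray) -> dict[str, float]:
    """Interval statistics over the NN series (IDs 6–15)."""
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 3:
        raise InsufficientBeatsError("need >= 3 NN intervals for statistics")
    d = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(d ** 2)))
    sdnn = float(np.std(nn, ddof=1))
    mean_nni = float(np.mean(nn))
    return {
        "RMSSD": rmssd,
        "SDNN": sdnn,
        "SDSD": float(np.std(d, ddof=1)),
        "Range_NN": float(np.max(nn) - np.min(nn)),
        "NN50": float(np.sum(np.abs(d) > 50.0)),
        "pNN50": float(100.0 * np.sum(np.abs(d) > 50.0) / d.size),
        "NN20": float(np.sum(np.abs(d) > 20.0)),
        "pNN20": float(100.0 * np.sum(np.abs(d) > 20.0) / d.size),
        "CVSD": rmssd / mean_nni,
        "CVNNI": sdnn / mean_nni,
    }


def frequency_features(nn_ms: np.ndarray, peak_times: np.ndarray,
                       df: float = 0.002) -> dict[str, float]:
    """Band powers of the NN tachogram (IDs 16–21).

    The tachogram is irregularly sampled (one NN value at its terminal
    peak time), so a Lomb–Scargle periodogram is used rather than
    resampling: a 10-s window holds only ~10–15 beats, too few for stable
    interpolation.  Band powers integrate the periodogram over LF
    (0.04–0.15 Hz), HF (0.15–0.4 Hz) and 0–0.4 Hz for the total.

    Note that a 10-s window cannot physically resolve the 0.04 Hz LF
    edge; values are computed as defined and a QC message is logged.
    """
    nn = np.asarray(nn_ms, dtype=float)
    t = np.asarray(peak_times, dtype=float)[1:]
    if nn.size < 4:
        raise InsufficientBeatsError("need >= 4 NN intervals for spectra")
    span = t[-1] - t[0]
    if span < 1.0 / LF_BAND[0]:
        logger.debug("tachogram span %.1f s cannot resolve the %.2f Hz LF edge",
                     span, LF_BAND[0])
    x = nn - np.mean(nn)
    freqs = np.arange(df, HF_BAND[1] + df / 2, df)
    if np.allclose(x, 0.0):
        psd = np.zeros_like(freqs)
    else:
        psd = lombscargle(t, x, 2.0 * np.pi * freqs) * 2.0 / x.size
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    lf = float(np.trapezoid(psd[lf_mask], freqs[lf_mask]))
    hf = float(np.trapezoid(psd[hf_mask], freqs[hf_mask]))
    total = float(np.trapezoid(psd, freqs))
    out = {"LF": lf, "HF": hf, "Total_Power": total}
    out["LF_HF_ratio"] = lf / hf if hf > 0 else np.nan
    if lf + hf > 0:
        out["nLFP"] = lf / (lf + hf)
        out["nHFP"] = hf / (lf + hf)
    else:
        out["nLFP"] = np.nan
        out["nHFP"] = np.nan
    return out


def poincare_features(nn_ms: np.ndarray) -> dict[str, float]:
    """Poincaré-plot dispersions and the derived autonomic indices.

    SD1 (spread across the identity line) and SD2 (spread along it) come
    from the algebraic convention SD1 = RMSSD/√2,
    SD2 = sqrt(2·var_pop(NN) − SD1²), under which the classic identities
    hold exactly.  CSI = (4·SD2)/(4·SD1) = SD2/SD1 — numerically the same
    quantity as SD12, but both are emitted because the registry lists
    them separately.  CVI = log10(4·SD1 · 4·SD2).
    """
    nn = np.asarray(nn_ms, dtype=float)
    if nn.size < 3:
        raise InsufficientBeatsError("need >= 3 NN intervals for Poincare features")
    d = np.diff(nn)
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    sd2_sq = 2.0 * float(np.var(nn)) - sd1 ** 2
    sd2 = float(np.sqrt(max(sd2_sq, 0.0)))
    ratio = sd2 / sd1 if sd1 > 0 else np.nan
    prod = 16.0 * sd1 * sd2
    return {
        "SD1": sd1,
        "SD2": sd2,
        "SD12": ratio,
        "CSI": ratio,
        "CVI": float(np.log10(prod)) if prod > 0 else np.nan,
    }


def extract_features(bs: BeatSeries) -> pd.Series:
    """Concatenate the four families into the 26-entry named vector."""
    vals: dict[str, float] = {}
    vals.update(time_geometric(bs))
    vals.update(time_statistical(bs.nn_ms))
    vals.update(frequency_features(bs.nn_ms, bs.peak_times))
    vals.update(poincare_features(bs.nn_ms))
    return pd.Series([vals[name] for name in FEATURE_NAMES],
                     index=list(FEATURE_NAMES), dtype=float)


def extract_matrix(segments: list[Segment], min_rate_bpm: float = 40.0,
                   max_rate_bpm: float = 180.0) -> tuple[FeatureMatrix, dict[str, int]]:
    """Feature matrix from labelled segments, with an accounting report.

    Segments dropped by the rating rule, by beat-detection failure, or by
    a sentinel (NaN) feature value never reach the matrix; the report
    counts each exit path so the row ledger is conserved.
    """
    rows, labels = [], []
    report = {"n_segments": len(segments), "dropped_rating": 0,
              "dropped_beats": 0, "dropped_sentinel": 0, "kept": 0}
    for seg in segments:
        if seg.label is None:
            raise ValueError("segments must be labelled (run assign_labels first)")
        if seg.label == DROPPED:
            report["dropped_rating"] += 1
            continue
        try:
            bs = beat_series_from_segment(seg, min_rate_bpm, max_rate_bpm)
            vec = extract_features(bs)
        except (BeatDetectionError, InsufficientBeatsError, StructuralError) as exc:
            logger.info("segment dropped by beat detection: %s", exc)
            report["dropped_beats"] += 1
            continue
        if vec.isna().any():
            report["dropped_sentinel"] += 1
            continue
        rows.append(vec.to_numpy())
        labels.append(seg.label)
        report["kept"] += 1
    values = np.asarray(rows, dtype=float) if rows else np.empty((0, len(FEATURE_NAMES)))
    fm = FeatureMatrix(FEATURE_NAMES, values, np.asarray(labels, dtype=int))
    if report["dropped_sentinel"]:
        logger.info("%d segment(s) dropped for sentinel feature values",
                    report["dropped_sentinel"])
    return fm, report


def feature_registry() -> list[dict]:
    """Machine-readable registry: ID (1-based), name, family, unit."""
    families = ([("timing", "bpm")] + [("timing", "ms")] * 4
                + [("statistical", "ms")] * 4
                + [("statistical", "count"), ("statistical", "%")] * 2
                + [("statistical", "ratio")] * 2
                + [("spectral", "ms^2")] * 2 + [("spectral", "ratio")]
                + [("spectral", "ms^2")] + [("spectral", "fraction")] * 2
                + [("poincare", "ms")] * 2 + [("poincare", "ratio")] * 2
                + [("poincare", "log10(ms^2)")])
    return [{"id": i + 1, "name": name, "family": fam, "unit": unit}
            for i, (name, (fam, unit)) in enumerate(zip(FEATURE_NAMES, families))]
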
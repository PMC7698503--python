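"""Data model, file I/O, segmentation and label processing.

The package works with four containers:

* :class:`PPGRecording` — a uniformly sampled single-channel pulse waveform;
* :class:`EventTable` — stimulus onsets, durations and 0–3 self-report
  ratings, the source of both segmentation and class labels;
* :class:`Segment` — one stimulus-locked window of the recording;
* :class:`FeatureMatrix` — the n_segments x 26 feature grid plus binary
  labels handed to the outlier filter and the classifiers.

Labels follow the rating rule used throughout: rating 0 maps to class 0
(state not elicited), ratings 2 and 3 map to class 1 (state elicited), and
the ambiguous rating 1 is dropped — kept as an explicit ``DROPPED`` marker
rather than silently deleted, so row counts stay auditable.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    SchemaError,
    SegmentationError,
    ValidationError,
)

logger = logging.getLogger(__name__)

#: Sentinel label for segments whose ambiguous rating (1) excludes them.
DROPPED = -1

#: Canonical feature names, in registry ID order 1–26.  Four families:
#: beat-timing means (1–5), interval statistics (6–15), spectral band
#: powers of the NN tachogram (16–21), and Poincaré-plot geometry (22–26).
FEATURE_NAMES: tuple[str, ...] = (
    "Mean_HR",
    "Mean_VP",
    "Mean_PV",
    "Mean_NNI",
    "Mean_VVI",
    "RMSSD",
    "SDNN",
    "SDSD",
    "Range_NN",
    "NN50",
    "pNN50",
    "NN20",
    "pNN20",
    "CVSD",
    "CVNNI",
    "LF",
    "HF",
    "LF_HF_ratio",
    "Total_Power",
    "nLFP",
    "nHFP",
    "SD1",
    "SD2",
    "SD12",
    "CSI",
    "CVI",
)

N_FEATURES = len(FEATURE_NAMES)


def nearest_sample(time_s: float, fs: float) -> int:
    """Map a time in seconds to the nearest sample index.

    Halves round up; a tiny epsilon absorbs binary-representation error so
    that e.g. 10.0025 s at 200 Hz lands on index 2001, not 2000.
    """
    return int(np.floor(time_s * fs + 0.5 + 1e-9))


@dataclass
class PPGRecording:
    """Uniformly sampled PPG amplitude series.

    Parameters
    ----------
    samples
        Amplitude values, arbitrary units.
    fs
        Sampling rate in Hz; must be positive.
    subject_id, session_id
        Opaque provenance strings.
    """

    samples: np.ndarray
    fs: float
    subject_id: str = ""
    session_id: str = ""

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValidationError("recording needs at least 2 samples in one channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("recording contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "PPGRecording":
        """Copy of this recording with new samples (and optionally new fs)."""
        return replace(self, samples=np.asarray(samples, dtype=float),
                       fs=self.fs if fs is None else fs)


@dataclass
class EventTable:
    """Stimulus events: onset (s), duration (s) and self-report rating 0–3."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    ratings: np.ndarray

    def __post_init__(self):
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        self.durations_s = np.asarray(self.durations_s, dtype=float)
        self.ratings = np.asarray(self.ratings, dtype=int)
        n = self.onsets_s.size
        if self.durations_s.size != n or self.ratings.size != n:
            raise ValidationError("event table columns differ in length")
        if n and np.any(np.diff(self.onsets_s) <= 0):
            raise ValidationError("event onsets must be strictly increasing")
        bad = (self.ratings < 0) | (self.ratings > 3)
        if np.any(bad):
            raise ValidationError(
                f"ratings must be in 0..3; offending rows: {np.flatnonzero(bad).tolist()}"
            )

    def __len__(self) -> int:
        return self.onsets_s.size

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, sep="\t")
        expected = ["onset_s", "duration_s", "rating"]
        if list(df.columns[:3]) != expected:
            raise SchemaError(
                f"event file must start with columns {expected}, got {list(df.columns)}"
            )
        return cls(df["onset_s"].to_numpy(), df["duration_s"].to_numpy(),
                   df["rating"].to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"onset_s": self.onsets_s, "duration_s": self.durations_s,
             "rating": self.ratings}
        ).to_csv(path, sep="\t", index=False)


@dataclass
class Segment:
    """One stimulus-locked window of a recording, with its rating and label."""

    samples: np.ndarray
    fs: float
    rating: int
    label: int | None = None  # 0, 1 or DROPPED once assigned

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class FeatureMatrix:
    """Rows = segments, columns = the 26 named features, plus binary labels."""

    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.feature_names = tuple(self.feature_names)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_names):
            raise ValidationError("feature values shape does not match names")
        if self.labels.size != self.values.shape[0]:
            raise ValidationError("label count does not match row count")
        if self.labels.size and not np.all(np.isin(self.labels, [0, 1])):
            raise ValidationError("labels must be binary 0/1")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df["label"] = self.labels
        return df

    def subset_rows(self, idx: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.feature_names, self.values[idx], self.labels[idx])


_FS_RE = re.compile(r"fs\s*=\s*([0-9.eE+-]+)")


def read_recording(path: str | Path, fs_override: float | None = None,
                   subject_id: str = "", session_id: str = "") -> PPGRecording:
    """Read a delimited-text signal file.

    The file holds one numeric column (amplitude) or two (time, amplitude);
    comma, tab or whitespace delimited.  The sampling rate comes from a
    ``# fs=<Hz>`` header line or from *fs_override* (override wins).
    """
    path = Path(path)
    fs_header: float | None = None
    values: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = _FS_RE.search(line)
                if m:
                    fs_header = float(m.group(1))
                continue
            fields = re.split(r"[,\t\s]+", line)
            try:
                nums = [float(f) for f in fields if f]
            except ValueError:
                raise ParseError(f"{path}: non-numeric data on line {lineno}: {line!r}")
            if not nums:
                continue
            # two-column files carry time in column 1, amplitude in column 2
            values.append(nums[1] if len(nums) >= 2 else nums[0])
    fs = fs_override if fs_override is not None else fs_header
    if fs is None:
        raise ConfigurationError(
            f"{path}: sampling rate not found — add a '# fs=<Hz>' header or pass fs_override"
        )
    return PPGRecording(np.asarray(values), fs=fs,
                        subject_id=subject_id, session_id=session_id)


def write_recording(rec: PPGRecording, path: str | Path) -> None:
    """Write a recording as single-column CSV with an ``# fs=`` header."""
    with open(path, "w") as fh:
        fh.write(f"# fs={rec.fs:g}\n")
        np.savetxt(fh, rec.samples, fmt="%.10g")


def segment_recording(rec: PPGRecording, events: EventTable,
                      window_s: float = 10.0) -> list[Segment]:
    """Cut one left-closed/right-open window per event.

    Sample indices use nearest-sample rounding of ``onset * fs``; every
    window must fit inside the recording.
    """
    n_win = nearest_sample(window_s, rec.fs)
    offending = []
    segments: list[Segment] = []
    for i in range(len(events)):
        start = nearest_sample(events.onsets_s[i], rec.fs)
        stop = start + n_win
        if start < 0 or stop > rec.samples.size:
            offending.append(i)
            continue
        segments.append(Segment(rec.samples[start:stop].copy(), rec.fs,
                                rating=int(events.ratings[i])))
    if offending:
        raise SegmentationError(
            f"window of {window_s} s exceeds recording for event rows {offending}"
        )
    return segments


def assign_labels(segments: list[Segment]) -> list[Segment]:
    """Map ratings to binary labels: 0 -> 0, {2,3} -> 1, 1 -> DROPPED."""
    out = []
    n_labeled = 0
    for seg in segments:
        if seg.rating == 0:
            label = 0
        elif seg.rating in (2, 3):
            label = 1
        elif seg.rating == 1:
            label = DROPPED
        else:
            raise ValidationError(f"rating {seg.rating} outside 0..3")
        if label != DROPPED:
            n_labeled += 1
        out.append(replace(seg, label=label))
    if segments and n_labeled == 0:
        logger.warning("all %d segments dropped by the rating rule", len(segments))
    return out


def write_feature_matrix(fm: FeatureMatrix, path: str | Path) -> None:
    """Write the matrix as CSV: 26 named feature columns then ``label``.

    Values are printed with 12 significant digits so a write/read round
    trip is lossless well below 1e-9.
    """
    fm.to_dataframe().to_csv(path, index=False, float_format="%.12g")


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    df = pd.read_csv(path)
    expected = list(FEATURE_NAMES) + ["label"]
    got = list(df.columns)
    if got != expected:
        for i, (e, g) in enumerate(zip(expected, got)):
            if e != g:
                raise SchemaError(
                    f"{path}: column {i} is {g!r}, expected {e!r}"
                )
        raise SchemaError(
            f"{path}: expected {len(expected)} columns, got {len(got)}"
        )
    return FeatureMatrix(FEATURE_NAMES,
                         df[list(FEATURE_NAMES)].to_numpy(dtype=float),
                         df["label"].to_numpy(dtype=int))
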
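"""Synthetic PPG generator with ground truth, for end-to-end testing.

Real stimulus-locked recordings of this kind are not redistributable, so
the generator emulates their structure: a beat sequence whose RR
intervals carry low-frequency (default 0.1 Hz) and high-frequency
(default 0.25 Hz) sinusoidal modulation plus Gaussian jitter; a pulse
waveform built from a two-Gaussian template (systolic peak at the beat
time, a smaller dicrotic bump 0.35*RR later, widths 0.08*RR and
0.12*RR — the asymmetry gives a fast upstroke and slow decay, so
valley->peak and peak->valley times genuinely differ); and the three
contaminants the preprocessing stage must remove: mains-frequency
interference, slow sinusoidal baseline drift, and broadband white noise.

The RR model is additive sinusoid-plus-noise rather than an integral
pulse frequency modulation model: simpler, and the LF/HF band placement
is directly controllable for spectral-feature tests.

``simulate_dataset`` emits a session-style long recording: one 14-s
block per stimulus (10-s window plus gap), events at +2 s into each
block, ratings 0 / 3 encoding the two classes (optionally rating-1
events to exercise the drop rule).  Class structure is parameterised —
pass identical configs for null experiments.

Everything is seeded and deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .io_core import EventTable, PPGRecording

logger = logging.getLogger(__name__)

RR_CLIP_MS = (333.0, 1500.0)  # 40–180 bpm physiological range


@dataclass
class SimConfig:
    """Generator parameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    fs: float = 1000.0          # acquisition rate, Hz
    duration_s: float = 10.0
    mean_rr_ms: float = 800.0   # 75 bpm
    sd_rr_ms: float = 30.0
    lf_amp_ms: float = 20.0
    lf_freq_hz: float = 0.1
    hf_amp_ms: float = 20.0
    hf_freq_hz: float = 0.25
    powerline_hz: float = 50.0
    powerline_amp: float = 0.2
    drift_freq_hz: float = 0.1
    drift_amp: float = 1.0
    broadband_sd: float = 0.05

    def __post_init__(self):
        if not RR_CLIP_MS[0] <= self.mean_rr_ms <= RR_CLIP_MS[1]:
            raise ValueError(f"mean_rr_ms must be within {RR_CLIP_MS}")
        for name in ("lf_amp_ms", "hf_amp_ms", "powerline_amp", "drift_amp",
                     "broadband_sd", "sd_rr_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimTruth:
    """Ground truth retained alongside a simulated recording."""

    beat_times: np.ndarray   # seconds
    rr_ms: np.ndarray        # intervals between consecutive beats
    clean_signal: np.ndarray
    class_label: int | None = None


def simulate_rr(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate the RR sequence and cumulative beat times.

    RR at beat time t is mean + LF sine + HF sine + Gaussian jitter,
    clipped to the 40–180 bpm range (clips are counted and logged).
    Returns ``(rr_ms, beat_times)`` with
    ``diff(beat_times) * 1000 == rr_ms``.
    """
    rng = np.random.default_rng(cfg.seed)
    beats = []
    t = 0.0
    n_clipped = 0
    while True:
        rr = (cfg.mean_rr_ms
              + cfg.lf_amp_ms * np.sin(2 * np.pi * cfg.lf_freq_hz * t)
              + cfg.hf_amp_ms * np.sin(2 * np.pi * cfg.hf_freq_hz * t)
              + (rng.normal(0.0, cfg.sd_rr_ms) if cfg.sd_rr_ms > 0 else 0.0))
        clipped = min(max(rr, RR_CLIP_MS[0]), RR_CLIP_MS[1])
        n_clipped += clipped != rr
        t_next = t + clipped / 1000.0
        if t_next > cfg.duration_s:
            break
        beats.append(t_next)
        t = t_next
    if n_clipped:
        logger.info("%d RR interval(s) clipped to %s ms", n_clipped, RR_CLIP_MS)
    beats = np.asarray(beats)
    rr_ms = np.diff(beats) * 1000.0
    return rr_ms, beats


def _pulse_template(t: np.ndarray, beat: float, rr_s: float) -> np.ndarray:
    sys_w = 0.08 * rr_s
    dic_w = 0.12 * rr_s
    out = np.exp(-0.5 * ((t - beat) / sys_w) ** 2)
    out += 0.2 * np.exp(-0.5 * ((t - beat - 0.35 * rr_s) / dic_w) ** 2)
    return out


def simulate_ppg(rr_ms: np.ndarray, beat_times: np.ndarray,
                 cfg: SimConfig) -> tuple[PPGRecording, SimTruth]:
    """Render the waveform for a beat sequence and add the contaminants."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    clean = np.zeros(n)
    for i, b in enumerate(np.asarray(beat_times)):
        rr_s = (rr_ms[i] if i < len(rr_ms) else
                (rr_ms[-1] if len(rr_ms) else cfg.mean_rr_ms)) / 1000.0
        # each template is negligible beyond ~1 RR either side
        lo = max(0, int((b - rr_s) * cfg.fs))
        hi = min(n, int((b + 1.5 * rr_s) * cfg.fs))
        clean[lo:hi] += _pulse_template(t[lo:hi], b, rr_s)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    noisy = clean.copy()
    if cfg.powerline_amp > 0:
        noisy = noisy + cfg.powerline_amp * np.sin(2 * np.pi * cfg.powerline_hz * t)
    if cfg.drift_amp > 0:
        noisy = noisy + cfg.drift_amp * np.sin(2 * np.pi * cfg.drift_freq_hz * t)
    if cfg.broadband_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.broadband_sd, n)
    rec = PPGRecording(noisy, fs=cfg.fs, subject_id="sim", session_id=f"seed{cfg.seed}")
    truth = SimTruth(np.asarray(beat_times), np.asarray(rr_ms), clean)
    return rec, truth


def simulate_segment(cfg: SimConfig) -> tuple[PPGRecording, SimTruth]:
    """One seeded recording: RR sequence then waveform."""
    rr_ms, beats = simulate_rr(cfg)
    return simulate_ppg(rr_ms, beats, cfg)


#: Default per-class HRV parameters for separable two-class datasets:
#: class 1 (state elicited) has a faster, steadier heart rate with less
#: high-frequency (vagal) modulation.
CLASS0_DEFAULTS = dict(mean_rr_ms=900.0, sd_rr_ms=50.0, hf_amp_ms=40.0, lf_amp_ms=25.0)
CLASS1_DEFAULTS = dict(mean_rr_ms=650.0, sd_rr_ms=15.0, hf_amp_ms=10.0, lf_amp_ms=10.0)

BLOCK_S = 14.0       # 10-s stimulus window plus inter-stimulus gap
EVENT_OFFSET_S = 2.0  # stimulus onset within each block
WINDOW_S = 10.0


def default_class_configs(seed: int = 0) -> tuple[SimConfig, SimConfig]:
    """Well-separated class configs used by the worked examples."""
    return (SimConfig(seed=seed, **CLASS0_DEFAULTS),
            SimConfig(seed=seed, **CLASS1_DEFAULTS))


def simulate_dataset(n_per_class: int, cfg0: SimConfig, cfg1: SimConfig,
                     seed: int, n_rating1: int = 0
                     ) -> tuple[PPGRecording, EventTable, list[SimTruth]]:
    """Session-style recording with one 14-s block per stimulus.

    Blocks for the two classes (plus optional ambiguous rating-1 blocks,
    drawn from the class-0 config) are shuffled into one long recording;
    events carry onset = block start + 2 s, duration 10 s and rating
    0 / 3 (or 1).  Per-block seeds derive from *seed*, so the whole
    dataset is reproducible.
    """
    if cfg0.fs != cfg1.fs:
        raise ValueError("class configs must share a sampling rate")
    rng = np.random.default_rng(seed)
    specs = ([(cfg0, 0)] * n_per_class + [(cfg1, 3)] * n_per_class
             + [(cfg0, 1)] * n_rating1)
    order = rng.permutation(len(specs))
    chunks, onsets, durations, ratings, truths = [], [], [], [], []
    for block_i, spec_i in enumerate(order):
        cfg, rating = specs[spec_i]
        block_seed = int(rng.integers(0, 2 ** 31))
        block_cfg = replace(cfg, seed=block_seed, duration_s=BLOCK_S)
        rec, truth = simulate_segment(block_cfg)
        truth.class_label = {0: 0, 3: 1, 1: None}[rating]
        chunks.append(rec.samples)
        onsets.append(block_i * BLOCK_S + EVENT_OFFSET_S)
        durations.append(WINDOW_S)
        ratings.append(rating)
        truths.append(truth)
    recording = PPGRecording(np.concatenate(chunks), fs=cfg0.fs,
                             subject_id="sim", session_id=f"dataset-seed{seed}")
    events = EventTable(np.asarray(onsets), np.asarray(durations),
                        np.asarray(ratings))
    return recording, events, truths
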
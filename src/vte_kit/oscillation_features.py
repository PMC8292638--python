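"""Hippocampal LFP preprocessing and oscillation features.

The CA1 field potential is preprocessed by 30x decimation (30 kHz -> 1 kHz)
and session-wide z-scoring, so amplitude is measured in standard deviations.
From the preprocessed trace we extract, per trial epoch:

* theta-cycle structure on an 80 Hz low-pass filtered copy — peaks at least
  0.0833 s apart (the upper edge of the 4-12 Hz theta band), trough = the
  minimum between consecutive peaks; each cycle runs peak -> trough -> next
  peak with descending (peak->trough) and ascending (trough->next peak)
  durations;
* the asymmetry index ``AI = ln(asc) - ln(desc)`` per cycle (0 for a
  symmetric cycle, positive when the rise is slower than the fall);
* low (35-55 Hz) and high (61-100 Hz) gamma power from third-order zero-lag
  Butterworth bandpass filters, z-scored per band over the session, with
  power the squared magnitude of the analytic (Hilbert) signal;
* the per-cycle gamma ratio ``GR`` = cycle-mean low-gamma power over
  cycle-mean high-gamma power;
* a 12-variable trial vector: mean and SD of AI, mean asc, mean desc,
  mean and SD of LG power, HG power, GR, and cycle duration (powers are
  averaged within each cycle before aggregating, so trial statistics are
  cycle-weighted);
* alternatively, a single-window Hamming periodogram of the z-scored
  epoch at 1 Hz resolution over 1-100 Hz (kept linear, no dB), with
  per-frequency feature selection by two-sample KS tests under
  Benjamini-Hochberg FDR correction.

Band z-scoring is session-level: filter and normalize the full session
trace, then slice epochs, so between-trial power differences survive
normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spst

from .core_io import FeatureTable, LfpSegment, LfpTrace

__all__ = [
    "ThetaCycle",
    "GammaEnvelope",
    "OSC_FEATURE_NAMES",
    "LOW_GAMMA_BAND",
    "HIGH_GAMMA_BAND",
    "MIN_PEAK_SEPARATION_S",
    "preprocess_lfp",
    "lowpass_for_cycles",
    "detect_theta_cycles",
    "asymmetry_index",
    "gamma_envelope",
    "gamma_ratio",
    "extract_osc_features",
    "compute_psd",
    "select_psd_features",
]

LOW_GAMMA_BAND = (35.0, 55.0)
HIGH_GAMMA_BAND = (61.0, 100.0)
MIN_PEAK_SEPARATION_S = 0.0833  # 1 / (12 Hz), upper edge of the theta band

OSC_FEATURE_NAMES = [
    "ai_mean", "ai_sd", "asc_mean", "desc_mean",
    "lg_mean", "lg_sd", "hg_mean", "hg_sd",
    "gr_mean", "gr_sd", "cycdur_mean", "cycdur_sd",
]


@dataclass
class ThetaCycle:
    """One peak-to-peak theta cycle (indices into the filtered trace)."""

    peak_idx: int
    trough_idx: int
    next_peak_idx: int
    asc: float  # ms, trough -> next peak
    desc: float  # ms, peak -> trough
    total: float  # ms, asc + desc

    def __post_init__(self) -> None:
        if not (self.peak_idx < self.trough_idx < self.next_peak_idx):
            raise ValueError("cycle indices must be ordered peak < trough < next peak")
        if self.asc <= 0 or self.desc <= 0:
            raise ValueError("cycle durations must be positive")


@dataclass
class GammaEnvelope:
    """Bandpassed, re-z-scored gamma trace and its instantaneous power."""

    band: tuple[float, float]
    g: np.ndarray  # z-units
    p: np.ndarray  # z-units^2, |analytic signal|^2


def preprocess_lfp(
    raw: np.ndarray,
    fs_raw: float = 30000.0,
    factor: int = 30,
    anti_alias: bool = True,
    session_id: str = "",
) -> LfpTrace:
    """Decimate the raw trace by 30 (anti-alias filtered) and z-score it."""
    raw = np.asarray(raw, dtype=float)
    if len(raw) < factor:
        raise ValueError("raw trace shorter than one decimation block")
    if np.ptp(raw) == 0:
        raise ValueError("constant signal cannot be z-scored")
    if anti_alias:
        down = sps.decimate(raw, factor, ftype="fir", zero_phase=True)
    else:
        down = raw[::factor]
    sd = down.std()
    if sd == 0:
        raise ValueError("constant signal cannot be z-scored")
    return LfpTrace((down - down.mean()) / sd, fs=fs_raw / factor, session_id=session_id)


def _zero_lag_butter(x: np.ndarray, fs: float, btype: str, edges, order: int = 3):
    sos = sps.butter(order, edges, btype=btype, fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def lowpass_for_cycles(
    trace: LfpTrace | LfpSegment | np.ndarray,
    fs: float | None = None,
    cutoff: float = 80.0,
) -> np.ndarray:
    """Zero-lag (forward-backward) 80 Hz low-pass for cycle landmarking."""
    if isinstance(trace, (LfpTrace, LfpSegment)):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace, float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    if len(x) < 28:  # sosfiltfilt padlen for a 3rd-order sos
        raise ValueError("segment shorter than filter warm-up")
    return _zero_lag_butter(x, fs, "lowpass", cutoff)


def detect_theta_cycles(
    filtered: np.ndarray,
    fs: float,
    min_separation_s: float = MIN_PEAK_SEPARATION_S,
    max_cycle_ms: float | None = None,
) -> list[ThetaCycle]:
    """Segment a low-pass filtered trace into peak-to-peak theta cycles.

    Peaks are local maxima with an enforced minimum separation of
    ``min_separation_s``; the trough is the global minimum between
    consecutive peaks (earliest sample on ties). With fewer than two peaks
    an empty list is returned with a warning. ``max_cycle_ms`` optionally
    drops implausibly long cycles (off by default).
    """
    filtered = np.asarray(filtered, float)
    distance = int(np.ceil(min_separation_s * fs))
    peaks, _ = sps.find_peaks(filtered, distance=distance)
    if len(peaks) < 2:
        warnings.warn("fewer than 2 theta peaks detected", stacklevel=2)
        return []
    cycles: list[ThetaCycle] = []
    for p0, p1 in zip(peaks[:-1], peaks[1:]):
        trough = p0 + int(np.argmin(filtered[p0 : p1 + 1]))
        if trough <= p0 or trough >= p1:
            continue  # monotone stretch, no interior trough
        desc = (trough - p0) / fs * 1e3
        asc = (p1 - trough) / fs * 1e3
        total = asc + desc
        if max_cycle_ms is not None and total > max_cycle_ms:
            continue
        cycles.append(
            ThetaCycle(
                peak_idx=int(p0), trough_idx=int(trough), next_peak_idx=int(p1),
                asc=asc, desc=desc, total=total,
            )
        )
    return cycles


def asymmetry_index(cycle: ThetaCycle) -> float:
    """AI = ln(ascending duration) - ln(descending duration)."""
    if cycle.asc <= 0 or cycle.desc <= 0:
        raise ValueError("durations must be positive")
    return float(np.log(cycle.asc) - np.log(cycle.desc))


def gamma_envelope(
    trace: LfpTrace | LfpSegment | np.ndarray,
    band: tuple[float, float],
    fs: float | None = None,
) -> GammaEnvelope:
    """Bandpass, re-z-score, and square the analytic-signal magnitude."""
    if isinstance(trace, (LfpTrace, LfpSegment)):
        x, fs = trace.samples, trace.fs
    else:
        x = np.asarray(trace, float)
        if fs is None:
            raise ValueError("fs required for a bare array")
    if band[1] >= fs / 2:
        raise ValueError(f"band {band} outside Nyquist for fs={fs}")
    g = _zero_lag_butter(x, fs, "bandpass", band)
    sd = g.std()
    if sd == 0:
        raise ValueError("bandpassed signal has zero variance")
    g = (g - g.mean()) / sd
    analytic = sps.hilbert(g)
    return GammaEnvelope(band=band, g=g, p=np.abs(analytic) ** 2)


def gamma_ratio(
    cycles: Sequence[ThetaCycle],
    lg: GammaEnvelope,
    hg: GammaEnvelope,
) -> np.ndarray:
    """Per-cycle gamma ratio: cycle-mean LG power / cycle-mean HG power.

    Cycles whose high-gamma power averages to zero are skipped with a
    warning. The trial-level GR is the mean of the returned values.
    """
    out = []
    for c in cycles:
        sl = slice(c.peak_idx, c.next_peak_idx)
        hg_mean = float(np.mean(hg.p[sl]))
        if hg_mean == 0:
            warnings.warn("zero high-gamma power in a cycle; skipped", stacklevel=2)
            continue
        out.append(float(np.mean(lg.p[sl])) / hg_mean)
    return np.asarray(out, float)


def extract_osc_features(
    segment: LfpSegment,
    lg: GammaEnvelope | None = None,
    hg: GammaEnvelope | None = None,
    min_cycles: int = 3,
) -> dict[str, float] | None:
    """The 12-variable oscillation feature vector for one trial epoch.

    ``lg``/``hg`` may be session-level envelopes (indexed via the segment's
    ``start_index``) so that band normalization is shared across trials; if
    omitted they are computed on the segment alone. Returns ``None`` (trial
    flagged unusable) when fewer than ``min_cycles`` complete cycles are
    found.
    """
    filtered = lowpass_for_cycles(segment)
    cycles = detect_theta_cycles(filtered, segment.fs)
    if len(cycles) < min_cycles:
        return None

    if lg is None:
        lg = gamma_envelope(segment, LOW_GAMMA_BAND)
        hg = gamma_envelope(segment, HIGH_GAMMA_BAND)
        offset = 0
    else:
        if hg is None:
            raise ValueError("provide both or neither session envelope")
        offset = segment.start_index

    ai = np.array([asymmetry_index(c) for c in cycles])
    asc = np.array([c.asc for c in cycles])
    desc = np.array([c.desc for c in cycles])
    total = np.array([c.total for c in cycles])
    lg_cyc = np.array(
        [np.mean(lg.p[offset + c.peak_idx : offset + c.next_peak_idx]) for c in cycles]
    )
    hg_cyc = np.array(
        [np.mean(hg.p[offset + c.peak_idx : offset + c.next_peak_idx]) for c in cycles]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        gr = lg_cyc[hg_cyc > 0] / hg_cyc[hg_cyc > 0]

    return {
        "ai_mean": float(ai.mean()), "ai_sd": float(ai.std()),
        "asc_mean": float(asc.mean()), "desc_mean": float(desc.mean()),
        "lg_mean": float(lg_cyc.mean()), "lg_sd": float(lg_cyc.std()),
        "hg_mean": float(hg_cyc.mean()), "hg_sd": float(hg_cyc.std()),
        "gr_mean": float(gr.mean()), "gr_sd": float(gr.std()),
        "cycdur_mean": float(total.mean()), "cycdur_sd": float(total.std()),
    }


def compute_psd(
    segment: LfpSegment,
    f_lo: float = 1.0,
    f_hi: float = 100.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-window Hamming periodogram sampled at 1 Hz bins over 1-100 Hz.

    Powers are kept linear (no dB conversion). The segment must be at least
    1 s long so the native resolution is at or below 1 Hz.
    """
    x = segment.samples
    if len(x) < segment.fs:
        raise ValueError("segment shorter than 1 s: cannot resolve 1 Hz bins")
    freqs, pxx = sps.periodogram(x, fs=segment.fs, window="hamming")
    targets = np.arange(f_lo, f_hi + 0.5, 1.0)
    idx = np.searchsorted(freqs, targets)
    idx = np.clip(idx, 1, len(freqs) - 1)
    idx = np.where(
        np.abs(freqs[idx - 1] - targets) <= np.abs(freqs[idx] - targets), idx - 1, idx
    )
    return targets, pxx[idx]


def select_psd_features(
    psd_table: FeatureTable,
    alpha: float = 0.05,
    positive: str = "VTE",
) -> list[str]:
    """Frequencies whose VTE/non-VTE power distributions differ.

    Per frequency column, a two-sample two-tailed KS test compares the two
    classes; Benjamini-Hochberg correction at ``alpha`` selects survivors.
    Returns the surviving column names (possibly empty, with a warning).
    """
    from .evaluation_stats import bh_correct  # local import: no cycle at import time

    is_pos = psd_table.labels == positive
    if is_pos.sum() < 2 or (~is_pos).sum() < 2:
        raise ValueError("need at least 2 trials per class")
    pvals = []
    for j in range(psd_table.values.shape[1]):
        col = psd_table.values[:, j]
        pvals.append(spst.ks_2samp(col[is_pos], col[~is_pos]).pvalue)
    _, rejected = bh_correct(np.asarray(pvals), alpha=alpha)
    names = [n for n, r in zip(psd_table.feature_names, rejected) if r]
    if not names:
        warnings.warn("no PSD features survive FDR correction", stacklevel=2)
    return names
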
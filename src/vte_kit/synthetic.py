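"""Synthetic plus-maze sessions with matched hippocampal LFP.

The simulator emulates the data the detection pipeline consumes, so every
stage is testable without recordings:

* **Trajectories** — head position at ~35 Hz in camera pixels on an
  elevated plus maze (arms along the axes, center platform at the origin).
  A non-VTE trial is a smooth arc from the start arm through the center to
  the chosen arm; a VTE trial inserts 1-3 head-sweep excursions toward the
  unchosen arm at the center (partial advance, reversal, re-orientation),
  which lengthens the trial and raises IdPhi. Gaussian tracking jitter is
  added to every frame.
* **LFP** — 1 kHz, z-scored. Theta (default 8 Hz) is a phase-warped cosine:
  within each cycle the descending (peak->trough) and ascending
  (trough->peak) durations realize a target asymmetry index exactly
  (asc/desc = exp(ai)) while the period stays fixed. Low (40-50 Hz) and
  high (70-90 Hz) gamma are narrowband-noise carriers amplitude-modulated
  by theta phase (low gamma mid-ascending, high gamma near the peak), with
  class-conditional power multipliers active during choice epochs.
  Broadband background is AR(1) pink noise plus white noise.
* **Labels** — ground-truth VTE flags at the configured rate plus four
  rater vote sets derived from truth with independent flip probability
  ``rater_error_rate``.

Class-conditional effects (theta asymmetry, gamma power) are applied only
during choice epochs; delay-epoch LFP is statistically identical across
classes, mirroring the empirical finding that delay oscillations carry no
VTE information.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .core_io import (
    NONVTE,
    VTE,
    LabelSet,
    LfpSegment,
    LfpTrace,
    PositionTrace,
    SessionPositions,
    TrialEpochs,
)

__all__ = [
    "SimConfig",
    "SimSession",
    "DEFAULT_CHOICE_REGION",
    "simulate_trajectory",
    "simulate_lfp",
    "simulate_votes",
    "simulate_session",
]

#: center-platform bounding box in simulator pixel coordinates
DEFAULT_CHOICE_REGION = np.array(
    [[-30.0, -30.0], [30.0, -30.0], [30.0, 30.0], [-30.0, 30.0]]
)

_ARM_TIP = 190.0  # px from center to the resting spot on an arm
_ARM_DIR = {
    "north": np.array([0.0, 1.0]),
    "south": np.array([0.0, -1.0]),
    "east": np.array([1.0, 0.0]),
    "west": np.array([-1.0, 0.0]),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated session.

    Sessions default to 60 trials with VTEs on ~20% of them. Per-class
    dictionaries are keyed ``"VTE"`` / ``"nonVTE"``; gamma entries are
    power multipliers relative to the session baseline, active during the
    choice epoch only.
    """

    n_trials: int = 60
    vte_fraction: float = 0.20
    frame_rate: float = 35.0
    lfp_fs: float = 1000.0
    theta_freq: float = 8.0
    #: choice-epoch theta asymmetry per class; baseline/delay uses ai_baseline
    ai_target: dict = field(default_factory=lambda: {VTE: 0.18, NONVTE: 0.10})
    ai_baseline: float = 0.10
    #: choice-epoch gamma power multipliers per class
    lg_power_target: dict = field(default_factory=lambda: {VTE: 1.3, NONVTE: 1.0})
    hg_power_target: dict = field(default_factory=lambda: {VTE: 1.08, NONVTE: 1.0})
    #: inclusive range of head sweeps per class
    sweep_count_range: dict = field(
        default_factory=lambda: {VTE: (1, 3), NONVTE: (0, 0)}
    )
    #: head-sweep excursion depth (px) per class; non-VTE hesitations are
    #: shallower glances that never leave the center platform area
    sweep_depth_range: dict = field(
        default_factory=lambda: {VTE: (18.0, 85.0), NONVTE: (12.0, 60.0)}
    )
    #: probability that a non-VTE trial contains one shallow hesitation
    nonvte_hesitation_prob: float = 0.5
    position_noise_sd: float = 0.5  # px of tracking jitter per frame
    run_speed: float = 80.0  # px/s along the path (median)
    run_speed_cv: float = 0.35  # per-trial lognormal speed variability
    rater_error_rate: float = 0.05
    theta_amp: float = 1.0
    gamma_amp: float = 0.06  # baseline burst amplitude (per band)
    noise_amp: float = 0.25  # broadband background SD
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.vte_fraction < 1:
            raise ValueError("vte_fraction must be in (0, 1)")
        if min(self.frame_rate, self.lfp_fs, self.theta_freq) <= 0:
            raise ValueError("rates must be positive")


@dataclass
class SimSession:
    positions: SessionPositions
    trials: list[TrialEpochs]
    lfp: LfpTrace
    truth_labels: np.ndarray
    votes: LabelSet
    ground_truth_params: list[dict]
    config: SimConfig = None


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def _smooth_path(waypoints: np.ndarray, spacing: float = 4.0, window: int = 9) -> np.ndarray:
    """Densify a piecewise-linear path and round its corners."""
    seglen = np.linalg.norm(np.diff(waypoints, axis=0), axis=1)
    pts = [waypoints[0]]
    for (a, b), L in zip(zip(waypoints[:-1], waypoints[1:]), seglen):
        n = max(int(np.ceil(L / spacing)), 1)
        for i in range(1, n + 1):
            pts.append(a + (b - a) * i / n)
    dense = np.asarray(pts)
    if len(dense) > window:
        kernel = np.ones(window) / window
        pad = window // 2
        padded = np.vstack(
            [np.repeat(dense[:1], pad, 0), dense, np.repeat(dense[-1:], pad, 0)]
        )
        dense = np.column_stack(
            [np.convolve(padded[:, 0], kernel, "valid"),
             np.convolve(padded[:, 1], kernel, "valid")]
        )
    return dense


def _waypoints(kind: str, start_arm: str, chosen_arm: str, cfg: SimConfig, rng) -> np.ndarray:
    s, c = _ARM_DIR[start_arm], _ARM_DIR[chosen_arm]
    unchosen = -c
    pts = [s * _ARM_TIP, s * 60.0, s * 18.0]
    lo, hi = cfg.sweep_count_range[kind]
    n_sweeps = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
    if kind == NONVTE and n_sweeps == 0 and rng.random() < cfg.nonvte_hesitation_prob:
        n_sweeps = 1  # a shallow glance, not a full reorientation
    d_lo, d_hi = cfg.sweep_depth_range[kind]
    for _ in range(n_sweeps):
        depth = rng.uniform(d_lo, d_hi)
        pts.append(unchosen * depth + s * rng.uniform(0.0, 8.0))
        pts.append(s * rng.uniform(4.0, 14.0))  # back near the center
    pts += [c * 18.0, c * 60.0, c * _ARM_TIP]
    return np.asarray(pts)


def _sample_path(
    path: np.ndarray, t0: float, cfg: SimConfig, rng, min_frames: int = 12
) -> PositionTrace:
    """Travel the path at constant speed; sample on the 35 Hz frame grid."""
    seglen = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    sigma = np.sqrt(np.log(1.0 + cfg.run_speed_cv**2))
    speed = cfg.run_speed * rng.lognormal(-0.5 * sigma**2, sigma)
    duration = cum[-1] / speed
    dt = 1.0 / cfg.frame_rate
    n = max(int(np.ceil(duration / dt)), min_frames)
    t = t0 + np.arange(n) * dt
    arc = np.linspace(0.0, cum[-1], n)
    x = np.interp(arc, cum, path[:, 0]) + rng.normal(0, cfg.position_noise_sd, n)
    y = np.interp(arc, cum, path[:, 1]) + rng.normal(0, cfg.position_noise_sd, n)
    return PositionTrace(t=t, x=x, y=y)


def simulate_trajectory(
    kind: str,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    start_arm: str = "north",
    chosen_arm: str = "east",
    t0: float = 0.0,
) -> PositionTrace:
    """One choice-epoch trajectory of the given class (``VTE``/``nonVTE``)."""
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    path = _smooth_path(_waypoints(kind, start_arm, chosen_arm, cfg, rng))
    return _sample_path(path, t0, cfg, rng)


# ---------------------------------------------------------------------------
# LFP
# ---------------------------------------------------------------------------

LG_CARRIER_BAND = (40.0, 50.0)
HG_CARRIER_BAND = (70.0, 90.0)


def _narrowband_noise(n: int, band: tuple[float, float], fs: float, rng) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _background(n: int, fs: float, rng) -> np.ndarray:
    """AR(1) pink noise plus white noise, unit SD."""
    pink = sps.lfilter([1.0], [1.0, -0.98], rng.standard_normal(n))
    x = pink / pink.std() * 0.7 + rng.standard_normal(n) * 0.7
    return x / x.std()


def _theta_phase(duration: float, fs: float, theta_freq: float, ai_of_cycle) -> np.ndarray:
    """Piecewise-linear phase realizing per-cycle asymmetry targets.

    Phase 2*pi*k at cycle k's peak, 2*pi*k + pi at its trough; the trough
    position within the fixed period sets asc/desc = exp(ai).
    """
    T = 1.0 / theta_freq
    n_cycles = int(np.ceil(duration / T)) + 1
    knots_t, knots_phase = [0.0], [0.0]
    for k in range(n_cycles):
        tc = k * T
        r = np.exp(ai_of_cycle(tc))  # asc / desc ratio
        desc = T / (1.0 + r)
        knots_t += [tc + desc, tc + T]
        knots_phase += [2 * np.pi * k + np.pi, 2 * np.pi * (k + 1)]
    t = np.arange(int(round(duration * fs))) / fs
    return np.interp(t, knots_t, knots_phase)


def _band_power_true(x: np.ndarray, band: tuple[float, float], fs: float) -> float:
    """Spectral band power of ``x`` under the analysis band definition.

    Computed in the frequency domain (rFFT of the raw trial segment) with
    the zero-lag Butterworth band weighting ``|H(f)|^4`` that a
    forward-backward third-order filter applies — an independent spectral
    route to the same quantity the Hilbert-envelope estimator measures, in
    variance units.
    """
    spec = np.fft.rfft(x - x.mean())
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    sos = sps.butter(3, band, btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=2 * np.pi * freqs / fs)
    weight = np.abs(h) ** 4  # filtfilt applies |H|^2 in amplitude
    return float(np.sum(weight * np.abs(spec) ** 2) * 2.0 / len(x) ** 2)


def _build_lfp(
    duration: float,
    cfg: SimConfig,
    rng,
    ai_of_cycle,
    lg_gain: np.ndarray | float,
    hg_gain: np.ndarray | float,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Raw (un-normalized) LFP plus its generative components."""
    fs = cfg.lfp_fs
    n = int(round(duration * fs))
    phase = _theta_phase(duration, fs, cfg.theta_freq, ai_of_cycle)
    theta = cfg.theta_amp * np.cos(phase)
    lg_mod = 0.5 * (1.0 + np.cos(phase - 1.5 * np.pi))  # mid-ascending
    hg_mod = 0.5 * (1.0 + np.cos(phase))  # near the peak
    lg = cfg.gamma_amp * np.sqrt(lg_gain) * lg_mod * _narrowband_noise(n, LG_CARRIER_BAND, fs, rng)
    hg = cfg.gamma_amp * np.sqrt(hg_gain) * hg_mod * _narrowband_noise(n, HG_CARRIER_BAND, fs, rng)
    noise = cfg.noise_amp * _background(n, fs, rng)
    return theta + lg + hg + noise, {"theta": theta, "lg": lg, "hg": hg, "noise": noise}


def simulate_lfp(
    trial_kind: str,
    duration: float,
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
) -> LfpSegment:
    """A standalone z-scored choice-epoch LFP segment of one class."""
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    if duration < 1.0:
        raise ValueError("duration must be at least 1 s")
    ai = cfg.ai_target[trial_kind]
    raw, _ = _build_lfp(
        duration, cfg, rng,
        ai_of_cycle=lambda t: ai,
        lg_gain=cfg.lg_power_target[trial_kind],
        hg_gain=cfg.hg_power_target[trial_kind],
    )
    z = (raw - raw.mean()) / raw.std()
    return LfpSegment(z, fs=cfg.lfp_fs, trial_id=-1, epoch="choice")


def simulate_votes(
    truth: np.ndarray, rater_error_rate: float, rng: np.random.Generator
) -> LabelSet:
    """Four rater vote sets: the truth flipped independently per rater/trial."""
    n = len(truth)
    flips = rng.random((n, 4)) < rater_error_rate
    votes = np.empty((n, 4), dtype=object)
    for i in range(n):
        for r in range(4):
            v = truth[i]
            if flips[i, r]:
                v = VTE if v == NONVTE else NONVTE
            votes[i, r] = v
    return LabelSet(np.arange(n), votes)


# ---------------------------------------------------------------------------
# full sessions
# ---------------------------------------------------------------------------


def simulate_session(
    cfg: SimConfig | None = None,
    rng: np.random.Generator | None = None,
    session_id: str = "sim",
) -> SimSession:
    """A full session: positions, epochs, LFP, truth labels, rater votes."""
    cfg = cfg or SimConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    dt = 1.0 / cfg.frame_rate

    truth = np.where(rng.random(cfg.n_trials) < cfg.vte_fraction, VTE, NONVTE).astype(object)

    start_arms = [rng.choice(["north", "south"]) for _ in range(cfg.n_trials + 1)]
    chosen_arms: list[str] = []
    for i in range(cfg.n_trials):
        if i == 0:
            chosen_arms.append(rng.choice(["east", "west"]))
        else:
            alt = "west" if chosen_arms[-1] == "east" else "east"
            chosen_arms.append(alt if rng.random() < 0.8 else chosen_arms[-1])

    frames_t, frames_x, frames_y, frames_tid, frames_epoch = [], [], [], [], []
    trials: list[TrialEpochs] = []
    choice_windows: list[tuple[float, float, str]] = []  # (start, end, kind)
    cursor = 0.0  # kept on the frame grid

    def _append(trace: PositionTrace, tid: int, epoch: str) -> None:
        frames_t.append(trace.t)
        frames_x.append(trace.x)
        frames_y.append(trace.y)
        frames_tid.append(np.full(len(trace), tid))
        frames_epoch.append(np.full(len(trace), epoch, dtype=object))

    for i in range(cfg.n_trials):
        kind = truth[i]
        # --- choice epoch
        path = _smooth_path(_waypoints(kind, start_arms[i], chosen_arms[i], cfg, rng))
        choice = _sample_path(path, cursor, cfg, rng)
        choice_start = cursor
        cursor = cursor + len(choice) * dt
        _append(choice, i, "choice")
        choice_windows.append((choice_start, cursor, kind))
        # --- return epoch: reward arm back to the next start arm
        rpath = _smooth_path(
            np.asarray(
                [
                    _ARM_DIR[chosen_arms[i]] * _ARM_TIP,
                    _ARM_DIR[chosen_arms[i]] * 40.0,
                    _ARM_DIR[start_arms[i + 1]] * 40.0,
                    _ARM_DIR[start_arms[i + 1]] * _ARM_TIP,
                ]
            )
        )
        ret = _sample_path(rpath, cursor, cfg, rng)
        return_start = cursor
        cursor = cursor + len(ret) * dt
        _append(ret, i, "return")
        # --- delay epoch: stationary at the start arm tip, exactly 10 s
        n_delay = int(round(10.0 * cfg.frame_rate))
        tip = _ARM_DIR[start_arms[i + 1]] * _ARM_TIP
        delay = PositionTrace(
            t=cursor + np.arange(n_delay) * dt,
            x=tip[0] + rng.normal(0, cfg.position_noise_sd, n_delay),
            y=tip[1] + rng.normal(0, cfg.position_noise_sd, n_delay),
        )
        delay_start = cursor
        cursor = cursor + n_delay * dt
        _append(delay, i, "delay")

        rewarded = i == 0 or chosen_arms[i] != chosen_arms[i - 1]
        trials.append(
            TrialEpochs(
                trial_id=i,
                start_arm=start_arms[i],
                chosen_arm=chosen_arms[i],
                rewarded=bool(rewarded),
                choice_window=(choice_start, return_start),
                return_window=(return_start, delay_start),
                delay_window=(delay_start, delay_start + n_delay * dt),
            )
        )

    positions = SessionPositions(
        session_id=session_id,
        t=np.concatenate(frames_t),
        x=np.concatenate(frames_x),
        y=np.concatenate(frames_y),
        trial_id=np.concatenate(frames_tid).astype(int),
        epoch=np.concatenate(frames_epoch),
        nominal_rate=cfg.frame_rate,
    )

    # --- session LFP with per-epoch class effects (1 s tail pad so the last
    # delay window always lies inside the trace despite frame/sample rounding)
    duration = cursor + 1.0
    fs = cfg.lfp_fs

    def ai_of_cycle(t: float) -> float:
        for lo, hi, kind in choice_windows:
            if lo <= t < hi:
                return cfg.ai_target[kind]
        return cfg.ai_baseline

    n = int(round(duration * fs))
    lg_gain = np.ones(n)
    hg_gain = np.ones(n)
    for lo, hi, kind in choice_windows:
        sl = slice(int(lo * fs), min(int(hi * fs), n))
        lg_gain[sl] = cfg.lg_power_target[kind]
        hg_gain[sl] = cfg.hg_power_target[kind]

    raw, parts = _build_lfp(duration, cfg, rng, ai_of_cycle, lg_gain, hg_gain)
    lfp = LfpTrace((raw - raw.mean()) / raw.std(), fs=fs, session_id=session_id)

    # --- ground truth bookkeeping (ideal-mask band powers per choice epoch)
    from .oscillation_features import HIGH_GAMMA_BAND, LOW_GAMMA_BAND

    ground_truth = []
    for i, (lo, hi, kind) in enumerate(choice_windows):
        sl = slice(int(lo * fs), min(int(hi * fs), n))
        seg = raw[sl]
        ground_truth.append(
            {
                "trial_id": i,
                "kind": kind,
                "ai_target": cfg.ai_target[kind],
                "lg_power_target": cfg.lg_power_target[kind],
                "hg_power_target": cfg.hg_power_target[kind],
                "lg_band_power_true": _band_power_true(seg, LOW_GAMMA_BAND, fs),
                "hg_band_power_true": _band_power_true(seg, HIGH_GAMMA_BAND, fs),
                "choice_duration": hi - lo,
            }
        )

    labelset = simulate_votes(truth, cfg.rater_error_rate, rng)

    return SimSession(
        positions=positions,
        trials=trials,
        lfp=lfp,
        truth_labels=truth,
        votes=labelset,
        ground_truth_params=ground_truth,
        config=replace(cfg),
    )
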
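"""Data model, epoch slicing, and plain-text readers/writers.

The package consumes head-position traces (timestamped x/y coordinates at
~35 Hz, camera-pixel units), hippocampal field-potential traces (1 kHz after
preprocessing, z-units), per-trial rater votes, and trial epoch annotations.
Everything is stored in small, explicit dataclasses; file formats are plain
CSV (positions, trials, labels, feature tables) and flat little-endian int16
binary with a JSON sidecar (LFP), so that sessions round-trip losslessly
through the simulator, the extractors, and the classifiers.

Conventions
-----------
* All timestamps are seconds (floats). On-disk position/trial files use the
  acquisition's millisecond timer (``*_ms`` columns); conversion happens at
  read/write time.
* Trial epoch windows are half-open ``[start, end)`` so that epoch slicing
  partitions a trial's samples with no double-counted boundary frame.
* Tracking dropouts are retained as gaps in ``t``, never interpolated;
  downstream feature code decides how to handle them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "EmptySliceError",
    "SessionPositions",
    "TrialEpochs",
    "PositionTrace",
    "LfpTrace",
    "LfpSegment",
    "LabelSet",
    "FeatureTable",
    "read_positions",
    "write_positions",
    "read_trials",
    "write_trials",
    "read_lfp",
    "write_lfp",
    "read_labels",
    "write_labels",
    "read_feature_table",
    "write_feature_table",
    "slice_epoch",
]

Epoch = Literal["choice", "return", "delay"]
EPOCHS: tuple[str, ...] = ("choice", "return", "delay")

VTE = "VTE"
NONVTE = "nonVTE"
EXCLUDED = "excluded"


class FormatError(ValueError):
    """A file does not conform to the expected dialect (missing columns...)."""


class ValidationError(ValueError):
    """Well-formed input violating a data-model invariant."""


class EmptySliceError(ValueError):
    """An epoch slice selected no samples."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PositionTrace:
    """Timestamped head coordinates for one trial epoch.

    ``t`` in seconds (strictly increasing), ``x``/``y`` in camera pixels.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValidationError("t, x, y must have equal lengths")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class SessionPositions:
    """All tracked frames of one session, with per-frame trial/epoch tags."""

    session_id: str
    t: np.ndarray  # seconds
    x: np.ndarray
    y: np.ndarray
    trial_id: np.ndarray  # int per frame, -1 outside any trial
    epoch: np.ndarray  # str per frame, "" outside any epoch
    nominal_rate: float = 35.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.epoch = np.asarray(self.epoch, dtype=object)
        n = len(self.t)
        if not all(len(a) == n for a in (self.x, self.y, self.trial_id, self.epoch)):
            raise ValidationError("per-frame arrays must share a length")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValidationError("coordinates must be finite")
        if self.nominal_rate <= 0:
            raise ValidationError("nominal_rate must be positive")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class TrialEpochs:
    """Choice/return/delay windows (seconds, half-open) for one trial."""

    trial_id: int
    start_arm: str  # north | south
    chosen_arm: str  # east | west
    rewarded: bool
    choice_window: tuple[float, float]
    return_window: tuple[float, float]
    delay_window: tuple[float, float]

    #: slack on the 10 s delay duration, one frame at ~35 Hz
    DELAY_TOL: float = field(default=0.05, repr=False)

    def __post_init__(self) -> None:
        windows = [self.choice_window, self.return_window, self.delay_window]
        for lo, hi in windows:
            if hi < lo:
                raise ValidationError(f"trial {self.trial_id}: window {lo}>{hi}")
        if not (
            self.choice_window[1] <= self.return_window[0]
            and self.return_window[1] <= self.delay_window[0]
        ):
            raise ValidationError(
                f"trial {self.trial_id}: epochs must be ordered choice<return<delay"
            )
        dd = self.delay_window[1] - self.delay_window[0]
        if abs(dd - 10.0) > self.DELAY_TOL:
            raise ValidationError(
                f"trial {self.trial_id}: delay duration {dd:.3f}s != 10s"
            )

    def window(self, epoch: str) -> tuple[float, float]:
        try:
            return {
                "choice": self.choice_window,
                "return": self.return_window,
                "delay": self.delay_window,
            }[epoch]
        except KeyError:
            raise ValueError(f"unknown epoch {epoch!r}") from None


@dataclass
class LfpTrace:
    """Full-session field potential, z-units at 1 kHz after preprocessing."""

    samples: np.ndarray
    fs: float
    session_id: str = ""
    t0: float = 0.0  # session time of samples[0], seconds

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("LFP samples must be finite")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.fs


@dataclass
class LfpSegment:
    """One trial epoch cut out of an :class:`LfpTrace`."""

    samples: np.ndarray
    fs: float
    trial_id: int = -1
    epoch: str = "choice"
    start_index: int = 0  # offset into the parent session trace

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValidationError("fs must be positive")

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class LabelSet:
    """Per-trial votes of the four raters plus consensus labels.

    ``votes`` has shape (n_trials, 4) with entries ``VTE``/``nonVTE``;
    ``consensus`` is filled by :func:`vte_kit.curation.apply_consensus`.
    """

    trial_ids: np.ndarray
    votes: np.ndarray
    consensus: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.votes = np.asarray(self.votes, dtype=object)
        if self.votes.ndim != 2 or self.votes.shape[1] != 4:
            raise ValidationError("votes must be (n_trials, 4)")
        if len(self.trial_ids) != len(self.votes):
            raise ValidationError("trial_ids and votes must align")
        bad = set(np.unique(self.votes)) - {VTE, NONVTE}
        if bad:
            raise ValidationError(f"unknown vote values {bad}")
        if self.consensus is not None:
            self.consensus = np.asarray(self.consensus, dtype=object)
            if len(self.consensus) != len(self.trial_ids):
                raise ValidationError("consensus must align to trial_ids")

    def __len__(self) -> int:
        return len(self.trial_ids)


@dataclass
class FeatureTable:
    """Trials x named features with binary labels, no missing values."""

    trial_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        self.feature_names = list(self.feature_names)
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValidationError("feature names must be unique")
        if self.values.shape != (len(self.trial_ids), len(self.feature_names)):
            raise ValidationError("values shape must be (trials, features)")
        if len(self.labels) != len(self.trial_ids):
            raise ValidationError("labels must align to trial_ids")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("feature table must not contain NaN/inf")
        bad = set(np.unique(self.labels)) - {VTE, NONVTE}
        if bad:
            raise ValidationError(f"unknown labels {bad}")

    def __len__(self) -> int:
        return len(self.trial_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        df.insert(0, "trial_id", self.trial_ids)
        return df

    def select(self, feature_names: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in feature_names]
        return FeatureTable(
            self.trial_ids, list(feature_names), self.values[:, idx], self.labels
        )

    def subset(self, trial_ids: Iterable[int]) -> "FeatureTable":
        wanted = list(trial_ids)
        pos = {tid: i for i, tid in enumerate(self.trial_ids)}
        rows = [pos[t] for t in wanted]
        return FeatureTable(
            np.asarray(wanted), self.feature_names, self.values[rows], self.labels[rows]
        )

    @staticmethod
    def concat_features(a: "FeatureTable", b: "FeatureTable") -> "FeatureTable":
        """Column-wise join on trial_id (inner), for combined feature sets."""
        common = [t for t in a.trial_ids if t in set(b.trial_ids)]
        aa, bb = a.subset(common), b.subset(common)
        if not np.array_equal(aa.labels, bb.labels):
            raise ValidationError("label mismatch between joined tables")
        names = aa.feature_names + [
            n if n not in aa.feature_names else f"{n}_2" for n in bb.feature_names
        ]
        return FeatureTable(
            aa.trial_ids, names, np.hstack([aa.values, bb.values]), aa.labels
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_POS_COLS = ["t_ms", "x", "y", "trial_id", "epoch"]
_TRIAL_COLS = [
    "trial_id", "start_arm", "chosen_arm", "rewarded",
    "choice_start_ms", "choice_end_ms",
    "return_start_ms", "return_end_ms",
    "delay_start_ms", "delay_end_ms",
]
_LABEL_COLS = ["trial_id", "rater1", "rater2", "rater3", "rater4"]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{what}: missing columns {missing}")


def read_positions(path: str | Path, session_id: str | None = None) -> SessionPositions:
    """Read a position CSV (``t_ms,x,y,trial_id,epoch``) into a session.

    Frames are sorted by time; rows with non-finite coordinates are rejected
    (reported via a ``ValidationError`` only when timestamps collide).
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, _POS_COLS, f"position file {path.name}")
    df = df.sort_values("t_ms", kind="stable")
    if df["t_ms"].duplicated().any():
        raise ValidationError(f"{path.name}: duplicated timestamps")
    return SessionPositions(
        session_id=session_id or path.stem,
        t=df["t_ms"].to_numpy(float) / 1000.0,
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        trial_id=df["trial_id"].to_numpy(int),
        epoch=df["epoch"].fillna("").to_numpy(object),
    )


def write_positions(positions: SessionPositions, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "t_ms": np.round(positions.t * 1000.0).astype(int),
            "x": positions.x,
            "y": positions.y,
            "trial_id": positions.trial_id,
            "epoch": positions.epoch,
        }
    )
    df.to_csv(path, index=False)


def read_trials(path: str | Path) -> list[TrialEpochs]:
    df = pd.read_csv(path)
    _require_columns(df, _TRIAL_COLS, f"trial table {Path(path).name}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialEpochs(
                trial_id=int(row.trial_id),
                start_arm=str(row.start_arm),
                chosen_arm=str(row.chosen_arm),
                rewarded=bool(row.rewarded),
                choice_window=(row.choice_start_ms / 1e3, row.choice_end_ms / 1e3),
                return_window=(row.return_start_ms / 1e3, row.return_end_ms / 1e3),
                delay_window=(row.delay_start_ms / 1e3, row.delay_end_ms / 1e3),
            )
        )
    return out


def write_trials(trials: Sequence[TrialEpochs], path: str | Path) -> None:
    rows = []
    for tr in trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "start_arm": tr.start_arm,
                "chosen_arm": tr.chosen_arm,
                "rewarded": tr.rewarded,
                "choice_start_ms": round(tr.choice_window[0] * 1e3),
                "choice_end_ms": round(tr.choice_window[1] * 1e3),
                "return_start_ms": round(tr.return_window[0] * 1e3),
                "return_end_ms": round(tr.return_window[1] * 1e3),
                "delay_start_ms": round(tr.delay_window[0] * 1e3),
                "delay_end_ms": round(tr.delay_window[1] * 1e3),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def write_lfp(trace: LfpTrace, path: str | Path, scale_to_uV: float = 1.0) -> None:
    """Write as little-endian int16 binary plus a JSON sidecar.

    z-units are mapped onto the int16 range with a fixed gain of 1000 counts
    per z-unit (recorded in the sidecar), comfortably inside +-32767 for the
    +-4 SD artifact-free range.
    """
    path = Path(path)
    gain = 1000.0
    counts = np.clip(np.round(trace.samples * gain), -32768, 32767).astype("<i2")
    counts.tofile(path)
    sidecar = {
        "fs": trace.fs,
        "scale_to_uV": scale_to_uV,
        "session_id": trace.session_id,
        "counts_per_unit": gain,
        "t0": trace.t0,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_lfp(path: str | Path) -> LfpTrace:
    """Read LFP from int16 binary + JSON sidecar, or a single-column CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        if df.shape[1] != 1:
            raise FormatError(f"{path.name}: LFP CSV must have one column")
        return LfpTrace(df.iloc[:, 0].to_numpy(float), fs=1000.0, session_id=path.stem)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path.name}")
    sidecar = json.loads(sidecar_path.read_text())
    counts = np.fromfile(path, dtype="<i2").astype(float)
    gain = float(sidecar.get("counts_per_unit", 1.0))
    return LfpTrace(
        counts / gain,
        fs=float(sidecar["fs"]),
        session_id=str(sidecar.get("session_id", path.stem)),
        t0=float(sidecar.get("t0", 0.0)),
    )


def read_labels(path: str | Path) -> LabelSet:
    df = pd.read_csv(path)
    _require_columns(df, _LABEL_COLS, f"label file {Path(path).name}")
    votes = df[["rater1", "rater2", "rater3", "rater4"]].to_numpy(object)
    return LabelSet(df["trial_id"].to_numpy(int), votes)


def write_labels(labels: LabelSet, path: str | Path) -> None:
    df = pd.DataFrame(labels.votes, columns=["rater1", "rater2", "rater3", "rater4"])
    df.insert(0, "trial_id", labels.trial_ids)
    df.to_csv(path, index=False)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write ``trial_id,label,<features>`` CSV at full float precision.

    Values are written as shortest round-trip decimal representations and
    read back with round-trip parsing, so write-then-read is the identity.
    """
    table.to_frame().to_csv(path, index=False)


def read_feature_table(
    path: str | Path, expected_features: Sequence[str] | None = None
) -> FeatureTable:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["trial_id", "label"], f"feature table {Path(path).name}")
    names = [c for c in df.columns if c not in ("trial_id", "label")]
    if expected_features is not None and set(names) != set(expected_features):
        raise FormatError(
            f"feature schema mismatch: got {names}, expected {list(expected_features)}"
        )
    return FeatureTable(
        df["trial_id"].to_numpy(int),
        names,
        df[names].to_numpy(float),
        df["label"].to_numpy(object),
    )


# ---------------------------------------------------------------------------
# epoch slicing
# ---------------------------------------------------------------------------


def slice_epoch(
    data: SessionPositions | LfpTrace,
    trial: TrialEpochs,
    epoch: str,
) -> PositionTrace | LfpSegment:
    """Cut one trial epoch out of a session recording.

    The window is half-open ``[t_start, t_end)``: a sample at exactly
    ``t_end`` belongs to the next window, making choice/return/delay a
    partition of the trial.
    """
    t_start, t_end = trial.window(epoch)
    if t_end <= t_start:
        raise EmptySliceError(f"zero-length {epoch} window on trial {trial.trial_id}")

    if isinstance(data, SessionPositions):
        if t_start < data.t[0] - 1.0 / data.nominal_rate or t_end > data.t[-1] + 1.0:
            raise ValueError(f"{epoch} window outside recording extent")
        mask = (data.t >= t_start) & (data.t < t_end)
        if not mask.any():
            raise EmptySliceError(f"no frames in {epoch} window of trial {trial.trial_id}")
        return PositionTrace(data.t[mask], data.x[mask], data.y[mask])

    if isinstance(data, LfpTrace):
        i0 = int(np.ceil((t_start - data.t0) * data.fs - 1e-9))
        i1 = int(np.ceil((t_end - data.t0) * data.fs - 1e-9))
        if i0 < 0 or i1 > len(data.samples):
            raise ValueError(f"{epoch} window outside recording extent")
        if i1 <= i0:
            raise EmptySliceError(f"no samples in {epoch} window of trial {trial.trial_id}")
        return LfpSegment(
            data.samples[i0:i1], data.fs, trial_id=trial.trial_id,
            epoch=epoch, start_index=i0,
        )

    raise TypeError(f"cannot slice object of type {type(data).__name__}")
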
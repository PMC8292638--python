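"""Trajectory-based VTE features for plus-maze choice epochs.

A vicarious-trial-and-error (VTE) trial shows head sweeps toward the
unchosen arm at the decision point; a clean pass-through is a smooth arc.
The features quantify this per choice-epoch trajectory:

``x_sd``, ``y_sd``
    population standard deviations of the coordinate vectors;
``idphi`` / ``zidphi``
    the integrated absolute change of the heading angle
    ``phi = arctan2(dy, dx)`` summed over successive frame displacements,
    and its z-score computed within each session;
``dur``
    time spent inside the experimenter-defined choice region;
``r2``
    goodness of a degree-6 least-squares polynomial fit of y on x
    (``r2 = 1 - SSE/SST``) — sweeping trajectories are multivalued in x and
    fit poorly;
``n_coef``
    the number of Fourier coefficients needed to capture 95% of the
    non-DC spectral energy of the fitted curve, capturing the damped
    oscillation look of poor fits.

Raw ``idphi`` is kept alongside ``zidphi`` as the seventh feature (toggle
``include_raw_idphi``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import PositionTrace

__all__ = [
    "DegenerateTrajectoryError",
    "HeadingSeries",
    "PolyFit",
    "TRAJECTORY_FEATURE_NAMES",
    "compute_heading",
    "compute_idphi",
    "zscore_by_session",
    "position_sds",
    "choice_duration",
    "points_in_polygon",
    "poly_fit_r2",
    "fourier_coef_count",
    "extract_trajectory_features",
    "zidphi_threshold_classifier",
]

TRAJECTORY_FEATURE_NAMES = ["x_sd", "y_sd", "zidphi", "dur", "r2", "n_coef", "idphi"]


class DegenerateTrajectoryError(ValueError):
    pass


@dataclass
class HeadingSeries:
    """Heading angles and their absolute successive changes."""

    phi: np.ndarray  # radians, in (-pi, pi]
    dphi_abs: np.ndarray  # |delta phi|, wrapped into [0, pi] by default


@dataclass
class PolyFit:
    coeffs: np.ndarray  # degree-6, highest power first
    y_hat: np.ndarray
    sse: float
    sst: float
    r2: float


def compute_heading(trace: PositionTrace, wrap: bool = True) -> HeadingSeries:
    """Heading angle per displacement and absolute heading changes.

    ``phi_i = arctan2(dy_i, dx_i)`` for each successive frame displacement.
    With ``wrap=True`` (default) angular differences are wrapped to the
    shortest circular distance in ``[0, pi]``; ``wrap=False`` uses the raw
    ``|phi_a - phi_{a-1}|``, which double-counts +-pi crossings.
    """
    if len(trace) < 3:
        raise DegenerateTrajectoryError("need at least 3 samples")
    dx = np.diff(trace.x)
    dy = np.diff(trace.y)
    moving = (dx != 0) | (dy != 0)
    if not moving.any():
        raise DegenerateTrajectoryError("all samples coincident")
    phi = np.arctan2(dy, dx)
    # zero-displacement frames carry no heading; hold the previous heading
    if not moving.all():
        idx = np.where(moving, np.arange(len(phi)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(moving)
        idx[idx < 0] = first
        phi = phi[idx]
    dphi = np.diff(phi)
    if wrap:
        dphi_abs = np.abs(np.mod(dphi + np.pi, 2 * np.pi) - np.pi)
    else:
        dphi_abs = np.abs(dphi)
    return HeadingSeries(phi=phi, dphi_abs=dphi_abs)


def compute_idphi(heading: HeadingSeries) -> float:
    """Integrated change in heading angle: the sum of ``|delta phi|``."""
    return float(np.sum(heading.dphi_abs))


def zscore_by_session(values: np.ndarray) -> np.ndarray:
    """z-score a session's trial values (population SD, divisor N)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least 2 trials to z-score a session")
    sd = values.std()  # ddof=0
    if sd == 0:
        raise ValueError("degenerate session: zero spread")
    return (values - values.mean()) / sd


def position_sds(trace: PositionTrace) -> tuple[float, float]:
    """Population SDs of the x and y coordinate vectors."""
    if len(trace) < 2:
        raise ValueError("need at least 2 samples")
    return float(trace.x.std()), float(trace.y.std())


def points_in_polygon(x: np.ndarray, y: np.ndarray, polygon: np.ndarray) -> np.ndarray:
    """Even-odd ray-casting point-in-polygon test (boundary counts as inside)."""
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[0] < 3 or polygon.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) vertex array")
    px, py = polygon[:, 0], polygon[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    x = np.asarray(x, float)[:, None]
    y = np.asarray(y, float)[:, None]
    crosses = ((py <= y) & (y < qy)) | ((qy <= y) & (y < py))
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = px + (y - py) * (qx - px) / np.where(qy == py, np.inf, qy - py)
    inside = np.sum(crosses & (x < xint), axis=1) % 2 == 1
    # include points exactly on an edge
    on_edge = np.zeros(inside.shape, bool)
    for ax, ay, bx, by in zip(px, py, qx, qy):
        cross = (bx - ax) * (y[:, 0] - ay) - (by - ay) * (x[:, 0] - ax)
        within = (
            (np.minimum(ax, bx) - 1e-12 <= x[:, 0]) & (x[:, 0] <= np.maximum(ax, bx) + 1e-12)
            & (np.minimum(ay, by) - 1e-12 <= y[:, 0]) & (y[:, 0] <= np.maximum(ay, by) + 1e-12)
        )
        on_edge |= (np.abs(cross) < 1e-9) & within
    return inside | on_edge


def choice_duration(trace: PositionTrace, choice_region: np.ndarray) -> float:
    """Total time the head spends inside the choice-point polygon.

    Sums the inter-frame intervals whose starting frame lies inside the
    region; returns 0 (with a warning) if the trace never enters it.
    """
    inside = points_in_polygon(trace.x, trace.y, choice_region)
    if not inside.any():
        warnings.warn("trajectory never enters the choice region", stacklevel=2)
        return 0.0
    dt = np.diff(trace.t)
    return float(np.sum(dt[inside[:-1]]))


def poly_fit_r2(trace: PositionTrace, degree: int = 6) -> PolyFit:
    """Least-squares degree-6 polynomial fit of y on x with r2 = 1 - SSE/SST."""
    if len(trace) < degree + 2:
        raise ValueError(f"need at least {degree + 2} samples for a degree-{degree} fit")
    y = trace.y
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("zero y spread: r2 undefined")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", np.exceptions.RankWarning)
        coeffs = np.polyfit(trace.x, y, degree)
    y_hat = np.polyval(coeffs, trace.x)
    sse = float(np.sum((y - y_hat) ** 2))
    return PolyFit(coeffs=coeffs, y_hat=y_hat, sse=sse, sst=sst, r2=1.0 - sse / sst)


def fourier_coef_count(fit: PolyFit, energy_fraction: float = 0.95) -> int:
    """Fourier coefficients needed to describe the polynomial fit estimate.

    Discrete Fourier magnitudes of the mean-removed fitted curve are sorted
    descending; returns the smallest k whose top-k coefficients hold at
    least ``energy_fraction`` of the total spectral energy. A constant
    estimate needs 0 coefficients. Non-periodic smooth curves (including a
    straight pass-through) incur spectral leakage and need several
    coefficients; the feature is used comparatively, oscillatory sweep
    fits needing more than smooth arcs.
    """
    y_hat = np.asarray(fit.y_hat, float)
    if len(y_hat) < 4:
        raise ValueError("need at least 4 fitted samples")
    centered = y_hat - y_hat.mean()
    spectrum = np.abs(np.fft.rfft(centered)[1:]) ** 2  # drop DC
    total = spectrum.sum()
    if total <= 1e-12 * max(1.0, float(np.sum(y_hat**2))):
        return 0
    ordered = np.sort(spectrum)[::-1]
    cum = np.cumsum(ordered) / total
    return int(np.searchsorted(cum, energy_fraction - 1e-12) + 1)


def extract_trajectory_features(
    traces: list[PositionTrace],
    choice_region: np.ndarray,
    wrap: bool = True,
    include_raw_idphi: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Feature matrix for one session's choice-epoch trajectories.

    zIdPhi is computed across the supplied traces (one session), so the
    zidphi column has mean 0 and population SD 1. Returns (values, names).
    """
    idphis = np.array(
        [compute_idphi(compute_heading(tr, wrap=wrap)) for tr in traces]
    )
    zidphi = zscore_by_session(idphis)
    rows = []
    for tr, iphi, ziphi in zip(traces, idphis, zidphi):
        x_sd, y_sd = position_sds(tr)
        fit = poly_fit_r2(tr)
        row = [
            x_sd,
            y_sd,
            ziphi,
            choice_duration(tr, choice_region),
            fit.r2,
            float(fourier_coef_count(fit)),
        ]
        if include_raw_idphi:
            row.append(iphi)
        rows.append(row)
    names = TRAJECTORY_FEATURE_NAMES if include_raw_idphi else TRAJECTORY_FEATURE_NAMES[:-1]
    return np.asarray(rows, float), list(names)


def zidphi_threshold_classifier(
    zidphi: np.ndarray,
    labels: np.ndarray,
    positive: str = "VTE",
    lo_percentile: float = 50.0,
    hi_percentile: float = 80.0,
) -> tuple[float, np.ndarray, float]:
    """The single-metric baseline: threshold zIdPhi, VTE above threshold.

    Candidate thresholds are the 50th..80th percentiles of the zIdPhi values
    in 1-percentile steps; the threshold maximizing the two-point ROC area
    ``(TPR + TNR) / 2`` is selected. Returns
    ``(threshold, predictions, area)``.
    """
    zidphi = np.asarray(zidphi, float)
    labels = np.asarray(labels, object)
    is_pos = labels == positive
    if is_pos.all() or not is_pos.any():
        raise ValueError("need both classes to set a threshold")
    best = None
    for pct in np.arange(lo_percentile, hi_percentile + 1e-9, 1.0):
        thr = float(np.percentile(zidphi, pct))
        pred_pos = zidphi > thr
        tpr = np.mean(pred_pos[is_pos])
        tnr = np.mean(~pred_pos[~is_pos])
        area = (tpr + tnr) / 2.0
        if best is None or area > best[2] + 1e-12:
            best = (thr, pred_pos, area)
    thr, pred_pos, area = best
    predictions = np.where(pred_pos, positive, "nonVTE").astype(object)
    return thr, predictions, float(area)
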
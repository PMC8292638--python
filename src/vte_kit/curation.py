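"""Label consensus, inter-rater reliability, and quality gates.

Four trained raters score each trial VTE/non-VTE. The consensus is the
majority vote; 2-2 ties are excluded from analysis. Session-level gates:
average pairwise percent agreement should exceed 90% and average pairwise
Cohen's kappa 0.7; trials whose analyzed LFP epoch contains any sample
beyond 4 session SDs are excluded; a session loses all its data when more
than 20% of its trials are excluded or when the theta asymmetry-index
distribution is not skewed in the expected direction (positive for this
preparation; the sign is configurable since other electrode placements
skew negative).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score

from .core_io import EXCLUDED, NONVTE, VTE, LabelSet, LfpTrace, TrialEpochs, slice_epoch

__all__ = [
    "RaterReport",
    "SessionQc",
    "consensus_label",
    "apply_consensus",
    "interrater_stats",
    "noise_exclusion",
    "session_qc",
]


@dataclass
class RaterReport:
    pair_agreement: dict[tuple[int, int], float]  # percent, 0-100
    pair_kappa: dict[tuple[int, int], float]  # NaN when undefined
    mean_agreement: float
    mean_kappa: float


@dataclass
class SessionQc:
    excluded_trials: list[int]
    excluded_fraction: float
    ai_median: float
    keep: bool
    reasons: list[str] = field(default_factory=list)


def consensus_label(votes: Sequence[str]) -> str:
    """Majority label of exactly 4 votes; a 2-2 tie is ``excluded``."""
    if len(votes) != 4:
        raise ValueError(f"expected 4 votes, got {len(votes)}")
    n_vte = sum(v == VTE for v in votes)
    if n_vte > 2:
        return VTE
    if n_vte < 2:
        return NONVTE
    return EXCLUDED


def apply_consensus(labels: LabelSet) -> LabelSet:
    """Fill the consensus column of a label set (returns the same object)."""
    labels.consensus = np.array(
        [consensus_label(row) for row in labels.votes], dtype=object
    )
    return labels


def interrater_stats(labels: LabelSet) -> RaterReport:
    """Pairwise percent agreement and Cohen's kappa, averaged over 6 pairs.

    Kappa compares observed agreement to chance agreement expected from the
    two raters' marginal vote rates. A pair where either rater votes
    constantly has undefined kappa, reported as NaN and left out of the
    average.
    """
    if len(labels) < 2:
        raise ValueError("need at least 2 trials")
    votes = labels.votes
    agreement: dict[tuple[int, int], float] = {}
    kappas: dict[tuple[int, int], float] = {}
    for i, j in combinations(range(4), 2):
        a, b = votes[:, i], votes[:, j]
        agreement[(i, j)] = float(np.mean(a == b) * 100.0)
        if len(set(a)) < 2 or len(set(b)) < 2:
            kappas[(i, j)] = float("nan")
        else:
            kappas[(i, j)] = float(cohen_kappa_score(list(a), list(b)))
    kvals = [v for v in kappas.values() if np.isfinite(v)]
    return RaterReport(
        pair_agreement=agreement,
        pair_kappa=kappas,
        mean_agreement=float(np.mean(list(agreement.values()))),
        mean_kappa=float(np.mean(kvals)) if kvals else float("nan"),
    )


def noise_exclusion(
    trace: LfpTrace,
    trials: Sequence[TrialEpochs],
    epoch: str = "choice",
    threshold_sd: float = 4.0,
) -> list[int]:
    """Trials whose analyzed epoch contains any sample beyond the threshold.

    The trace is expected z-scored over the entire session, so the 4 SD
    threshold is in units of the full-timeseries SD.
    """
    excluded = []
    for tr in trials:
        seg = slice_epoch(trace, tr, epoch)
        if np.any(np.abs(seg.samples) > threshold_sd):
            excluded.append(tr.trial_id)
    return excluded


def session_qc(
    n_trials: int,
    ai_values: np.ndarray,
    excluded_trials: Sequence[int],
    max_excluded_fraction: float = 0.20,
    required_ai_sign: int = +1,
) -> SessionQc:
    """Session keep/drop decision.

    A session is dropped when *more than* 20% of its trials are excluded
    (strictly greater: 12/60 keeps, 13/60 drops) or when the median per-cycle
    asymmetry index does not have the required sign (``required_ai_sign``
    0 disables the skew check).
    """
    ai_values = np.asarray(ai_values, float)
    if len(ai_values) == 0:
        raise ValueError("need asymmetry-index values for at least one trial")
    frac = len(set(excluded_trials)) / n_trials if n_trials else 0.0
    ai_median = float(np.median(ai_values))
    reasons = []
    if frac > max_excluded_fraction:
        reasons.append(
            f"excluded fraction {frac:.3f} > {max_excluded_fraction:.2f}"
        )
    if required_ai_sign and np.sign(ai_median) != np.sign(required_ai_sign):
        reasons.append(f"AI median {ai_median:.3f} not of required sign")
    return SessionQc(
        excluded_trials=sorted(set(excluded_trials)),
        excluded_fraction=frac,
        ai_median=ai_median,
        keep=not reasons,
        reasons=reasons,
    )
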
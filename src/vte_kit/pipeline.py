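"""Session-level feature-table builders gluing I/O, features, and curation.

These helpers take a session (real files or a :class:`~vte_kit.synthetic`
session) and produce labeled :class:`~vte_kit.core_io.FeatureTable` objects
ready for the balanced cross-validation in :mod:`vte_kit.classification`.
Labels come from the rater consensus (majority; 2-2 ties excluded), and
trials flagged by the LFP noise gate or with unusable oscillation segments
are dropped from the tables.
"""

from __future__ import annotations

import numpy as np

from .core_io import (
    EXCLUDED,
    FeatureTable,
    LabelSet,
    LfpTrace,
    SessionPositions,
    TrialEpochs,
    slice_epoch,
)
from .curation import apply_consensus, noise_exclusion
from .oscillation_features import (
    HIGH_GAMMA_BAND,
    LOW_GAMMA_BAND,
    OSC_FEATURE_NAMES,
    compute_psd,
    extract_osc_features,
    gamma_envelope,
)
from .synthetic import DEFAULT_CHOICE_REGION
from .trajectory_features import extract_trajectory_features

__all__ = [
    "consensus_labels_for",
    "trajectory_feature_table",
    "osc_feature_table",
    "psd_feature_table",
]


def consensus_labels_for(
    labels: LabelSet, trial_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(kept_trial_ids, consensus) with 2-2 tie trials dropped."""
    if labels.consensus is None:
        apply_consensus(labels)
    lookup = dict(zip(labels.trial_ids.tolist(), labels.consensus))
    kept, cons = [], []
    for tid in trial_ids:
        c = lookup.get(int(tid))
        if c is not None and c != EXCLUDED:
            kept.append(int(tid))
            cons.append(c)
    return np.asarray(kept, int), np.asarray(cons, object)


def trajectory_feature_table(
    positions: SessionPositions,
    trials: list[TrialEpochs],
    labels: LabelSet,
    choice_region: np.ndarray = DEFAULT_CHOICE_REGION,
    exclude: set[int] | None = None,
) -> FeatureTable:
    """Seven trajectory features per choice epoch, consensus-labeled.

    zIdPhi is z-scored within this session, over the retained trials.
    """
    exclude = exclude or set()
    kept_ids, consensus = consensus_labels_for(
        labels, np.array([tr.trial_id for tr in trials])
    )
    keep = [tid for tid in kept_ids if tid not in exclude]
    cons = consensus[[i for i, tid in enumerate(kept_ids) if tid not in exclude]]
    by_id = {tr.trial_id: tr for tr in trials}
    traces = [slice_epoch(positions, by_id[tid], "choice") for tid in keep]
    values, names = extract_trajectory_features(traces, choice_region)
    return FeatureTable(np.asarray(keep), names, values, cons)


def osc_feature_table(
    lfp: LfpTrace,
    trials: list[TrialEpochs],
    labels: LabelSet,
    epoch: str = "choice",
    apply_noise_gate: bool = True,
) -> FeatureTable:
    """The 12-variable oscillation vector per trial epoch.

    Gamma bands are filtered and z-scored over the whole session trace
    before slicing, so between-trial power differences survive
    normalization. Trials failing the 4 SD noise gate or with too few
    theta cycles are dropped.
    """
    excluded = set(noise_exclusion(lfp, trials, epoch=epoch)) if apply_noise_gate else set()
    lg = gamma_envelope(lfp, LOW_GAMMA_BAND)
    hg = gamma_envelope(lfp, HIGH_GAMMA_BAND)
    kept_ids, consensus = consensus_labels_for(
        labels, np.array([tr.trial_id for tr in trials])
    )
    cons_by_id = dict(zip(kept_ids.tolist(), consensus))
    by_id = {tr.trial_id: tr for tr in trials}
    rows, ids, labs = [], [], []
    for tid in kept_ids:
        if tid in excluded:
            continue
        seg = slice_epoch(lfp, by_id[tid], epoch)
        feats = extract_osc_features(seg, lg=lg, hg=hg)
        if feats is None:
            continue
        rows.append([feats[k] for k in OSC_FEATURE_NAMES])
        ids.append(tid)
        labs.append(cons_by_id[tid])
    return FeatureTable(
        np.asarray(ids, int), list(OSC_FEATURE_NAMES),
        np.asarray(rows, float), np.asarray(labs, object),
    )


def psd_feature_table(
    lfp: LfpTrace,
    trials: list[TrialEpochs],
    labels: LabelSet,
    epoch: str = "choice",
    apply_noise_gate: bool = True,
) -> FeatureTable:
    """Per-trial 1-100 Hz periodogram features (linear power, 1 Hz bins)."""
    excluded = set(noise_exclusion(lfp, trials, epoch=epoch)) if apply_noise_gate else set()
    kept_ids, consensus = consensus_labels_for(
        labels, np.array([tr.trial_id for tr in trials])
    )
    cons_by_id = dict(zip(kept_ids.tolist(), consensus))
    by_id = {tr.trial_id: tr for tr in trials}
    rows, ids, labs = [], [], []
    names: list[str] | None = None
    for tid in kept_ids:
        if tid in excluded:
            continue
        seg = slice_epoch(lfp, by_id[tid], epoch)
        if len(seg) < seg.fs:
            continue
        freqs, power = compute_psd(seg)
        if names is None:
            names = [f"psd_{int(f)}hz" for f in freqs]
        rows.append(power)
        ids.append(tid)
        labs.append(cons_by_id[tid])
    return FeatureTable(
        np.asarray(ids, int), names or [],
        np.asarray(rows, float), np.asarray(labs, object),
    )
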
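"""Desk-scale reproduction of the VTE-classification comparison experiments.

`run_experiment` chains simulate -> curate -> extract -> classify ->
evaluate on synthetic plus-maze data. All experiments in a run share one
seeded split matrix so per-split metric comparisons are paired:

``traj_only``
    KNN / RBF-SVM on the seven trajectory features.
``zidphi_baseline``
    the single-metric zIdPhi percentile-threshold classifier on the same
    splits (threshold set on each split's training portion).
``osc_choice`` / ``osc_delay``
    SVM on the 12 oscillation features from the choice or delay epoch,
    reported as delta scores against the random-label baseline.
``psd``
    SVM on 1-100 Hz periodogram features; per split, only frequencies
    whose class distributions differ (KS + Benjamini-Hochberg on the
    training portion) enter the model.
``combined``
    trajectory features joined with the training-selected oscillation
    features, against ``traj_only`` on identical splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .classification import (
    PredictionSet,
    SplitMatrix,
    build_split_matrix,
    grid_search_svm,
    random_label_baseline,
    run_cv,
    standardize,
    train_knn,
    train_svm,
)
from .core_io import FeatureTable
from .curation import apply_consensus, interrater_stats, noise_exclusion, session_qc
from .evaluation_stats import (
    cohens_d,
    confusion_from_predictions,
    classification_metrics,
    delta_scores,
    ks_test_2samp,
    roc_and_auc,
    wilcoxon_signed_rank,
)
from .oscillation_features import select_psd_features
from .pipeline import osc_feature_table, psd_feature_table, trajectory_feature_table
from .synthetic import SimConfig, SimSession, simulate_session
from .trajectory_features import zidphi_threshold_classifier

__all__ = [
    "RunConfig",
    "Dataset",
    "simulate_dataset",
    "evaluate_predictions",
    "run_zidphi_baseline",
    "run_selected_feature_cv",
    "run_experiment",
    "EXPERIMENTS",
]

EXPERIMENTS = (
    "traj_only", "zidphi_baseline", "osc_choice", "osc_delay", "psd", "combined",
)


@dataclass
class RunConfig:
    """Configuration for one experiment run on simulated data."""

    experiment: str = "traj_only"
    model: str = "svm"
    seed: int = 1
    n_sessions: int = 4
    n_splits: int = 100
    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")


@dataclass
class Dataset:
    """Feature tables pooled over simulated sessions with unique trial ids."""

    sessions: list[SimSession]
    traj: FeatureTable
    osc_choice: FeatureTable
    osc_delay: FeatureTable
    psd: FeatureTable
    qc_reports: list[dict]


def _offset_table(table: FeatureTable, offset: int) -> FeatureTable:
    return FeatureTable(
        table.trial_ids + offset, table.feature_names, table.values, table.labels
    )


def simulate_dataset(
    n_sessions: int = 4,
    sim: SimConfig | None = None,
    seed: int = 1,
    with_lfp_tables: bool = True,
) -> Dataset:
    """Simulate sessions and pool per-session feature tables.

    Trial ids are offset by 1000 per session so they stay unique; sessions
    failing the QC gates (excess exclusions, wrong AI skew) are dropped in
    their entirety, mirroring the curation rules.
    """
    sim = sim or SimConfig()
    rng = np.random.default_rng(seed)
    sessions, qc_reports = [], []
    traj_parts, oc_parts, od_parts, psd_parts = [], [], [], []
    for s in range(n_sessions):
        sess = simulate_session(
            replace(sim, seed=seed), rng=rng, session_id=f"sim{s:02d}"
        )
        apply_consensus(sess.votes)
        rater = interrater_stats(sess.votes)
        offset = 1000 * s

        traj_tbl = trajectory_feature_table(
            sess.positions, sess.trials, sess.votes
        )
        if with_lfp_tables:
            oc_tbl = osc_feature_table(sess.lfp, sess.trials, sess.votes, epoch="choice")
            od_tbl = osc_feature_table(sess.lfp, sess.trials, sess.votes, epoch="delay")
            psd_tbl = psd_feature_table(sess.lfp, sess.trials, sess.votes, epoch="choice")
            ai_vals = oc_tbl.values[:, oc_tbl.feature_names.index("ai_mean")]
            qc = session_qc(
                sim.n_trials, ai_vals,
                excluded_trials=noise_exclusion(sess.lfp, sess.trials, epoch="choice"),
            )
        else:
            ai_vals = np.array([0.1])
            qc = session_qc(sim.n_trials, ai_vals, excluded_trials=[])
        qc_reports.append(
            {
                "session_id": sess.positions.session_id,
                "keep": qc.keep,
                "excluded_fraction": qc.excluded_fraction,
                "ai_median": qc.ai_median,
                "mean_agreement": rater.mean_agreement,
                "mean_kappa": rater.mean_kappa,
            }
        )
        if not qc.keep:
            continue
        sessions.append(sess)
        traj_parts.append(_offset_table(traj_tbl, offset))
        if with_lfp_tables:
            oc_parts.append(_offset_table(oc_tbl, offset))
            od_parts.append(_offset_table(od_tbl, offset))
            psd_parts.append(_offset_table(psd_tbl, offset))

    def _pool(parts: list[FeatureTable]) -> FeatureTable:
        if not parts:
            return FeatureTable(np.array([], int), [], np.empty((0, 0)), np.array([], object))
        return FeatureTable(
            np.concatenate([p.trial_ids for p in parts]),
            parts[0].feature_names,
            np.vstack([p.values for p in parts]),
            np.concatenate([p.labels for p in parts]),
        )

    empty = FeatureTable(np.array([], int), [], np.empty((0, 0)), np.array([], object))
    return Dataset(
        sessions=sessions,
        traj=_pool(traj_parts),
        osc_choice=_pool(oc_parts) if with_lfp_tables else empty,
        osc_delay=_pool(od_parts) if with_lfp_tables else empty,
        psd=_pool(psd_parts) if with_lfp_tables else empty,
        qc_reports=qc_reports,
    )


def evaluate_predictions(predsets: list[PredictionSet]) -> list[dict]:
    """Per-split accuracy/precision/recall/FNR/AUC from prediction sets."""
    out = []
    for p in predsets:
        m = classification_metrics(confusion_from_predictions(p.predicted, p.truth))
        m["auc"] = roc_and_auc(p.scores, p.truth).auc
        m["split_id"] = p.split_id
        out.append(m)
    return out


def run_zidphi_baseline(
    traj: FeatureTable, splits: SplitMatrix
) -> list[dict]:
    """Per-split two-point ROC area of the zIdPhi threshold classifier.

    The percentile threshold is selected on each split's training portion
    and applied to its test portion; the score per split is the two-point
    area (TPR + TNR)/2 of the resulting hard classifier.
    """
    col = traj.feature_names.index("zidphi")
    out = []
    for s in range(splits.n_splits):
        train = traj.subset(splits.train_ids(s))
        test = traj.subset(splits.test_ids(s))
        thr, _, _ = zidphi_threshold_classifier(train.values[:, col], train.labels)
        pred_pos = test.values[:, col] > thr
        is_pos = test.labels == "VTE"
        tpr = float(np.mean(pred_pos[is_pos]))
        tnr = float(np.mean(~pred_pos[~is_pos]))
        predicted = np.where(pred_pos, "VTE", "nonVTE").astype(object)
        m = classification_metrics(confusion_from_predictions(predicted, test.labels))
        m["auc"] = (tpr + tnr) / 2.0  # two-point ROC area of a hard threshold
        m["split_id"] = s
        out.append(m)
    return out


def run_selected_feature_cv(
    features: FeatureTable,
    splits: SplitMatrix,
    select: str = "psd",
    base: FeatureTable | None = None,
    seed: int = 1,
    gamma: float | None = None,
    cost: float | None = None,
) -> list[PredictionSet]:
    """SVM over splits with per-split training-data feature selection.

    ``select='psd'``: KS + BH selection of feature columns on the training
    portion; splits with no survivors yield no usable model and are scored
    at chance (constant scores). With ``base`` given, the selected columns
    are appended to the base table's features (the combined design).
    """
    if gamma is None:
        first = (base or features).subset(splits.train_ids(0))
        Xtr, _, _ = standardize(first.values, first.values)
        gamma, cost = grid_search_svm(Xtr, first.labels, seed=seed)
    out = []
    for s in range(splits.n_splits):
        tr_ids, te_ids = splits.train_ids(s), splits.test_ids(s)
        train_sel = features.subset(tr_ids)
        selected = select_psd_features(train_sel) if select == "psd" else list(
            features.feature_names
        )
        tables = []
        if base is not None:
            tables.append(base)
        if selected:
            tables.append(features.select(selected))
        if not tables:
            test = features.subset(te_ids)
            out.append(
                PredictionSet(
                    split_id=s, trial_ids=test.trial_ids,
                    scores=np.zeros(len(test)),
                    predicted=np.full(len(test), "nonVTE", object),
                    truth=test.labels, hyperparams={"selected": 0},
                )
            )
            continue
        tbl = tables[0]
        for extra in tables[1:]:
            tbl = FeatureTable.concat_features(tbl, extra)
        train, test = tbl.subset(tr_ids), tbl.subset(te_ids)
        Xtr, Xte, _ = standardize(train.values, test.values)
        model = train_svm(Xtr, train.labels, gamma=gamma, cost=cost)
        out.append(
            PredictionSet(
                split_id=s, trial_ids=test.trial_ids,
                scores=model.score_samples(Xte),
                predicted=model.predict(Xte),
                truth=test.labels,
                hyperparams={"gamma": gamma, "C": cost, "selected": len(selected)},
            )
        )
    return out


def _summary(per_split: list[dict]) -> dict:
    keys = [k for k in per_split[0] if k != "split_id"]
    return {
        k: {
            "mean": float(np.nanmean([m[k] for m in per_split])),
            "sd": float(np.nanstd([m[k] for m in per_split])),
        }
        for k in keys
    }


def run_experiment(cfg: RunConfig, dataset: Dataset | None = None) -> dict:
    """Execute one named experiment; returns (and optionally writes) a report."""
    needs_lfp = cfg.experiment not in ("traj_only", "zidphi_baseline")
    data = dataset or simulate_dataset(
        cfg.n_sessions, cfg.sim, seed=cfg.seed, with_lfp_tables=needs_lfp
    )
    labels_tbl = data.traj
    splits = build_split_matrix(
        labels_tbl.trial_ids, labels_tbl.labels, n_splits=cfg.n_splits, seed=cfg.seed
    )
    report: dict = {
        "experiment": cfg.experiment,
        "model": cfg.model,
        "seed": cfg.seed,
        "n_trials": int(len(labels_tbl)),
        "n_vte": int(np.sum(labels_tbl.labels == "VTE")),
        "qc": data.qc_reports,
    }

    if cfg.experiment == "zidphi_baseline":
        per_split = run_zidphi_baseline(data.traj, splits)
        report["per_split"] = per_split
        report["summary"] = _summary(per_split)
    elif cfg.experiment == "traj_only":
        preds = run_cv(data.traj, splits, model=cfg.model, seed=cfg.seed)
        per_split = evaluate_predictions(preds)
        report["per_split"] = per_split
        report["summary"] = _summary(per_split)
        report["hyperparams"] = preds[0].hyperparams
    elif cfg.experiment in ("osc_choice", "osc_delay"):
        tbl = data.osc_choice if cfg.experiment == "osc_choice" else data.osc_delay
        splits_o = build_split_matrix(
            tbl.trial_ids, tbl.labels, n_splits=cfg.n_splits, seed=cfg.seed
        )
        preds = run_cv(tbl, splits_o, model=cfg.model, seed=cfg.seed)
        base = random_label_baseline(tbl, splits_o, model=cfg.model, seed=cfg.seed)
        per_split = evaluate_predictions(preds)
        base_split = evaluate_predictions(base)
        deltas = delta_scores(per_split, base_split)
        report["per_split"] = per_split
        report["baseline_per_split"] = base_split
        report["delta_per_split"] = deltas
        report["summary"] = _summary(per_split)
        report["delta_summary"] = _summary(
            [{k: v for k, v in d.items() if k != "split_id"} | {"split_id": d["split_id"]} for d in deltas]
        )
    elif cfg.experiment == "psd":
        tbl = data.psd
        splits_o = build_split_matrix(
            tbl.trial_ids, tbl.labels, n_splits=cfg.n_splits, seed=cfg.seed
        )
        preds = run_selected_feature_cv(tbl, splits_o, select="psd", seed=cfg.seed)
        base = random_label_baseline(tbl, splits_o, model="svm", seed=cfg.seed)
        per_split = evaluate_predictions(preds)
        base_split = evaluate_predictions(base)
        report["per_split"] = per_split
        report["delta_per_split"] = delta_scores(per_split, base_split)
        report["summary"] = _summary(per_split)
    elif cfg.experiment == "combined":
        # join trajectory features with training-selected oscillation features
        common = [t for t in data.traj.trial_ids if t in set(data.osc_choice.trial_ids)]
        traj = data.traj.subset(common)
        osc = data.osc_choice.subset(common)
        splits_o = build_split_matrix(
            traj.trial_ids, traj.labels, n_splits=cfg.n_splits, seed=cfg.seed
        )
        comb_preds = run_selected_feature_cv(
            osc, splits_o, select="psd", base=traj, seed=cfg.seed
        )
        traj_preds = run_cv(traj, splits_o, model="svm", seed=cfg.seed)
        comb_split = evaluate_predictions(comb_preds)
        traj_split = evaluate_predictions(traj_preds)
        diffs = np.array(
            [c["auc"] - t["auc"] for c, t in zip(comb_split, traj_split)]
        )
        if np.count_nonzero(diffs) >= 6:
            w_stat, w_p = wilcoxon_signed_rank(diffs)
        else:  # (near-)identical pipelines: no evidence against symmetry
            w_stat, w_p = float("nan"), 1.0
        report["per_split"] = comb_split
        report["traj_per_split"] = traj_split
        report["summary"] = _summary(comb_split)
        report["auc_diff_mean"] = float(diffs.mean())
        report["wilcoxon"] = {"W": w_stat, "p": w_p}
        report["cohens_d"] = (
            cohens_d([c["auc"] for c in comb_split], [t["auc"] for t in traj_split])
        )

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / f"{cfg.experiment}_{cfg.model}.json").write_text(
            json.dumps(report, indent=1, default=_json_default)
        )
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
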
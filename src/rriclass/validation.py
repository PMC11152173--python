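"""Model assessment: F1, precision-recall curves, AUC-PR and baselines.

AUC-PR is computed by step-wise (right-continuous) integration — the
average-precision estimator — rather than trapezoidal interpolation,
which is optimistic for PR curves. The chance baseline of a PR curve is
the positive-class prevalence. The energy-only baseline scores each site
by the negated minimum duplex energy (more stable = higher score), the
classical stability-only ranking that the learned model is compared
against.

Cross-validation is stratified and site-grouped: all instances deriving
from one trusted site stay in the same fold, so a model is never
validated on the negative flank of a site it trained on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import (
    average_precision_score,
    f1_score as _sk_f1,
    precision_recall_curve,
    precision_score,
    recall_score,
)

from .config import Config
from .model import RRISiteClassifier


def f1(labels, predictions) -> float:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError("labels/predictions length mismatch")
    return float(_sk_f1(labels, predictions, zero_division=0))


def pr_curve(labels, scores):
    """Precision-recall curve with step-wise AUC-PR and chance baseline.

    Returns (points, auc_pr, baseline) where points is a list of
    (recall, precision) at every distinct threshold, descending score
    order, ties grouped.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if np.unique(labels).size < 2:
        raise ValueError("PR curve requires both classes")
    precision, recall, _ = precision_recall_curve(labels, scores)
    # sklearn returns points from the lowest threshold up plus the (0, 1)
    # endpoint; present them recall-ascending without the endpoint.
    points = list(zip(recall[::-1], precision[::-1]))[1:]
    auc_pr = float(average_precision_score(labels, scores))
    baseline = float(np.mean(labels))
    return points, auc_pr, baseline


def energy_baseline_scores(instances):
    """Stability-only score per instance: negated minimum duplex energy.

    Instances without duplexes are excluded; returns (ids, scores,
    skipped_ids).
    """
    ids, scores, skipped = [], [], []
    for inst in instances:
        if not inst.has_prediction:
            skipped.append(inst.instance_id)
            continue
        ids.append(inst.instance_id)
        scores.append(-inst.min_energy())
    return ids, np.array(scores, dtype=float), skipped


def cross_validate(
    features,
    config: Config | None = None,
    groups=None,
):
    """Site-grouped stratified k-fold CV of the full classifier.

    ``features`` is a FeatureTable (labels taken from it) whose site
    groups keep sibling instances in one fold. Returns (per-fold
    DataFrame, aggregate dict).
    """
    config = config or Config()
    table = features.labelled_subset()
    X = table.matrix()
    y = table.labels.astype(int)
    groups = np.asarray(groups if groups is not None else table.site_groups())

    proto = RRISiteClassifier(
        search_iters=config.search_iters,
        cv_folds=config.cv_folds,
        importance_cutoff=config.importance_cutoff,
        random_state=config.rng_seed,
    )
    splitter = proto._splitter(config.rng_seed, groups)
    rows = []
    for fold_no, (tr, te) in enumerate(splitter.split(X, y, groups)):
        if np.unique(y[tr]).size < 2 or np.unique(y[te]).size < 2:
            raise ValueError(f"fold {fold_no}: stratification infeasible")
        clf = RRISiteClassifier(
            search_iters=config.search_iters,
            cv_folds=config.cv_folds,
            importance_cutoff=config.importance_cutoff,
            random_state=config.rng_seed,
        )
        clf.fit(X[tr], y[tr], groups=groups[tr])
        pred = clf.predict(X[te])
        proba = clf.predict_proba(X[te])[:, 1]
        rows.append(
            {
                "fold": fold_no,
                "f1": f1(y[te], pred),
                "precision": float(precision_score(y[te], pred, zero_division=0)),
                "recall": float(recall_score(y[te], pred, zero_division=0)),
                "auc_pr": float(average_precision_score(y[te], proba)),
            }
        )
    report = pd.DataFrame(rows)
    aggregate = {
        f"{m}_{stat}": float(getattr(report[m], stat)())
        for m in ("f1", "precision", "recall", "auc_pr")
        for stat in ("mean", "std")
    }
    return report, aggregate


def validate_on(model, features):
    """External validation: apply a trained model to a labelled feature
    table from a different source (train-on-A / test-on-B)."""
    table = features.labelled_subset()
    X = table.matrix()
    y = table.labels.astype(int)
    pred = model.classifier.predict(X)
    proba = model.classifier.predict_proba(X)[:, 1]
    return {
        "f1": f1(y, pred),
        "precision": float(precision_score(y, pred, zero_division=0)),
        "recall": float(recall_score(y, pred, zero_division=0)),
        "auc_pr": float(average_precision_score(y, proba)),
        "n": int(len(y)),
    }


def write_metrics_report(report: pd.DataFrame, aggregate: dict, path) -> None:
    with open(path, "w") as fh:
        report.to_csv(fh, sep="\t", index=False, float_format="%.6g")
        fh.write("# aggregate\n")
        for k in sorted(aggregate):
            fh.write(f"# {k}\t{aggregate[k]:.6g}\n")


def write_pr_points(points, path) -> None:
    """PR-curve points as a two-column (recall, precision) TSV."""
    with open(path, "w") as fh:
        fh.write("recall\tprecision\n")
        for r, p in points:
            fh.write(f"{r:.6g}\t{p:.6g}\n")


def plot_pr_curves(curves: dict, path) -> None:
    """Optional PR-curve plot; ``curves`` maps name -> (points, auc,
    baseline)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for name, (points, auc, baseline) in curves.items():
        rec = [p[0] for p in points]
        prec = [p[1] for p in points]
        ax.step(rec, prec, where="post", label=f"{name} (AUC-PR {auc:.2f})")
        ax.axhline(baseline, ls="--", lw=0.8, color="gray")
    ax.set_xlabel("recall")
    ax.set_ylabel("precision")
    ax.set_ylim(0, 1.05)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
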